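"""Stratified nested cross-validation and the metric panel.

Four split regimes are supported, each answering a different
generalization question about a (drug A, drug B, cell line) dataset:

``random``            shuffle samples into k folds (optimistic baseline);
``leave_combination`` all samples of an unordered drug pair share one test
                      fold — the "novel combination" regime;
``leave_drug``        drugs are partitioned into folds; a fold's test set is
                      every quartet touching a held-out drug, and its
                      training set excludes all of them — "novel drug";
``leave_cell_line``   the same construction over cell lines.

In the entity-held-out regimes a quartet can touch held-out entities of two
different folds; it is tested in the fold of the lexicographically smaller
entity and excluded from both folds' training sets (flagged for audit).
Each outer fold carves one inner validation split (3:1 by the same scheme)
from its training pool for hyperparameter selection and early stopping.

The metric panel mirrors a regression screen evaluation: MSE, RMSE and
Pearson r for the continuous scores, plus classification metrics (ROC and
PR AUC, accuracy, balanced accuracy, precision, sensitivity, specificity,
Cohen's kappa) after binarizing measured scores at a synergy threshold
(default 30, the top decile of a typical Loewe score distribution) and
predictions at a cut chosen to maximize balanced accuracy on validation
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCHEMES",
    "FoldAssignment",
    "MetricsReport",
    "make_folds",
    "nested_cv",
    "regression_metrics",
    "classification_metrics",
    "select_threshold",
    "paired_method_test",
    "groupwise_correlation",
    "write_fold_csv",
    "metrics_table",
]

SCHEMES = ("random", "leave_combination", "leave_drug", "leave_cell_line")
MEASURED_SYNERGY_THRESHOLD = 30.0


def _pair_key(df: pd.DataFrame) -> pd.Series:
    a, b = df["drug_a"], df["drug_b"]
    return pd.Series(np.where(a <= b, a + "||" + b, b + "||" + a), index=df.index)


@dataclass
class FoldAssignment:
    """Outer/inner partition of quartets under one split scheme.

    ``test_fold[i]`` is the outer fold whose test set holds sample i (test
    sets are disjoint and cover all samples).  ``validation[f]`` marks the
    inner validation rows carved from fold f's training pool;
    ``excluded[f]`` marks rows touching fold f's held-out entities that are
    tested elsewhere (cross-fold quartets) and must not be trained on.
    ``cross_fold`` flags those quartets globally for audit.
    """

    scheme: str
    k: int
    seed: int
    quartets: pd.DataFrame
    test_fold: np.ndarray
    validation: dict[int, np.ndarray]
    excluded: dict[int, np.ndarray]
    cross_fold: np.ndarray
    entity_group: dict | None = None  # drug/cell-line -> fold, entity schemes only

    def roles(self, fold: int) -> pd.Series:
        """Per-sample role within one outer fold: train/validation/test/excluded."""
        role = np.full(len(self.quartets), "train", dtype=object)
        role[self.validation[fold]] = "validation"
        role[self.excluded[fold]] = "excluded"
        role[self.test_fold == fold] = "test"
        return pd.Series(role, index=self.quartets.index)


def _greedy_groups(keys: pd.Series, k: int, rng) -> pd.Series:
    """Assign each group of samples to one of k folds, greedily balancing
    fold sizes by sample count after a seeded shuffle of the groups."""
    counts = keys.value_counts()
    groups = counts.index.to_numpy()
    rng.shuffle(groups)
    load = np.zeros(k, dtype=int)
    assignment = {}
    for g in groups:
        f = int(np.argmin(load))  # ties -> lowest fold index
        assignment[g] = f
        load[f] += counts[g]
    return keys.map(assignment)


def make_folds(
    quartets: pd.DataFrame, scheme: str, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Build the outer folds and one inner validation split per fold."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    q = quartets.reset_index(drop=True)
    n = len(q)
    rng = np.random.default_rng(seed)
    cross = np.zeros(n, dtype=bool)

    if scheme == "random":
        order = rng.permutation(n)
        test_fold = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, k)):
            test_fold[chunk] = f
    elif scheme == "leave_combination":
        pairs = _pair_key(q)
        if pairs.nunique() < k:
            raise ValueError(
                f"leave_combination needs >= {k} distinct drug pairs, "
                f"got {pairs.nunique()}"
            )
        test_fold = _greedy_groups(pairs, k, rng).to_numpy()
    else:
        col = "drug" if scheme == "leave_drug" else "cell_line"
        if scheme == "leave_drug":
            entities = pd.Index(pd.concat([q["drug_a"], q["drug_b"]]).unique())
        else:
            entities = pd.Index(q["cell_line"].unique())
        if len(entities) < k:
            raise ValueError(
                f"{scheme} needs >= {k} distinct {col}s, got {len(entities)}"
            )
        ent = entities.to_numpy().copy()
        rng.shuffle(ent)
        # greedy balance by how many quartets touch each entity
        if scheme == "leave_drug":
            touch = pd.concat([q["drug_a"], q["drug_b"]]).value_counts()
        else:
            touch = q["cell_line"].value_counts()
        load = np.zeros(k, dtype=int)
        group = {}
        for e in ent:
            f = int(np.argmin(load))
            group[e] = f
            load[f] += int(touch[e])
        if scheme == "leave_cell_line":
            test_fold = q["cell_line"].map(group).to_numpy()
        else:
            fa = q["drug_a"].map(group).to_numpy()
            fb = q["drug_b"].map(group).to_numpy()
            # both drugs held out in different folds: test in the fold of the
            # lexicographically smaller drug; excluded from both trainings
            smaller_is_a = q["drug_a"].to_numpy() <= q["drug_b"].to_numpy()
            test_fold = np.where(smaller_is_a, fa, fb)
            cross = fa != fb

    # Per-fold training exclusions: in leave_drug a non-test quartet that
    # touches a fold-f drug (its other drug was held out elsewhere) must not
    # appear in fold f's training pool either.
    excluded: dict[int, np.ndarray] = {f: np.zeros(0, dtype=int) for f in range(k)}
    if scheme == "leave_drug":
        fa = q["drug_a"].map(group).to_numpy()
        fb = q["drug_b"].map(group).to_numpy()
        for f in range(k):
            touches = (fa == f) | (fb == f)
            excluded[f] = np.where(touches & (test_fold != f))[0]

    validation: dict[int, np.ndarray] = {}
    for f in range(k):
        pool_mask = (test_fold != f)
        if len(excluded[f]):
            pool_mask[excluded[f]] = False
        pool = np.where(pool_mask)[0]
        validation[f] = _inner_validation(q, pool, scheme, np.random.default_rng(seed * 100003 + f + 1))

    return FoldAssignment(
        scheme=scheme,
        k=k,
        seed=seed,
        quartets=q,
        test_fold=test_fold,
        validation=validation,
        excluded=excluded,
        cross_fold=cross,
        entity_group=group if scheme in ("leave_drug", "leave_cell_line") else None,
    )


def _inner_validation(q, pool, scheme, rng) -> np.ndarray:
    """Carve ~1/4 of a training pool as validation, honoring the scheme."""
    target = max(1, len(pool) // 4)
    sub = q.iloc[pool]
    if scheme == "random":
        pick = rng.permutation(len(pool))[:target]
        return pool[pick]
    if scheme == "leave_combination":
        keys = _pair_key(sub).to_numpy()
    elif scheme == "leave_drug":
        keys = None  # handled below (two keys per sample)
    else:
        keys = sub["cell_line"].to_numpy()

    if scheme == "leave_drug":
        drugs = pd.concat([sub["drug_a"], sub["drug_b"]]).unique()
        rng.shuffle(drugs)
        chosen: set = set()
        covered = np.zeros(len(sub), dtype=bool)
        a = sub["drug_a"].to_numpy()
        b = sub["drug_b"].to_numpy()
        for d in drugs:
            if covered.sum() >= target:
                break
            chosen.add(d)
            covered |= (a == d) | (b == d)
        return pool[covered]

    uniq = pd.unique(keys)
    rng.shuffle(uniq)
    covered = np.zeros(len(sub), dtype=bool)
    for u in uniq:
        if covered.sum() >= target:
            break
        covered |= keys == u
    return pool[covered]


def write_fold_csv(folds: FoldAssignment, path):
    """Long-format audit file: one row per (sample, outer fold) with its role."""
    frames = []
    for f in range(folds.k):
        df = folds.quartets[["drug_a", "drug_b", "cell_line"]].copy()
        df["outer_fold"] = f
        df["role"] = folds.roles(f).to_numpy()
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nested cross-validation harness
# ---------------------------------------------------------------------------

def nested_cv(
    quartets: pd.DataFrame,
    folds: FoldAssignment,
    learner_factory,
    grid: list[dict],
) -> tuple[pd.DataFrame, list[dict]]:
    """Grid search in the inner loop, one unbiased prediction per test sample.

    For each outer fold every grid point is trained on the inner-training
    rows and scored by validation MSE; the best point is retrained on the
    full outer-training pool (the inner validation rows remain available to
    the learner for early stopping) and applied exactly once to the test
    fold.  Returns the quartet table with ``prediction`` and ``outer_fold``
    columns, and the chosen grid point per fold.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    q = folds.quartets
    predictions = np.full(len(q), np.nan)
    chosen = []
    for f in range(folds.k):
        roles = folds.roles(f).to_numpy()
        train_df = q[roles == "train"]
        val_df = q[roles == "validation"]
        test_df = q[roles == "test"]
        best_mse, best_params = np.inf, None
        for params in grid:
            try:
                learner = learner_factory(**params)
                learner.fit(train_df, val_df)
                mse = float(
                    np.mean((learner.predict(val_df) - val_df["synergy"]) ** 2)
                )
            except Exception as err:  # noqa: BLE001 - grid point failure is logged
                warnings.warn(f"grid point {params} failed on fold {f}: {err}")
                continue
            if mse < best_mse:
                best_mse, best_params = mse, params
        if best_params is None:
            raise RuntimeError(f"every grid point failed on fold {f}")
        learner = learner_factory(**best_params)
        learner.fit(pd.concat([train_df, val_df]), val_df)
        predictions[roles == "test"] = learner.predict(test_df)
        chosen.append(best_params)
    out = q.copy()
    out["prediction"] = predictions
    out["outer_fold"] = folds.test_fold
    return out, chosen


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Regression + classification panel for one prediction set."""

    mse: float
    rmse: float
    pearson_r: float
    roc_auc: float = np.nan
    pr_auc: float = np.nan
    acc: float = np.nan
    bacc: float = np.nan
    prec: float = np.nan
    tpr: float = np.nan
    tnr: float = np.nan
    kappa: float = np.nan
    threshold_used: float = np.nan
    n: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def regression_metrics(y, yhat) -> dict:
    """MSE, RMSE and Pearson r; r is NaN (undefined) under zero variance."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need equal-length vectors with at least 2 samples")
    mse = float(np.mean((y - yhat) ** 2))
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(y, yhat).statistic)
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "pearson_r": r}


def classification_metrics(
    y,
    yhat,
    measured_threshold: float = MEASURED_SYNERGY_THRESHOLD,
    predicted_threshold: float | None = None,
) -> dict:
    """Binary panel: measured scores > threshold are the positive class.

    ROC/PR AUCs rank the continuous predictions; the thresholded metrics
    binarize predictions at ``predicted_threshold`` (defaulting to the
    measured threshold).  With a single-class truth the AUCs are NaN but
    the thresholded metrics are still computed.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if predicted_threshold is None:
        predicted_threshold = measured_threshold
    pos = y > measured_threshold
    pred_pos = yhat > predicted_threshold
    if pos.all() or not pos.any():
        roc = pr = np.nan
    else:
        roc = float(roc_auc_score(pos, yhat))
        pr = float(average_precision_score(pos, yhat))
    tp = int(np.sum(pos & pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    n = len(y)
    tpr = tp / (tp + fn) if tp + fn else np.nan
    tnr = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    acc = (tp + tn) / n
    bacc = np.nanmean([tpr, tnr])
    po = acc
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe != 1 else np.nan
    return {
        "roc_auc": roc,
        "pr_auc": pr,
        "acc": acc,
        "bacc": float(bacc),
        "prec": prec,
        "tpr": tpr,
        "tnr": tnr,
        "kappa": kappa,
        "threshold_used": float(predicted_threshold),
        "n": n,
    }


def full_report(
    y, yhat, measured_threshold: float = MEASURED_SYNERGY_THRESHOLD,
    predicted_threshold: float | None = None,
) -> MetricsReport:
    return MetricsReport(
        **regression_metrics(y, yhat),
        **classification_metrics(y, yhat, measured_threshold, predicted_threshold),
    )


def select_threshold(
    y_val, yhat_val, measured_threshold: float = MEASURED_SYNERGY_THRESHOLD
) -> float:
    """Cut on predictions maximizing balanced accuracy on validation data.

    Candidates are the midpoints between consecutive sorted unique
    predictions, plus one cut below the minimum (everything positive).
    Ties break toward the lower threshold.
    """
    y_val = np.asarray(y_val, dtype=float)
    yhat_val = np.asarray(yhat_val, dtype=float)
    pos = y_val > measured_threshold
    if pos.all() or not pos.any():
        raise ValueError("validation data must contain both classes")
    uniq = np.unique(yhat_val)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_bacc = candidates[0], -np.inf
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for t in candidates:
        pred = yhat_val > t
        tpr = np.sum(pred & pos) / n_pos
        tnr = np.sum(~pred & ~pos) / n_neg
        bacc = (tpr + tnr) / 2
        if bacc > best_bacc:  # strict: ties keep the lower threshold
            best_bacc, best_t = bacc, t
    return float(best_t)


def paired_method_test(errors_1, errors_2):
    """Wilcoxon signed-rank test on paired per-sample squared errors.

    Zero differences are dropped (standard convention).  With all pairs
    tied the statistic is undefined and (nan, nan) is returned.
    """
    errors_1 = np.asarray(errors_1, dtype=float)
    errors_2 = np.asarray(errors_2, dtype=float)
    if errors_1.shape != errors_2.shape:
        raise ValueError("paired error vectors must have equal length")
    diffs = errors_1 - errors_2
    if np.all(diffs == 0):
        return np.nan, np.nan
    res = stats.wilcoxon(errors_1, errors_2, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def groupwise_correlation(
    quartets: pd.DataFrame, predictions, group_by: str = "drug"
) -> pd.DataFrame:
    """Per-entity Pearson r between measured and predicted synergy.

    ``group_by`` is "drug" (a quartet counts for both pair members) or
    "cell_line".  Entities with fewer than 3 samples or zero variance are
    flagged (``too_few`` / ``zero_variance``), never silently dropped.
    """
    if group_by not in ("drug", "cell_line"):
        raise ValueError("group_by must be 'drug' or 'cell_line'")
    q = quartets.reset_index(drop=True)
    pred = np.asarray(predictions, dtype=float)
    if group_by == "cell_line":
        groups = {c: np.where(q["cell_line"] == c)[0] for c in q["cell_line"].unique()}
    else:
        drugs = pd.concat([q["drug_a"], q["drug_b"]]).unique()
        groups = {
            d: np.where((q["drug_a"] == d) | (q["drug_b"] == d))[0] for d in drugs
        }
    rows = []
    for entity, idx in sorted(groups.items()):
        yy = q["synergy"].to_numpy(float)[idx]
        pp = pred[idx]
        if len(idx) < 3:
            rows.append({"entity": entity, "n": len(idx), "r": np.nan, "flag": "too_few"})
        elif np.ptp(yy) == 0 or np.ptp(pp) == 0:
            rows.append(
                {"entity": entity, "n": len(idx), "r": np.nan, "flag": "zero_variance"}
            )
        else:
            r = float(stats.pearsonr(yy, pp).statistic)
            rows.append({"entity": entity, "n": len(idx), "r": r, "flag": "ok"})
    return pd.DataFrame(rows).set_index("entity")


def metrics_table(per_fold: list[MetricsReport]) -> pd.DataFrame:
    """Per-fold metric rows plus mean and sd summary rows."""
    df = pd.DataFrame([m.to_dict() for m in per_fold])
    df.index = [f"fold_{i}" for i in range(len(per_fold))]
    summary = pd.DataFrame(
        {"mean": df.mean(numeric_only=True), "sd": df.std(ddof=1, numeric_only=True)}
    ).T
    return pd.concat([df, summary])
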