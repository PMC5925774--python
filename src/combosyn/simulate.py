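"""Synthetic combination-screen generator.

Every other module can be exercised without downloading a real screen: this
module generates (i) the combination design — an "exhaustive" drug set
combined all-vs-all plus a "supplemental" set combined only against the
exhaustive drugs, crossed with a cell-line panel; (ii) a latent world with
drug mechanism classes and cell-line pathway activities that drive both
the feature blocks and a ground-truth synergy function; (iii) dose-response
corpora: Hill-shaped single-agent titrations (8 doses, 6 replicates) and
4x4 checkerboards (quadruplicate) whose deviation from the Loewe reference
is planted and therefore known exactly.

The default full-scale design (22 exhaustive + 16 supplemental drugs, 39
cell lines) reproduces the arithmetic of a published large oncology screen:
583 distinct combinations covering 83% of all possible pairs, and 22 737
(drug, drug, cell line, synergy) quartets.  The default label distribution
is concentrated near zero with heavy tails (median 4.37, sd ~23 synergy
units), emulating a Loewe score distribution from such a screen.  Reduced
sizes (8 drugs, 6 cell lines) are provided for fast tests.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurize import FeatureBlock
from .surfaces import (
    CHECKERBOARD_COLUMNS,
    SINGLE_AGENT_COLUMNS,
    HillCurve,
    hill_response,
    loewe_reference,
)

__all__ = [
    "DesignSpec",
    "WorldSpec",
    "SyntheticWorld",
    "SurfaceCorpus",
    "REDUCED_DESIGN",
    "generate_design",
    "generate_world",
    "generate_surfaces",
]


@dataclass(frozen=True)
class DesignSpec:
    """Screen geometry: which drug pairs are measured on how many cell lines."""

    n_exhaustive: int = 22
    n_supplemental: int = 16
    n_cell_lines: int = 39

    def __post_init__(self):
        if self.n_exhaustive < 1 or self.n_supplemental < 0 or self.n_cell_lines < 1:
            raise ValueError("design counts must be positive")

    @property
    def n_drugs(self) -> int:
        return self.n_exhaustive + self.n_supplemental

    @property
    def n_pairs(self) -> int:
        return (
            self.n_exhaustive * (self.n_exhaustive - 1) // 2
            + self.n_supplemental * self.n_exhaustive
        )

    @property
    def coverage(self) -> float:
        """Measured fraction of all possible unordered drug pairs."""
        total = self.n_drugs * (self.n_drugs - 1) // 2
        return self.n_pairs / total


REDUCED_DESIGN = DesignSpec(n_exhaustive=5, n_supplemental=3, n_cell_lines=6)


def generate_design(spec: DesignSpec = DesignSpec()):
    """Enumerate the measured pairs and the quartet skeleton.

    Drugs are named ``E01..`` (exhaustive) and ``S01..`` (supplemental);
    cell lines ``C01..``.  Pairs are all exhaustive-exhaustive pairs plus
    every supplemental-exhaustive pair; no self-pairs, no
    supplemental-supplemental pairs.  The skeleton is pairs x cell lines.
    """
    we = len(str(max(spec.n_exhaustive, 1)))
    ws = len(str(max(spec.n_supplemental, 1)))
    wc = len(str(spec.n_cell_lines))
    exhaustive = [f"E{i + 1:0{we}d}" for i in range(spec.n_exhaustive)]
    supplemental = [f"S{i + 1:0{ws}d}" for i in range(spec.n_supplemental)]
    cells = [f"C{i + 1:0{wc}d}" for i in range(spec.n_cell_lines)]
    pairs = [
        (exhaustive[i], exhaustive[j])
        for i in range(len(exhaustive))
        for j in range(i + 1, len(exhaustive))
    ]
    pairs += [(s, e) for s in supplemental for e in exhaustive]
    skeleton = pd.DataFrame(
        [(a, b, c) for a, b in pairs for c in cells],
        columns=["drug_a", "drug_b", "cell_line"],
    )
    return pairs, skeleton


@dataclass(frozen=True)
class WorldSpec:
    """Latent structure behind features and labels.

    Labels are calibrated so the noiseless synergy function has the target
    median and a spread that, combined with ``label_noise_sd``, yields the
    target standard deviation — the shape of a Loewe score distribution
    from a large screen: most combinations near additive, heavy tails.
    """

    n_classes: int = 4
    n_pathways: int = 3
    n_count_features: int = 64
    n_continuous_features: int = 8
    n_binary_features: int = 12
    n_genes: int = 100
    n_informative_genes: int = 30
    target_median: float = 4.37
    target_sd: float = 23.0
    label_noise_sd: float = 5.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticWorld:
    """Realized world: features, latent assignments, truth, labels."""

    spec: WorldSpec
    drug_block: FeatureBlock
    drug_kinds: pd.Series
    expression_block: FeatureBlock
    informative_genes: list[str]
    drug_class: pd.Series
    pathway_activity: pd.DataFrame
    quartets: pd.DataFrame  # drug_a, drug_b, cell_line, synergy (noisy labels)
    truth: pd.Series  # noiseless synergy per skeleton row

    def truth_fn(self, drug_a: str, drug_b: str, cell_line: str) -> float:
        """Noiseless expected synergy for one (unordered) combination."""
        key = tuple(sorted((drug_a, drug_b))) + (cell_line,)
        return float(self._truth_lookup[key])

    @property
    def _truth_lookup(self):
        idx = [
            tuple(sorted((a, b))) + (c,)
            for a, b, c in zip(
                self.quartets["drug_a"], self.quartets["drug_b"], self.quartets["cell_line"]
            )
        ]
        return dict(zip(idx, self.truth))


def generate_world(
    spec: WorldSpec, design: DesignSpec = DesignSpec()
) -> SyntheticWorld:
    """Draw a synthetic world over a combination design.

    Drugs belong to latent mechanism classes; their count features are
    Poisson draws around class-specific sparse archetypes, continuous
    features are Gaussian around class means, and binary features are
    Bernoulli with class-specific rates.  Cell lines carry pathway activity
    vectors; an informative subset of genes tracks pathway activity
    linearly while the remainder is noise.  Ground-truth synergy is a
    heavy-tailed class-pair interaction modulated by the cell line's
    pathway activity, affinely calibrated to the target median/sd; labels
    add zero-centred Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    pairs, skeleton = generate_design(design)
    drugs = sorted(set(skeleton["drug_a"]) | set(skeleton["drug_b"]))
    cells = sorted(skeleton["cell_line"].unique())

    # -- latent assignments -------------------------------------------------
    classes = rng.integers(0, spec.n_classes, size=len(drugs))
    drug_class = pd.Series(classes, index=drugs)
    pathways = rng.normal(size=(len(cells), spec.n_pathways))
    pathway_activity = pd.DataFrame(
        pathways, index=cells, columns=[f"pathway_{p}" for p in range(spec.n_pathways)]
    )

    # -- drug features -------------------------------------------------------
    archetypes = rng.gamma(1.0, 2.0, size=(spec.n_classes, spec.n_count_features))
    archetypes *= rng.random((spec.n_classes, spec.n_count_features)) < 0.3
    counts = rng.poisson(archetypes[classes] + 0.05)
    cont_means = rng.normal(0, 2.0, size=(spec.n_classes, spec.n_continuous_features))
    cont = cont_means[classes] + rng.normal(
        0, 0.5, size=(len(drugs), spec.n_continuous_features)
    )
    bin_rates = rng.beta(1.0, 3.0, size=(spec.n_classes, spec.n_binary_features))
    binary = (rng.random((len(drugs), spec.n_binary_features)) < bin_rates[classes]).astype(
        np.int64
    )
    drug_values = pd.DataFrame(
        np.hstack([counts.astype(float), cont, binary.astype(float)]),
        index=drugs,
        columns=(
            [f"cnt_{i:03d}" for i in range(spec.n_count_features)]
            + [f"phys_{i:02d}" for i in range(spec.n_continuous_features)]
            + [f"flag_{i:02d}" for i in range(spec.n_binary_features)]
        ),
    )
    drug_kinds = pd.Series("continuous", index=drug_values.columns)
    drug_kinds[drug_kinds.index.str.startswith("cnt_")] = "count"
    drug_kinds[drug_kinds.index.str.startswith("flag_")] = "binary"
    drug_block = FeatureBlock(drug_values, drug_kinds)

    # -- expression ----------------------------------------------------------
    gene_names = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    informative = gene_names[: spec.n_informative_genes]
    loadings = rng.normal(size=(spec.n_pathways, spec.n_informative_genes))
    expr = rng.normal(6.0, 1.0, size=(len(cells), spec.n_genes))
    expr[:, : spec.n_informative_genes] += pathways @ loadings
    expr_values = pd.DataFrame(
        expr, index=cells, columns=[f"expr_{g}" for g in gene_names]
    )
    expression_block = FeatureBlock(
        expr_values, pd.Series("continuous", index=expr_values.columns)
    )

    # -- ground-truth synergy ------------------------------------------------
    # heavy-tailed class-pair interactions, cell-modulated through pathways
    interaction = rng.laplace(0.0, 1.0, size=(spec.n_classes, spec.n_classes))
    interaction = (interaction + interaction.T) / 2.0
    cell_weights = rng.normal(size=spec.n_pathways)
    cell_factor = 1.0 + 0.8 * np.tanh(pathways @ cell_weights)
    cell_factor_s = pd.Series(cell_factor, index=cells)
    ca = drug_class[skeleton["drug_a"]].to_numpy()
    cb = drug_class[skeleton["drug_b"]].to_numpy()
    raw = interaction[ca, cb] * cell_factor_s[skeleton["cell_line"]].to_numpy()

    g_sd = math.sqrt(max(spec.target_sd**2 - spec.label_noise_sd**2, 1e-12))
    raw_sd = raw.std()
    scale = g_sd / raw_sd if raw_sd > 0 else 0.0
    truth = raw * scale
    truth = truth + (spec.target_median - np.median(truth))
    labels = truth + rng.normal(0.0, spec.label_noise_sd, size=len(truth))

    quartets = skeleton.copy()
    quartets["synergy"] = labels
    return SyntheticWorld(
        spec=spec,
        drug_block=drug_block,
        drug_kinds=drug_kinds,
        expression_block=expression_block,
        informative_genes=informative,
        drug_class=drug_class,
        pathway_activity=pathway_activity,
        quartets=quartets,
        truth=pd.Series(truth, index=skeleton.index),
    )


# ---------------------------------------------------------------------------
# Dose-response corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillRanges:
    """Sampling ranges for synthetic single-agent curves."""

    e0_mean: float = 100.0
    e0_sd: float = 1.0
    einf_low: float = 0.0
    einf_high: float = 40.0
    log10_ec50_low: float = -1.5
    log10_ec50_high: float = 1.0
    h_low: float = 0.8
    h_high: float = 2.5


@dataclass(frozen=True)
class SurfaceCorpus:
    """Generated screen: raw tables plus the hidden truth for round trips."""

    single_agent: pd.DataFrame
    checkerboards: pd.DataFrame
    curves: dict  # (drug, cell_line) -> HillCurve
    planted_totals: pd.Series  # per skeleton row, sum-aggregated deviation


def _bump_weights() -> np.ndarray:
    """Smooth mid-dose bump over the 4x4 grid, normalized to sum 1."""
    i = np.arange(4)
    g = np.exp(-((i - 1.5) ** 2) / 2.0)
    w = np.outer(g, g)
    return w / w.sum()


def generate_surfaces(
    skeleton: pd.DataFrame,
    hill_ranges: HillRanges = HillRanges(),
    planted_totals=None,
    seed: int = 0,
    *,
    pattern: str = "bump",
    noise_sd: float = 0.0,
    n_single_doses: int = 8,
    n_single_replicates: int = 6,
    n_board_replicates: int = 4,
) -> SurfaceCorpus:
    """Emit single-agent and checkerboard tables with known Loewe deviations.

    One Hill curve is drawn per (drug, cell line).  Each quartet's
    checkerboard equals its Loewe reference minus a planted deviation whose
    sum over the 16 wells is ``planted_totals`` for that row (default 0 =
    perfectly additive), distributed over wells either uniformly or as a
    smooth mid-dose bump; replicate-level Gaussian measurement noise
    (``noise_sd``, %-of-control points) is added on top.  Single-agent
    titrations span 8 log-spaced doses around each curve's EC50 with 6
    replicates; checkerboards use the 4 central doses in quadruplicate.
    """
    if pattern not in ("bump", "uniform"):
        raise ValueError("pattern must be 'bump' or 'uniform'")
    rng = np.random.default_rng(seed)
    if planted_totals is None:
        planted_totals = np.zeros(len(skeleton))
    planted_totals = pd.Series(np.asarray(planted_totals, dtype=float), index=skeleton.index)
    if not np.all(np.isfinite(planted_totals)):
        raise ValueError("planted deviations must be finite")
    weights = _bump_weights() if pattern == "bump" else np.full((4, 4), 1 / 16)

    combos = {
        (row.drug_a, row.cell_line) for row in skeleton.itertuples()
    } | {(row.drug_b, row.cell_line) for row in skeleton.itertuples()}
    curves = {}
    for drug, cell in sorted(combos):
        e0 = rng.normal(hill_ranges.e0_mean, hill_ranges.e0_sd)
        einf = rng.uniform(hill_ranges.einf_low, hill_ranges.einf_high)
        ec50 = 10 ** rng.uniform(hill_ranges.log10_ec50_low, hill_ranges.log10_ec50_high)
        h = rng.uniform(hill_ranges.h_low, hill_ranges.h_high)
        curves[(drug, cell)] = HillCurve(e0=e0, einf=einf, ec50=ec50, h=h)

    def dose_ladder(curve: HillCurve, n: int) -> np.ndarray:
        return np.geomspace(curve.ec50 / 20.0, curve.ec50 * 20.0, n)

    single_rows = []
    for (drug, cell), curve in sorted(curves.items()):
        doses = dose_ladder(curve, n_single_doses)
        clean = hill_response(curve, doses)
        for rep in range(1, n_single_replicates + 1):
            noisy = clean + rng.normal(0.0, noise_sd, size=len(doses)) if noise_sd else clean
            for d, r in zip(doses, noisy):
                single_rows.append((drug, cell, d, r, rep))
    single_agent = pd.DataFrame(single_rows, columns=SINGLE_AGENT_COLUMNS)

    board_rows = []
    for row in skeleton.itertuples():
        ca = curves[(row.drug_a, row.cell_line)]
        cb = curves[(row.drug_b, row.cell_line)]
        doses_a = dose_ladder(ca, n_single_doses)[2:6]
        doses_b = dose_ladder(cb, n_single_doses)[2:6]
        total = planted_totals[row.Index]
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                ref = loewe_reference(da, db, ca, cb)
                clean = ref - total * weights[i, j]
                for rep in range(1, n_board_replicates + 1):
                    val = clean + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    board_rows.append(
                        (row.drug_a, row.drug_b, row.cell_line, da, db, val, rep)
                    )
    checkerboards = pd.DataFrame(board_rows, columns=CHECKERBOARD_COLUMNS)
    return SurfaceCorpus(
        single_agent=single_agent,
        checkerboards=checkerboards,
        curves=curves,
        planted_totals=planted_totals,
    )
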