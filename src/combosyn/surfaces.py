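"""Dose-response surfaces and Loewe-additivity synergy scoring.

A combination screen measures two drugs on one cell line over a factorial
("checkerboard") dose grid, alongside separate single-agent titrations.
This module fits 4-parameter Hill curves to the single-agent data, completes
the measured 4x4 checkerboard into a 5x5 surface whose zero-dose edges come
from the fitted curves, and scores each surface against the Loewe-additivity
null model: the expected response E at doses (a, b) solves

    a / A(E) + b / B(E) = 1

where A and B are the inverse single-agent dose-response functions.  The
synergy score of a surface is the aggregated deviation (reference minus
observed) over the 16 nonzero-dose wells; positive scores mean more growth
inhibition than additivity predicts, i.e. synergy.

Responses are expressed as percent of untreated control throughout.  They
may exceed 100 or drop below 0 (cytotoxicity) and are never clipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HillCurve",
    "Checkerboard",
    "DoseSurface",
    "SynergyQuartet",
    "InvalidInputError",
    "DegenerateFitError",
    "fit_hill",
    "hill_response",
    "inverse_hill",
    "loewe_reference",
    "assemble_surface",
    "synergy_score",
    "score_screen",
    "read_single_agent_csv",
    "read_checkerboard_csv",
    "read_quartets_csv",
    "write_quartets_csv",
]

# Numerical policy for the Loewe root search: absolute tolerance on the
# response scale (percent of control), well below assay noise.
LOEWE_TOL = 1e-6
LOEWE_MAX_ITER = 200

# Hill-fit search box; ec50 bounds are relative to the dosed range.
HILL_SLOPE_BOUNDS = (0.1, 10.0)
HILL_EC50_RANGE_FACTOR = 100.0
HILL_MULTISTART = 3

# A curve whose total effect |e0 - einf| is below this is treated as flat
# (inactive agent) by the Loewe reference.
FLAT_EFFECT_EPS = 1e-9


class InvalidInputError(ValueError):
    """Raised when inputs violate an operation's preconditions."""


class DegenerateFitError(RuntimeError):
    """Hill fit failed to converge or the data carry no dose response.

    Carries ``fallback``, a flat curve with e0 = einf = mean response, so
    callers screening inactive agents can proceed deliberately.
    """

    def __init__(self, message: str, fallback: "HillCurve"):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class HillCurve:
    """Fitted 4-parameter sigmoidal dose-response model for one (drug, cell line).

    response(c) = einf + (e0 - einf) * ec50**h / (ec50**h + c**h)

    Parameters
    ----------
    e0 : response at zero dose (% of control), typically ~100.
    einf : asymptotic response at infinite dose (% of control).
    ec50 : half-effect concentration, uM, > 0.
    h : Hill slope, > 0.
    """

    e0: float
    einf: float
    ec50: float
    h: float

    def __post_init__(self):
        if not (self.ec50 > 0):
            raise InvalidInputError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.h > 0):
            raise InvalidInputError(f"Hill slope must be > 0, got {self.h}")

    @property
    def is_flat(self) -> bool:
        return abs(self.e0 - self.einf) < FLAT_EFFECT_EPS

    def response(self, dose):
        return hill_response(self, dose)


@dataclass(frozen=True)
class Checkerboard:
    """Measured 4x4 combination block at nonzero doses (replicate-averaged)."""

    drug_a_doses: np.ndarray  # 4 strictly ascending nonzero uM concentrations
    drug_b_doses: np.ndarray
    response: np.ndarray  # 4x4, rows follow drug_a_doses, cols drug_b_doses
    replicate_count: int = 1

    def __post_init__(self):
        a = np.asarray(self.drug_a_doses, dtype=float)
        b = np.asarray(self.drug_b_doses, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "drug_a_doses", a)
        object.__setattr__(self, "drug_b_doses", b)
        object.__setattr__(self, "response", r)
        for name, d in (("drug_a_doses", a), ("drug_b_doses", b)):
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise InvalidInputError(
                    f"{name} must be strictly positive and ascending, got {d}"
                )
        if r.shape != (len(a), len(b)):
            raise InvalidInputError(
                f"response shape {r.shape} does not match dose ladders "
                f"({len(a)}, {len(b)})"
            )
        if self.replicate_count < 1:
            raise InvalidInputError("replicate_count must be positive")


@dataclass(frozen=True)
class DoseSurface:
    """5x5 response surface; first dose on each axis is zero."""

    drug_a_doses: np.ndarray
    drug_b_doses: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.drug_a_doses, dtype=float)
        b = np.asarray(self.drug_b_doses, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "drug_a_doses", a)
        object.__setattr__(self, "drug_b_doses", b)
        object.__setattr__(self, "response", r)
        for name, d in (("drug_a_doses", a), ("drug_b_doses", b)):
            if d[0] != 0 or np.any(np.diff(d) <= 0):
                raise InvalidInputError(
                    f"{name} must start at 0 and ascend strictly, got {d}"
                )
        if r.shape != (len(a), len(b)):
            raise InvalidInputError(
                f"response shape {r.shape} does not match dose ladders"
            )


@dataclass(frozen=True)
class SynergyQuartet:
    """(drug A, drug B, cell line, Loewe synergy score); the pair is unordered."""

    drug_a: str
    drug_b: str
    cell_line: str
    score: float

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise InvalidInputError(f"self-pair {self.drug_a!r} is not a combination")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical unordered pair key."""
        return tuple(sorted((self.drug_a, self.drug_b)))


# ---------------------------------------------------------------------------
# Hill model
# ---------------------------------------------------------------------------

def hill_response(curve: HillCurve, dose):
    """Evaluate the Hill model at one or more doses (uM); returns % of control."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise InvalidInputError(f"dose must be >= 0, got {dose}")
    # fraction of baseline effect remaining: 1 / (1 + (c/ec50)^h), exact at 0
    with np.errstate(divide="ignore"):
        frac = 1.0 / (1.0 + (dose / curve.ec50) ** curve.h)
    out = curve.einf + (curve.e0 - curve.einf) * frac
    return float(out) if out.ndim == 0 else out


def inverse_hill(curve: HillCurve, effect: float) -> float:
    """Dose producing ``effect``; +inf beyond einf, 0 at e0, nan for flat curves."""
    if curve.is_flat:
        return math.nan
    t = (curve.e0 - effect) / (effect - curve.einf)
    if t <= 0:
        # effect at or beyond one of the asymptotes
        return 0.0 if (effect - curve.e0) * (curve.einf - curve.e0) <= 0 else math.inf
    return curve.ec50 * t ** (1.0 / curve.h)


def _hill_vec(params, doses):
    e0, einf, log_ec50, h = params
    ec50 = math.exp(log_ec50)
    return einf + (e0 - einf) / (1.0 + (doses / ec50) ** h)


def fit_hill(doses, responses, *, rng=None):
    """Least-squares fit of the 4-parameter Hill model to a single-agent screen.

    Parameters
    ----------
    doses : sequence of >= 4 nonnegative concentrations (uM); at least 4 must
        be distinct and nonzero.
    responses : array-like, either one response per dose or a replicate x dose
        matrix (% of control).  Replicates are averaged per dose before
        fitting.
    rng : optional ``numpy.random.Generator`` for multi-start perturbations.

    Returns
    -------
    (HillCurve, float)
        The fitted curve and the root-mean-square residual of the fit.

    Raises
    ------
    InvalidInputError
        Fewer than 4 distinct doses, or non-finite responses.
    DegenerateFitError
        No dose response in the data or no converged fit; carries a flat
        fallback curve with e0 = einf = mean response.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if responses.shape[-1] != doses.size:
        responses = responses.T
    if not np.all(np.isfinite(responses)):
        raise InvalidInputError("responses contain non-finite values")
    if np.any(doses < 0):
        raise InvalidInputError("doses must be nonnegative")
    mean_resp = responses.mean(axis=0)

    # collapse duplicate doses
    uniq, inv = np.unique(doses, return_inverse=True)
    resp = np.zeros_like(uniq)
    for i in range(uniq.size):
        resp[i] = mean_resp[inv == i].mean()
    nz = uniq > 0
    if np.count_nonzero(nz) < 4:
        raise InvalidInputError(
            f"need at least 4 distinct nonzero doses, got {np.count_nonzero(nz)}"
        )

    flat = HillCurve(
        e0=float(resp.mean()), einf=float(resp.mean()), ec50=float(np.median(uniq[nz])), h=1.0
    )
    if np.ptp(resp) < 1e-12:
        raise DegenerateFitError("no dose response (constant readout)", flat)

    d_nz = uniq[nz]
    lo_ec50 = d_nz.min() / HILL_EC50_RANGE_FACTOR
    hi_ec50 = d_nz.max() * HILL_EC50_RANGE_FACTOR
    # extreme-dose responses seed the asymptotes; geometric-mean dose seeds ec50
    e0_init = resp[0] if uniq[0] == 0 else resp[nz][0]
    einf_init = resp[-1]
    x0 = np.array(
        [e0_init, einf_init, math.log(math.exp(np.mean(np.log(d_nz)))), 1.0]
    )
    lb = np.array([-np.inf, -np.inf, math.log(lo_ec50), HILL_SLOPE_BOUNDS[0]])
    ub = np.array([np.inf, np.inf, math.log(hi_ec50), HILL_SLOPE_BOUNDS[1]])

    if rng is None:
        rng = np.random.default_rng(0)
    best = None
    starts = [x0]
    for _ in range(HILL_MULTISTART - 1):
        jit = x0.copy()
        jit[2] += rng.uniform(-1.5, 1.5)
        jit[3] = np.clip(x0[3] * rng.uniform(0.5, 2.0), *HILL_SLOPE_BOUNDS)
        starts.append(jit)
    for start in starts:
        try:
            sol = least_squares(
                lambda p: _hill_vec(p, uniq) - resp,
                np.clip(start, lb, ub),
                bounds=(lb, ub),
                method="trf",
            )
        except Exception:  # noqa: BLE001 - optimizer failure routes to fallback
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < best.cost + 1e-15:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise DegenerateFitError("Hill fit did not converge", flat)
    e0, einf, log_ec50, h = best.x
    curve = HillCurve(e0=float(e0), einf=float(einf), ec50=float(math.exp(log_ec50)), h=float(h))
    rmse = float(np.sqrt(2 * best.cost / uniq.size))
    return curve, rmse


# ---------------------------------------------------------------------------
# Loewe additivity
# ---------------------------------------------------------------------------

def _hsa(resp_a: float, resp_b: float, decreasing: bool) -> float:
    """Highest-single-agent response: the stronger of the two effects."""
    return min(resp_a, resp_b) if decreasing else max(resp_a, resp_b)


def loewe_reference(
    dose_a: float,
    dose_b: float,
    curve_a: HillCurve,
    curve_b: HillCurve,
    *,
    tol: float = LOEWE_TOL,
) -> float:
    """Expected % of control at (dose_a, dose_b) under Loewe additivity.

    Solves ``dose_a / A(E) + dose_b / B(E) = 1`` for the response E by
    bisection over the overlap of the two curves' attainable response
    ranges.  When no solution exists in the overlap (one agent cannot reach
    the other's effect level) the result is clipped to the nearest
    attainable boundary.  Flat (inactive) curves fall back to the
    highest-single-agent response with a warning; two zero doses return the
    mean baseline.
    """
    if dose_a < 0 or dose_b < 0:
        raise InvalidInputError("doses must be nonnegative")
    if dose_a == 0 and dose_b == 0:
        return 0.5 * (curve_a.e0 + curve_b.e0)
    if dose_a == 0:
        return hill_response(curve_b, dose_b)
    if dose_b == 0:
        return hill_response(curve_a, dose_a)

    if curve_a.is_flat or curve_b.is_flat:
        ref_curve = curve_b if curve_a.is_flat else curve_a
        decreasing = ref_curve.einf < ref_curve.e0
        warnings.warn(
            "flat dose-response curve in Loewe reference; "
            "falling back to highest single agent",
            stacklevel=2,
        )
        return _hsa(
            hill_response(curve_a, dose_a), hill_response(curve_b, dose_b), decreasing
        )

    dec_a, dec_b = curve_a.einf < curve_a.e0, curve_b.einf < curve_b.e0
    if dec_a != dec_b:
        raise InvalidInputError("curves must be monotone in the same direction")
    decreasing = dec_a

    # attainable open response interval of each curve, oriented (low, high)
    if decreasing:
        lo = max(curve_a.einf, curve_b.einf)
        hi = min(curve_a.e0, curve_b.e0)
    else:
        lo = max(curve_a.e0, curve_b.e0)
        hi = min(curve_a.einf, curve_b.einf)
    if not lo < hi:
        # no overlap at all: one curve lives entirely beyond the other
        return lo if decreasing else hi

    def index_sum(effect: float) -> float:
        a_need = inverse_hill(curve_a, effect)
        b_need = inverse_hill(curve_b, effect)
        total = 0.0
        for dose, need in ((dose_a, a_need), (dose_b, b_need)):
            if need == 0:
                return math.inf
            if math.isfinite(need):
                total += dose / need
        return total

    eps = max(1e-12, (hi - lo) * 1e-12)
    f_lo, f_hi = index_sum(lo + eps), index_sum(hi - eps)
    # For decreasing curves the index sum falls as E moves from the
    # no-effect end toward the max-effect end; clip when it never crosses 1.
    near, far = (hi, lo) if decreasing else (lo, hi)
    f_near, f_far = (f_hi, f_lo) if decreasing else (f_lo, f_hi)
    if f_near <= 1.0:  # combination weaker than the weakest attainable effect
        return near
    if f_far >= 1.0:  # combination exceeds what the overlap can express
        return far
    a, b = lo, hi
    for _ in range(LOEWE_MAX_ITER):
        mid = 0.5 * (a + b)
        if index_sum(mid) > 1.0:
            # effect deeper than mid: move toward the max-effect end
            if decreasing:
                b = mid
            else:
                a = mid
        else:
            if decreasing:
                a = mid
            else:
                b = mid
        if b - a < tol:
            break
    return 0.5 * (a + b)


def assemble_surface(
    board: Checkerboard, curve_a: HillCurve, curve_b: HillCurve
) -> DoseSurface:
    """Complete a measured 4x4 checkerboard into a 5x5 surface.

    The interior block is the (replicate-averaged) measurement; the zero-dose
    row/column are the fitted single-agent responses at the board's doses;
    the zero-zero corner is the mean of the two fitted baselines.
    """
    for name, d, curve in (
        ("drug_a", board.drug_a_doses, curve_a),
        ("drug_b", board.drug_b_doses, curve_b),
    ):
        if d.max() > curve.ec50 * HILL_EC50_RANGE_FACTOR:
            warnings.warn(
                f"{name} checkerboard doses extrapolate far beyond the fitted "
                "curve's range",
                stacklevel=2,
            )
    a_doses = np.concatenate(([0.0], board.drug_a_doses))
    b_doses = np.concatenate(([0.0], board.drug_b_doses))
    resp = np.empty((5, 5))
    resp[0, 0] = 0.5 * (curve_a.e0 + curve_b.e0)
    resp[1:, 0] = hill_response(curve_a, board.drug_a_doses)
    resp[0, 1:] = hill_response(curve_b, board.drug_b_doses)
    resp[1:, 1:] = board.response
    return DoseSurface(drug_a_doses=a_doses, drug_b_doses=b_doses, response=resp)


def synergy_score(
    surface: DoseSurface,
    curve_a: HillCurve,
    curve_b: HillCurve,
    aggregation: str = "sum",
) -> float:
    """Loewe synergy score of a surface: aggregated (reference - observed).

    Only the 16 nonzero-dose wells contribute.  Positive deviations mean the
    observed growth is below the additive expectation (synergy).  The default
    aggregation is the sum over wells, in %-of-control points; ``mean`` is
    available.
    """
    if aggregation not in ("sum", "mean"):
        raise InvalidInputError(f"unknown aggregation {aggregation!r}")
    devs = []
    for i, da in enumerate(surface.drug_a_doses[1:], start=1):
        for j, db in enumerate(surface.drug_b_doses[1:], start=1):
            ref = loewe_reference(da, db, curve_a, curve_b)
            devs.append(ref - surface.response[i, j])
    total = float(np.sum(devs))
    return total if aggregation == "sum" else total / len(devs)


# ---------------------------------------------------------------------------
# Screen-level scoring and CSV interfaces
# ---------------------------------------------------------------------------

SINGLE_AGENT_COLUMNS = ["drug", "cell_line", "dose_uM", "response_pct", "replicate"]
CHECKERBOARD_COLUMNS = [
    "drug_a", "drug_b", "cell_line", "dose_a_uM", "dose_b_uM", "response_pct", "replicate",
]
QUARTET_COLUMNS = ["drug_a", "drug_b", "cell_line", "synergy"]


def _require_columns(df: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} is missing columns {missing}")


def read_single_agent_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, SINGLE_AGENT_COLUMNS, "single-agent table")
    return df


def read_checkerboard_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty and not set(CHECKERBOARD_COLUMNS) <= set(df.columns):
        return pd.DataFrame(columns=CHECKERBOARD_COLUMNS)
    _require_columns(df, CHECKERBOARD_COLUMNS, "checkerboard table")
    return df


def read_quartets_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, QUARTET_COLUMNS, "quartet table")
    return df


def write_quartets_csv(quartets: pd.DataFrame, path):
    quartets.to_csv(path, index=False, columns=QUARTET_COLUMNS)


def fit_single_agents(single_agent: pd.DataFrame) -> dict[tuple[str, str], HillCurve]:
    """Fit one Hill curve per (drug, cell line), keyed by that tuple.

    Degenerate fits (inactive agents) are replaced by their flat fallback
    curve with a warning rather than aborting the screen.
    """
    curves: dict[tuple[str, str], HillCurve] = {}
    for (drug, cell), grp in single_agent.groupby(["drug", "cell_line"], sort=True):
        pivot = grp.pivot_table(
            index="replicate", columns="dose_uM", values="response_pct", aggfunc="mean"
        )
        try:
            curve, _ = fit_hill(pivot.columns.to_numpy(float), pivot.to_numpy())
        except DegenerateFitError as err:
            warnings.warn(
                f"degenerate single-agent fit for ({drug}, {cell}); "
                "using flat fallback",
                stacklevel=2,
            )
            curve = err.fallback
        curves[(drug, cell)] = curve
    return curves


def score_screen(
    single_agent: pd.DataFrame,
    checkerboards: pd.DataFrame,
    aggregation: str = "sum",
) -> pd.DataFrame:
    """Score every (drug pair, cell line) checkerboard in a screen.

    Replicates are averaged per well before scoring.  Returns a quartet
    table with columns ``drug_a, drug_b, cell_line, synergy``.
    """
    if checkerboards.empty:
        return pd.DataFrame(columns=QUARTET_COLUMNS)
    curves = fit_single_agents(single_agent)
    records = []
    for (da, db, cell), grp in checkerboards.groupby(
        ["drug_a", "drug_b", "cell_line"], sort=True
    ):
        for drug in (da, db):
            if (drug, cell) not in curves:
                raise InvalidInputError(
                    f"no single-agent data for drug {drug!r} on cell line "
                    f"{cell!r} required by pair ({da}, {db})"
                )
        well = grp.pivot_table(
            index="dose_a_uM", columns="dose_b_uM", values="response_pct", aggfunc="mean"
        ).sort_index().sort_index(axis=1)
        board = Checkerboard(
            drug_a_doses=well.index.to_numpy(float),
            drug_b_doses=well.columns.to_numpy(float),
            response=well.to_numpy(),
            replicate_count=int(grp["replicate"].nunique()),
        )
        ca, cb = curves[(da, cell)], curves[(db, cell)]
        surface = assemble_surface(board, ca, cb)
        records.append(
            {
                "drug_a": da,
                "drug_b": db,
                "cell_line": cell,
                "synergy": synergy_score(surface, ca, cb, aggregation=aggregation),
            }
        )
    return pd.DataFrame.from_records(records, columns=QUARTET_COLUMNS)
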