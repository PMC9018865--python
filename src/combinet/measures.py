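"""Drug-potency read-outs for dose-response series.

A monotherapy screen reports cell viability at a handful of doses.  Several
scalar summaries of such a series are in routine use — the median viability,
the (normalised) area under the viability curve, absolute and relative IC50
from a four-parameter logistic fit, and the relative-inhibition percentage.
This module computes all of them, plus the nonparametric association
statistics (MIC / MAS / MEV) used to decide which summary should carry the
edge weight of the drug–sample bipartite network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "FourPLFit",
    "PotencyMeasures",
    "MeasureComparison",
    "median_viability",
    "fit_4pl",
    "ic50",
    "auc",
    "relative_inhibition",
    "compute_measures",
    "mine_statistics",
    "compare_measures",
]

MEASURE_NAMES = ("median_viability", "auc", "ic50_abs", "ic50_rel", "ri")

# viability values outside this window are treated as corrupt and clipped
VIABILITY_CLIP = (0.0, 10.0)


class InvalidSeriesError(ValueError):
    """Raised when a dose-response series violates its invariants."""


@dataclass(frozen=True)
class DoseResponseSeries:
    """One drug × sample viability curve.

    Doses are concentrations in nM, strictly increasing; responses are
    viability fractions on the control scale (1 = untreated).  Replicates
    are expected to have been aggregated (mean per dose) before
    construction; :func:`aggregate_replicates` does that for long tables.
    """

    drug_id: str
    sample_id: str
    doses: np.ndarray
    responses: np.ndarray
    replicate_id: str | None = None

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        if doses.size != responses.size:
            raise InvalidSeriesError("doses and responses differ in length")
        if doses.size < 2:
            raise InvalidSeriesError("a series needs at least 2 doses")
        if np.any(doses <= 0):
            raise InvalidSeriesError("doses must be positive (nM)")
        if np.any(np.diff(doses) <= 0):
            raise InvalidSeriesError("doses must be strictly increasing")
        if not (np.all(np.isfinite(doses)) and np.all(np.isfinite(responses))):
            raise InvalidSeriesError("non-finite dose or response")
        n_clipped = int(np.sum((responses < VIABILITY_CLIP[0]) | (responses > VIABILITY_CLIP[1])))
        if n_clipped:
            warnings.warn(f"{n_clipped} responses outside {VIABILITY_CLIP} clipped")
            responses = np.clip(responses, *VIABILITY_CLIP)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)


def aggregate_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Mean response per (drug, sample, dose) from a long replicate table."""
    return (
        df.groupby(["drug_id", "sample_id", "dose_nM"], as_index=False)["response"]
        .mean()
        .sort_values(["drug_id", "sample_id", "dose_nM"])
        .reset_index(drop=True)
    )


def series_from_long(df: pd.DataFrame) -> list[DoseResponseSeries]:
    """Build one series per drug × sample from a long-format response table."""
    agg = aggregate_replicates(df)
    out = []
    for (drug, sample), grp in agg.groupby(["drug_id", "sample_id"], sort=True):
        out.append(
            DoseResponseSeries(
                drug_id=str(drug),
                sample_id=str(sample),
                doses=grp["dose_nM"].to_numpy(),
                responses=grp["response"].to_numpy(),
            )
        )
    return out


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit y = lower + (upper-lower)/(1+(x/ec50)^slope).

    With slope > 0 the curve decreases with dose (inhibition).  ``dose_range``
    records the tested range so downstream IC50 extraction can refuse to
    extrapolate absurdly far.
    """

    upper: float
    lower: float
    ec50: float
    slope: float
    dose_range: tuple[float, float]
    converged: bool = True
    degenerate: bool = False
    inhibitory: bool = True
    fallback_points: tuple | None = None  # (doses, responses) for interp fallback

    def predict(self, doses: np.ndarray | float) -> np.ndarray | float:
        doses = np.asarray(doses, dtype=float)
        if self.fallback_points is not None:
            xs, ys = self.fallback_points
            return np.interp(np.log10(doses), np.log10(xs), ys)
        return four_pl(doses, self.upper, self.lower, self.ec50, self.slope)


def four_pl(x, upper, lower, ec50, slope):
    """Evaluate the 4PL curve on dose scale (computed via log-dose for stability)."""
    x = np.asarray(x, dtype=float)
    t = slope * (np.log10(x) - np.log10(ec50))
    t = np.clip(t, -500, 500)
    return lower + (upper - lower) / (1.0 + 10.0**t)


def median_viability(series: DoseResponseSeries) -> float:
    """Middle order statistic of the responses (mean of middle pair when even)."""
    if series.responses.size == 0:
        raise InvalidSeriesError("empty responses")
    return float(np.median(series.responses))


def fit_4pl(series: DoseResponseSeries) -> FourPLFit:
    """Least-squares 4PL fit on log-dose; never raises on bad data.

    Fewer than 4 distinct doses → slope fixed at 1.  A near-constant series is
    returned as a degenerate flat fit.  Non-convergence falls back to monotone
    interpolation through the data, flagged via ``converged=False``.
    """
    x = series.doses
    y = series.responses
    dose_range = (float(x[0]), float(x[-1]))
    span = float(np.max(y) - np.min(y))
    if span < 1e-9:
        return FourPLFit(
            upper=float(y[0]), lower=float(y[0]),
            ec50=float(np.sqrt(x[0] * x[-1])), slope=1.0,
            dose_range=dose_range, converged=True, degenerate=True,
            inhibitory=False,
        )

    logx = np.log10(x)
    mid = 10 ** np.mean(logx)
    decreasing = y[-1] <= y[0]
    p0_slope = 1.0 if decreasing else -1.0
    lo_bound = [min(y) - 0.5, min(y) - 0.5, x[0] / 1e3, -20.0]
    hi_bound = [max(y) + 0.5, max(y) + 0.5, x[-1] * 1e3, 20.0]

    full = len(np.unique(x)) >= 4
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if full:
                popt, _ = optimize.curve_fit(
                    four_pl, x, y,
                    p0=[max(y), min(y), mid, p0_slope],
                    bounds=(lo_bound, hi_bound), maxfev=20000,
                )
                upper, lower, ec50, slope = popt
            else:
                def fixed_slope(xv, u, l, e):
                    return four_pl(xv, u, l, e, p0_slope)

                popt, _ = optimize.curve_fit(
                    fixed_slope, x, y,
                    p0=[max(y), min(y), mid],
                    bounds=(lo_bound[:3], hi_bound[:3]), maxfev=20000,
                )
                upper, lower, ec50 = popt
                slope = p0_slope
    except (RuntimeError, ValueError):
        order = np.argsort(x)
        return FourPLFit(
            upper=float(np.max(y)), lower=float(np.min(y)),
            ec50=float(mid), slope=p0_slope, dose_range=dose_range,
            converged=False, degenerate=False, inhibitory=decreasing,
            fallback_points=(tuple(x[order]), tuple(y[order])),
        )

    # canonicalise so upper >= lower (flip slope sign accordingly)
    if upper < lower:
        upper, lower, slope = lower, upper, -slope
    return FourPLFit(
        upper=float(upper), lower=float(lower), ec50=float(ec50),
        slope=float(slope), dose_range=dose_range, converged=True,
        degenerate=False, inhibitory=bool(slope > 0),
    )


def ic50(fit: FourPLFit, mode: str = "relative") -> float:
    """IC50 from a 4PL fit; NaN when undefined.

    relative: dose at the midpoint of the plateaus (= EC50).
    absolute: dose where fitted viability crosses 0.5 on the control scale;
    undefined when the crossing lies beyond 10× the tested dose range or the
    curve never reaches 0.5.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown IC50 mode: {mode!r}")
    if fit.degenerate or fit.fallback_points is not None:
        return float("nan")
    if mode == "relative":
        return fit.ec50
    lo, hi = (fit.lower, fit.upper)
    if not (lo < 0.5 < hi) or fit.slope == 0:
        return float("nan")
    # solve lower + (upper-lower)/(1+(d/ec50)^s) = 0.5
    ratio = (fit.upper - 0.5) / (0.5 - fit.lower)
    d = fit.ec50 * ratio ** (1.0 / fit.slope)
    dmin, dmax = fit.dose_range
    if not (dmin / 10.0 <= d <= dmax * 10.0):
        return float("nan")
    return float(d)


def auc(series: DoseResponseSeries, on_fit: bool = False, fit: FourPLFit | None = None) -> float:
    """Normalised area under viability vs log10(dose).

    Divided by the log-dose span, so constant viability v yields exactly v and
    every series is summarised on the viability scale regardless of its tested
    range.  ``on_fit`` integrates the 4PL curve sampled at 100 points instead
    of the raw data.
    """
    if series.doses.size < 2:
        raise InvalidSeriesError("AUC needs at least 2 doses")
    logx = np.log10(series.doses)
    span = logx[-1] - logx[0]
    if on_fit:
        f = fit if fit is not None else fit_4pl(series)
        grid = np.linspace(logx[0], logx[-1], 100)
        yv = f.predict(10.0**grid)
        return float(np.trapezoid(yv, grid) / span)
    return float(np.trapezoid(series.responses, logx) / span)


def relative_inhibition(series: DoseResponseSeries) -> float:
    """Percent area under the inhibition curve: 100 × (1 − normalised AUC)."""
    return 100.0 * (1.0 - auc(series))


@dataclass(frozen=True)
class PotencyMeasures:
    drug_id: str
    sample_id: str
    median_viability: float
    auc: float
    ic50_abs: float
    ic50_rel: float
    ri: float


def compute_measures(series: DoseResponseSeries, with_fit: bool = True) -> PotencyMeasures:
    """All five potency read-outs for one series (IC50s NaN when with_fit=False)."""
    if with_fit:
        f = fit_4pl(series)
        abs_ic, rel_ic = ic50(f, "absolute"), ic50(f, "relative")
    else:
        abs_ic = rel_ic = float("nan")
    return PotencyMeasures(
        drug_id=series.drug_id,
        sample_id=series.sample_id,
        median_viability=median_viability(series),
        auc=auc(series),
        ic50_abs=abs_ic,
        ic50_rel=rel_ic,
        ri=relative_inhibition(series),
    )


def measures_table(series_list: Sequence[DoseResponseSeries], with_fit: bool = True) -> pd.DataFrame:
    rows = [compute_measures(s, with_fit=with_fit) for s in series_list]
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# MINE-family association statistics
# ---------------------------------------------------------------------------

def _equal_freq_bins(v: np.ndarray, k: int) -> np.ndarray:
    """Assign ranks of v to k roughly equal-frequency bins."""
    ranks = stats.rankdata(v, method="average")
    return np.minimum((ranks - 1) * k // len(v), k - 1).astype(int)


def _mutual_information_bits(bx: np.ndarray, by: np.ndarray, kx: int, ky: int) -> float:
    joint = np.zeros((kx, ky))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))


def mine_statistics(x: Sequence[float], y: Sequence[float], max_bins: int = 15):
    """Approximate MIC, MAS and MEV for a pair of value vectors.

    A characteristic matrix M[a, b] of normalised mutual information is built
    over equal-frequency grids with a × b ≤ B(n) = n^0.6 cells (axes capped at
    ``max_bins`` bins).  MIC is its maximum, MAS the largest asymmetry
    |M[a,b] − M[b,a]| and MEV the maximum over grids with 2 rows or columns —
    hence MEV ≤ MIC by construction.  Constant input yields all zeros.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("mine_statistics needs two equal-length vectors, n >= 10")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, 0.0

    n = x.size
    B = max(4.0, n**0.6)
    kmax = min(max_bins, int(B // 2))
    M: dict[tuple[int, int], float] = {}
    bins_x = {k: _equal_freq_bins(x, k) for k in range(2, kmax + 1)}
    bins_y = {k: _equal_freq_bins(y, k) for k in range(2, kmax + 1)}
    for a in range(2, kmax + 1):
        for b in range(2, kmax + 1):
            if a * b > B:
                continue
            mi = _mutual_information_bits(bins_x[a], bins_y[b], a, b)
            M[(a, b)] = mi / np.log2(min(a, b))
    if not M:
        return 0.0, 0.0, 0.0
    mic = max(M.values())
    mev = max(v for (a, b), v in M.items() if a == 2 or b == 2)
    mas = max(abs(M[(a, b)] - M[(b, a)]) for (a, b) in M if (b, a) in M)
    return float(min(mic, 1.0)), float(min(mas, 1.0)), float(min(mev, 1.0))


@dataclass
class MeasureComparison:
    """Pairwise diagnostics over the five potency measures."""

    pearson: pd.DataFrame
    mic: pd.DataFrame
    mas: pd.DataFrame
    mev: pd.DataFrame
    skewness: pd.Series
    n_rows: int = 0
    measures: tuple = MEASURE_NAMES


def compare_measures(table: pd.DataFrame, measures: Sequence[str] = MEASURE_NAMES) -> MeasureComparison:
    """Pearson r, MIC/MAS/MEV and skewness across potency measures.

    Rows with missing values are dropped pairwise for Pearson and per-pair for
    the MINE statistics; skewness uses each column's non-missing values.
    """
    cols = [m for m in measures if m in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least two measure columns")
    sub = table[cols]
    if len(sub.dropna()) < 3:
        raise ValueError("fewer than 3 complete rows")
    pearson = sub.corr(method="pearson")
    mic = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    mas = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    mev = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        pair = sub[[a, b]].dropna()
        if len(pair) < 10:
            vals = (np.nan, np.nan, np.nan)
        else:
            vals = mine_statistics(pair[a].to_numpy(), pair[b].to_numpy())
        mic.loc[a, b] = mic.loc[b, a] = vals[0]
        mas.loc[a, b] = mas.loc[b, a] = vals[1]
        mev.loc[a, b] = mev.loc[b, a] = vals[2]
    skewness = sub.apply(lambda c: stats.skew(c.dropna()))
    return MeasureComparison(
        pearson=pearson, mic=mic, mas=mas, mev=mev,
        skewness=skewness, n_rows=len(sub.dropna()), measures=tuple(cols),
    )
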