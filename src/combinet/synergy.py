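"""Reference-model synergy scoring of drug-pair dose-response matrices.

A combination screen measures % inhibition over a dose grid whose first row
and column are the monotherapies.  Each reference model predicts the
non-interactive expectation y_e at every dose pair; the synergy surface is
δ = observed − expected (percentage points), summarised by its mean over the
positive-dose grid:

* HSA     — y_e = max(y1, y2).
* Bliss   — probabilistic independence, y_e = y1 + y2 − y1·y2 on fractions.
* Loewe   — dose additivity, y_e solves d1/D1(y) + d2/D2(y) = 1 via the
            inverted monotherapy logistic fits.
* ZIP     — departure of partner-conditioned logistic refits from the
            Bliss-type reference of the fitted monotherapies.

All effects are handled internally as inhibition fractions; viability inputs
should be converted as 1 − viability before construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "CombinationMatrix",
    "SynergySummary",
    "hsa_expected",
    "bliss_expected",
    "loewe_expected",
    "zip_delta",
    "score_combination",
]

MODELS = ("zip", "bliss", "loewe", "hsa")


@dataclass
class CombinationMatrix:
    """Dose-grid % inhibition surface for one drug pair on one sample.

    ``doses_a`` index the rows and include 0 first; likewise ``doses_b`` for
    columns.  Cell (0, 0) is the untreated control and must be 0 by
    definition of the inhibition scale.
    """

    drug_a: str
    drug_b: str
    sample_id: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray  # percent

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValueError("dose grids must start at 0 (monotherapy margins)")
        if np.any(np.diff(self.doses_a) <= 0) or np.any(np.diff(self.doses_b) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.inhibition.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("inhibition grid shape mismatch")
        if abs(self.inhibition[0, 0]) > 1e-9:
            raise ValueError("inhibition at (0, 0) must be 0")

    def monotherapy_a(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_a[1:], self.inhibition[1:, 0]

    def monotherapy_b(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_b[1:], self.inhibition[0, 1:]

    def transposed(self) -> "CombinationMatrix":
        return CombinationMatrix(
            drug_a=self.drug_b, drug_b=self.drug_a, sample_id=self.sample_id,
            doses_a=self.doses_b.copy(), doses_b=self.doses_a.copy(),
            inhibition=self.inhibition.T.copy(),
        )


@dataclass(frozen=True)
class HillFit:
    """Rising logistic on the inhibition-fraction scale.

    y(d) = emin + (emax − emin) / (1 + (ec50/d)^slope), slope > 0 for a
    standard dose-inhibition curve; y(0) = emin.
    """

    emin: float
    emax: float
    ec50: float
    slope: float
    converged: bool = True

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore"):
            t = self.slope * (np.log(self.ec50) - np.log(d))
        t = np.clip(t, -500, 500)
        y = self.emin + (self.emax - self.emin) / (1.0 + np.exp(t))
        return np.where(d == 0, self.emin, y)

    def inverse(self, y: float) -> float:
        """Dose producing effect y; inf/0 outside the open (emin, emax) range."""
        if not (min(self.emin, self.emax) < y < max(self.emin, self.emax)):
            return float("inf") if y >= max(self.emin, self.emax) else 0.0
        return float(self.ec50 * ((y - self.emin) / (self.emax - y)) ** (1.0 / self.slope))


def fit_hill(doses: np.ndarray, effects: np.ndarray, emin_fixed: float | None = None) -> HillFit:
    """Least-squares logistic fit of inhibition fractions vs dose."""
    doses = np.asarray(doses, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if np.ptp(effects) < 1e-9:
        return HillFit(float(effects[0]), float(effects[0]),
                       float(np.sqrt(doses[0] * doses[-1])), 1.0, converged=True)
    mid = float(np.exp(np.mean(np.log(doses))))
    lo = [min(effects) - 0.5, min(effects) - 0.5, doses[0] / 1e3, 0.05]
    hi = [max(effects) + 0.5, max(effects) + 0.5, doses[-1] * 1e3, 20.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if emin_fixed is None:
                def f(d, emin, emax, ec50, slope):
                    return HillFit(emin, emax, ec50, slope).predict(d)

                p0 = [float(effects[0]), float(effects[-1]), mid, 1.0]
                popt, _ = optimize.curve_fit(f, doses, effects, p0=p0,
                                             bounds=(lo, hi), maxfev=20000)
                return HillFit(*map(float, popt))
            else:
                def f(d, emax, ec50, slope):
                    return HillFit(emin_fixed, emax, ec50, slope).predict(d)

                p0 = [float(effects[-1]), mid, 1.0]
                popt, _ = optimize.curve_fit(f, doses, effects, p0=p0,
                                             bounds=(lo[1:], hi[1:]), maxfev=20000)
                return HillFit(emin_fixed, *map(float, popt))
    except (RuntimeError, ValueError):
        return HillFit(float(effects[0]), float(effects[-1]), mid, 1.0, converged=False)


def hsa_expected(y1: float, y2: float) -> float:
    """Highest single agent: the larger monotherapy effect."""
    return max(y1, y2)


def bliss_expected(y1: float, y2: float) -> float:
    """Bliss independence y1 + y2 − y1·y2 on the fraction scale.

    Inputs are clipped to [0, 1] for the independence product, as the
    probabilistic interpretation requires.
    """
    a = min(max(y1, 0.0), 1.0)
    b = min(max(y2, 0.0), 1.0)
    return a + b - a * b


def loewe_expected(d1: float, d2: float, fit1: HillFit, fit2: HillFit,
                   tol: float = 1e-6) -> tuple[float, bool]:
    """Dose-additive expected effect; returns (effect fraction, clamped flag).

    Solves d1/D1(y) + d2/D2(y) = 1 by bisection on y over the effect range
    achievable by both drugs.  When no root exists the nearest achievable
    effect is returned with ``clamped=True``.
    """
    if d1 == 0 and d2 == 0:
        return min(fit1.emin, fit2.emin), False
    if d2 == 0:
        return float(fit1.predict(d1)), False
    if d1 == 0:
        return float(fit2.predict(d2)), False
    lo = max(min(fit1.emin, fit1.emax), min(fit2.emin, fit2.emax))
    hi = min(max(fit1.emin, fit1.emax), max(fit2.emin, fit2.emax))
    if not (hi > lo):
        return float("nan"), True

    def g(y):
        D1, D2 = fit1.inverse(y), fit2.inverse(y)
        if np.isinf(D1) or np.isinf(D2):
            return -1.0
        if D1 == 0 or D2 == 0:
            return np.inf
        return d1 / D1 + d2 / D2 - 1.0

    eps = (hi - lo) * 1e-9
    ylo, yhi = lo + eps, hi - eps
    glo, ghi = g(ylo), g(yhi)
    # g is decreasing in y: g(lo) < 0 → doses too small for any achievable
    # effect (clamp low); g(hi) > 0 → doses exceed the top plateau (clamp high)
    if glo < 0:
        return lo, True
    if ghi > 0:
        return hi, True
    while yhi - ylo > tol:
        ym = 0.5 * (ylo + yhi)
        if g(ym) > 0:
            ylo = ym
        else:
            yhi = ym
    return 0.5 * (ylo + yhi), False


def _monotherapy_fits(matrix: CombinationMatrix) -> tuple[HillFit, HillFit]:
    da, ya = matrix.monotherapy_a()
    db, yb = matrix.monotherapy_b()
    return fit_hill(da, ya / 100.0), fit_hill(db, yb / 100.0)


def zip_delta(matrix: CombinationMatrix):
    """ZIP synergy surface (percentage points) over the positive-dose grid.

    The reference is Bliss-type independence of the two fitted monotherapy
    logistics.  The potentiated response at each dose pair averages two
    partner-conditioned logistic refits: for each positive partner dose, the
    conditional series (combination row/column at positive own doses) is
    refitted with a full free-parameter logistic; a failed fit falls back to
    the raw observed values for that row/column (flagged in the diagnostics).
    """
    da, db = matrix.doses_a[1:], matrix.doses_b[1:]
    if da.size < 3 or db.size < 3:
        raise ValueError("ZIP needs at least 3 positive doses per drug")
    fa, fb = _monotherapy_fits(matrix)
    y1 = fa.predict(da)  # fractions
    y2 = fb.predict(db)
    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]

    obs = matrix.inhibition[1:, 1:] / 100.0
    n_fallback = 0
    cond_rows = np.empty_like(obs)  # refit along drug A within each column (fixed b dose)
    for j in range(db.size):
        f = fit_hill(da, obs[:, j])
        if f.converged:
            cond_rows[:, j] = f.predict(da)
        else:
            n_fallback += 1
            cond_rows[:, j] = obs[:, j]
    cond_cols = np.empty_like(obs)
    for i in range(da.size):
        f = fit_hill(db, obs[i, :])
        if f.converged:
            cond_cols[i, :] = f.predict(db)
        else:
            n_fallback += 1
            cond_cols[i, :] = obs[i, :]
    potentiated = 0.5 * (cond_rows + cond_cols)
    delta = (potentiated - expected) * 100.0
    diagnostics = {
        "fit_a": fa, "fit_b": fb,
        "n_fallback_fits": n_fallback,
    }
    return delta, float(delta.mean()), diagnostics


@dataclass
class SynergySummary:
    """Per-model δ surfaces (%) and mean δ for one combination matrix."""

    drug_a: str
    drug_b: str
    sample_id: str
    surfaces: dict[str, np.ndarray]
    means: dict[str, float]
    n_excluded: dict[str, int] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def synergistic(self) -> dict[str, bool]:
        return {m: v > 0 for m, v in self.means.items()}


def score_combination(matrix: CombinationMatrix, models=MODELS) -> SynergySummary:
    """δ = observed − expected per reference model over the positive grid.

    Loewe cells where the dose-equivalence equation has no root in the
    achievable effect range are excluded from the mean (counted in
    ``n_excluded``); ZIP follows :func:`zip_delta`.
    """
    da, db = matrix.doses_a[1:], matrix.doses_b[1:]
    y1 = matrix.inhibition[1:, 0] / 100.0
    y2 = matrix.inhibition[0, 1:] / 100.0
    obs = matrix.inhibition[1:, 1:] / 100.0
    surfaces: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    n_excluded: dict[str, int] = {}
    diagnostics: dict = {}

    for model in models:
        if model == "hsa":
            exp = np.maximum(y1[:, None], np.broadcast_to(y2[None, :], obs.shape))
            delta = (obs - exp) * 100.0
        elif model == "bliss":
            c1 = np.clip(y1, 0, 1)[:, None]
            c2 = np.clip(y2, 0, 1)[None, :]
            exp = c1 + c2 - c1 * c2
            delta = (obs - exp) * 100.0
        elif model == "loewe":
            fa, fb = _monotherapy_fits(matrix)
            delta = np.full_like(obs, np.nan)
            clamped = 0
            for i, d1 in enumerate(da):
                for j, d2 in enumerate(db):
                    ye, clamp = loewe_expected(d1, d2, fa, fb)
                    if np.isnan(ye):
                        clamped += 1
                        continue
                    if clamp:
                        clamped += 1
                        continue
                    delta[i, j] = (obs[i, j] - ye) * 100.0
            n_excluded["loewe"] = clamped
            diagnostics["loewe_fits"] = (fa, fb)
        elif model == "zip":
            delta, _, zdiag = zip_delta(matrix)
            diagnostics["zip"] = zdiag
        else:
            raise ValueError(f"unknown synergy model: {model!r}")
        surfaces[model] = delta
        means[model] = float(np.nanmean(delta))
    return SynergySummary(
        drug_a=matrix.drug_a, drug_b=matrix.drug_b, sample_id=matrix.sample_id,
        surfaces=surfaces, means=means, n_excluded=n_excluded,
        diagnostics=diagnostics,
    )
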