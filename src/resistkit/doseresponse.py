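"""Viability plate processing and four-parameter logistic (4PL) dose-response fitting.

The workflow mirrors a standard CellTiter-Glo growth-inhibition assay:
raw luminescence counts are converted to Tumor cell Growth Inhibition (TGI)
scores by subtracting the mean day-1 baseline signal and normalizing to the
endpoint untreated signal,

    TGI = 1 - (treated - baseline) / (untreated - baseline),

so TGI = 0 means growth indistinguishable from untreated cells and TGI = 1
means growth stasis at the seeding level (values above 1 indicate net cell
kill, values below 0 growth stimulation).  TGI as a function of dose is then
fit with the four-parameter logistic

    TGI(x) = L + (U - L) / (1 + (IC50 / x)^h),

where L and U are the lower/upper asymptotes, h > 0 the Hill slope, and IC50
the inflection concentration (relative IC50).  Curves with no detectable
effect are reported as censored (">top dose") rather than forced to a
numeric IC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DoseLadder",
    "PlateReadout",
    "TGIValue",
    "FourPLFit",
    "FourParamLogistic",
    "build_dilution_ladder",
    "compute_tgi",
    "fit_4pl",
    "predict_4pl",
    "four_pl",
    "format_concentration",
    "InvalidParameterError",
    "DegeneratePlateError",
    "InsufficientDataError",
    "FitFailureError",
]


class InvalidParameterError(ValueError):
    """A parameter violates its documented precondition."""


class DegeneratePlateError(ValueError):
    """The plate's adjusted untreated signal is non-positive."""


class InsufficientDataError(ValueError):
    """Too few distinct doses with finite TGI to fit a curve."""


class FitFailureError(RuntimeError):
    """The 4PL optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


_UNITS = (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12))


def format_concentration(molar: float) -> str:
    """Render a molar concentration with 3 significant figures and a sensible unit.

    >>> format_concentration(152.588e-12)
    '153 pM'
    """
    if molar <= 0 or not np.isfinite(molar):
        raise InvalidParameterError(f"concentration must be positive, got {molar}")
    for unit, scale in _UNITS:
        value = molar / scale
        if value >= 1.0:
            return f"{float(f'{value:.3g}'):g} {unit}"
    return f"{molar / 1e-12:.3g} pM"


@dataclass(frozen=True)
class DoseLadder:
    """A serial-dilution ladder: ``concentrations[i] = top / fold**i``."""

    top: float  # molar
    fold: float  # dilution ratio, > 1 (== any value for a single point)
    n_points: int

    def __post_init__(self):
        if not (self.top > 0):
            raise InvalidParameterError(f"top concentration must be > 0, got {self.top}")
        if self.n_points < 1:
            raise InvalidParameterError(f"n_points must be >= 1, got {self.n_points}")
        if self.n_points > 1 and not (self.fold > 1):
            raise InvalidParameterError(f"dilution fold must be > 1, got {self.fold}")

    @property
    def concentrations(self) -> np.ndarray:
        return self.top / self.fold ** np.arange(self.n_points, dtype=float)

    def display(self) -> list[str]:
        """Concentrations rounded to 3 significant figures for reporting."""
        return [format_concentration(c) for c in self.concentrations]


def build_dilution_ladder(top: float, fold: float, n_points: int) -> DoseLadder:
    """Build a strictly decreasing serial-dilution ladder from ``top``."""
    if n_points == 1 and not (fold > 1):
        # Single point: no dilution performed; still reject nonsense folds.
        if fold <= 0:
            raise InvalidParameterError(f"dilution fold must be positive, got {fold}")
        return DoseLadder(top=top, fold=2.0, n_points=1)
    return DoseLadder(top=top, fold=fold, n_points=n_points)


@dataclass(frozen=True)
class PlateReadout:
    """One plate's raw counts: treated wells plus baseline/untreated controls.

    ``wells`` holds (well_id, drug_id_or_None, dose_molar_or_None, raw_count)
    for treated wells; control counts are kept separately.
    """

    wells: tuple
    baseline_wells: tuple  # (well_id, count)
    untreated_wells: tuple  # (well_id, count)

    def __post_init__(self):
        if len(self.baseline_wells) == 0 or len(self.untreated_wells) == 0:
            raise InvalidParameterError(
                "plate needs at least one baseline and one untreated well"
            )
        for _, count in tuple(self.baseline_wells) + tuple(self.untreated_wells):
            if count < 0:
                raise InvalidParameterError("raw counts must be >= 0")

    @property
    def baseline_mean(self) -> float:
        return float(np.mean([c for _, c in self.baseline_wells]))

    @property
    def untreated_mean(self) -> float:
        return float(np.mean([c for _, c in self.untreated_wells]))


@dataclass(frozen=True)
class TGIValue:
    dose: float | None  # molar
    tgi: float


def compute_tgi(raw_treated: float, plate: PlateReadout, dose: float | None = None) -> TGIValue:
    """Baseline-adjusted growth inhibition for one treated well.

    TGI = 1 - (treated - mean(baseline)) / (untreated - mean(baseline)).
    """
    b = plate.baseline_mean
    u = plate.untreated_mean
    denom = u - b
    if denom <= 0:
        offenders = [w for w, _ in plate.untreated_wells] + [w for w, _ in plate.baseline_wells]
        raise DegeneratePlateError(
            "adjusted untreated signal is non-positive "
            f"(untreated mean {u:g} <= baseline mean {b:g}); wells: {offenders}"
        )
    tgi = 1.0 - (raw_treated - b) / denom
    return TGIValue(dose=dose, tgi=float(tgi))


@dataclass(frozen=True)
class FourPLFit:
    """A fitted four-parameter logistic curve.

    ``censored`` is "exact" for a resolvable IC50 and "greater_than_top" when
    the fitted span is below the minimum-effect threshold or the inflection
    lies above the top tested dose; then ``ic50`` holds the top-dose bound.
    """

    lower: float
    upper: float
    ic50: float
    hill: float
    censored: str = "exact"  # "exact" | "greater_than_top"
    rss: float = 0.0
    ladder: DoseLadder | None = None


def four_pl(dose, lower: float, upper: float, ic50: float, hill: float):
    """Evaluate the 4PL response at ``dose`` (scalar or array, molar)."""
    dose = np.asarray(dose, dtype=float)
    return lower + (upper - lower) / (1.0 + (ic50 / dose) ** hill)


def predict_4pl(fit, dose):
    """Evaluate a fitted curve; at dose == IC50 this is (L+U)/2 exactly."""
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr <= 0) or not np.all(np.isfinite(dose_arr)):
        raise InvalidParameterError("dose must be positive and finite")
    out = four_pl(dose_arr, fit.lower, fit.upper, fit.ic50, fit.hill)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response regressor.

    Fits TGI(x) = L + (U-L)/(1 + (IC50/x)^h) by bounded nonlinear least
    squares on the log10-dose scale, with three deterministic multi-starts.
    Replicate wells at the same dose are averaged before fitting.

    Parameters
    ----------
    min_span : float
        Minimum fitted effect span U - L below which the curve is declared
        flat and censored as ">top dose" (default 0.2 TGI units).

    Attributes
    ----------
    lower_, upper_, ic50_, hill_ : float
        Fitted parameters (IC50 in molar).
    censored_ : str
        "exact" or "greater_than_top".
    rss_ : float
        Residual sum of squares at the optimum.
    """

    # Box constraints: TGI lives on ~[0, 1]; IC50 confined to two decades
    # beyond the tested range so extrapolation stays sane.
    _L_BOUNDS = (-0.5, 1.0)
    _U_BOUNDS = (0.0, 1.5)
    _H_BOUNDS = (1e-3, 10.0)

    def __init__(self, min_span: float = 0.2):
        self.min_span = min_span

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).ravel()
        tgis = np.asarray(y, dtype=float).ravel()
        if doses.shape != tgis.shape:
            raise InvalidParameterError("doses and TGI values must align")
        keep = np.isfinite(doses) & np.isfinite(tgis) & (doses > 0)
        doses, tgis = doses[keep], tgis[keep]
        # average replicates per dose
        uniq, inv = np.unique(doses, return_inverse=True)
        if uniq.size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct doses with finite TGI, got {uniq.size}"
            )
        means = np.bincount(inv, weights=tgis) / np.bincount(inv)
        logd = np.log10(uniq)
        top = float(uniq.max())
        logi_lo = np.log10(uniq.min() / 100.0)
        logi_hi = np.log10(top * 100.0)

        def residuals(theta):
            L, U, logi, h = theta
            pred = L + (U - L) / (1.0 + 10.0 ** (h * (logi - logd)))
            return pred - means

        lo = np.array([self._L_BOUNDS[0], self._U_BOUNDS[0], logi_lo, self._H_BOUNDS[0]])
        hi = np.array([self._L_BOUNDS[1], self._U_BOUNDS[1], logi_hi, self._H_BOUNDS[1]])
        L0 = float(np.clip(means.min(), *self._L_BOUNDS))
        U0 = float(np.clip(max(means.max(), L0 + 1e-3), *self._U_BOUNDS))
        best = None
        attempts = []
        for q in (0.25, 0.5, 0.75):
            logi0 = float(np.clip(np.quantile(logd, q), logi_lo, logi_hi))
            x0 = np.array([L0, U0, logi0, 1.0])
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            attempts.append({"x0": x0.tolist(), "cost": float(res.cost), "status": res.status})
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitFailureError("4PL optimizer failed from all starts", {"attempts": attempts})

        L, U, logi, h = best.x
        self.lower_, self.upper_, self.hill_ = float(L), float(U), float(h)
        self.rss_ = float(2.0 * best.cost)
        ic50 = float(10.0 ** logi)
        span = self.upper_ - self.lower_
        if span < self.min_span or ic50 > top:
            self.censored_ = "greater_than_top"
            self.ic50_ = top  # reported bound: the top tested dose
        else:
            self.censored_ = "exact"
            self.ic50_ = ic50
        self.top_dose_ = top
        return self

    def predict(self, X):
        dose = np.asarray(X, dtype=float).ravel()
        if np.any(dose <= 0):
            raise InvalidParameterError("dose must be positive")
        return four_pl(dose, self.lower_, self.upper_, self.ic50_, self.hill_)

    def to_fit(self, ladder: DoseLadder | None = None) -> FourPLFit:
        return FourPLFit(
            lower=self.lower_,
            upper=self.upper_,
            ic50=self.ic50_,
            hill=self.hill_,
            censored=self.censored_,
            rss=self.rss_,
            ladder=ladder,
        )


def fit_4pl(
    doses,
    tgis: Sequence[TGIValue] | Sequence[float],
    min_span: float = 0.2,
) -> FourPLFit:
    """Fit a 4PL curve; thin wrapper over :class:`FourParamLogistic`.

    ``doses`` may be a :class:`DoseLadder` or an array of molar doses;
    ``tgis`` may be :class:`TGIValue` records or plain fractions.
    """
    ladder = doses if isinstance(doses, DoseLadder) else None
    dose_arr = doses.concentrations if ladder is not None else np.asarray(doses, dtype=float)
    vals = np.array([t.tgi if isinstance(t, TGIValue) else float(t) for t in tgis])
    est = FourParamLogistic(min_span=min_span).fit(dose_arr, vals)
    return est.to_fit(ladder=ladder)
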