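"""Relative viability, 4PL dose-response fits, median-effect fits, and
Chou-Talalay combination indices.

The median-effect model is ``fa/fu = (D/Dm)**m`` with ``fu = 1 - fa``:
``Dm`` is the dose producing half effect and ``m`` the sigmoidicity.  For a
constant-ratio combination the combination index at a fraction affected
``fa`` is

    CI(fa) = d1/Dx1(fa) + d2/Dx2(fa)

where ``(d1, d2)`` are the constituent doses of the combination achieving
``fa`` and ``Dx_i(fa)`` the single-agent doses achieving the same effect
(mutually exclusive form).  CI < 1, CI = 1 and CI > 1 read as synergism,
additivity and antagonism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    CalibrationError,
    DegenerateFitError,
    DependencyError,
    InsufficientDataError,
    InvalidInputError,
)

#: Clipping bound applied to fraction-affected values before log-odds fits.
FA_CLIP_EPS = 1e-4

#: Default fraction-affected grid for CI-fa curves (0.05 to 0.97, step 0.01).
DEFAULT_FA_GRID = np.round(np.arange(0.05, 0.97 + 1e-9, 0.01), 10)


def relative_viability(treated_signals, control_signals):
    """Relative viability: mean treated signal over mean control signal.

    Returns ``(rv, per_replicate_rv)`` where the replicate values share the
    control mean as denominator (retained for error bars).
    """
    treated = np.asarray(treated_signals, dtype=float)
    control = np.asarray(control_signals, dtype=float)
    control_mean = control.mean()
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise CalibrationError(
            f"control mean must be positive, got {control_mean!r}"
        )
    per_replicate = treated / control_mean
    return float(treated.mean() / control_mean), per_replicate


def fraction_affected(rv, eps: float = FA_CLIP_EPS):
    """fa = 1 - RV, clipped into [eps, 1 - eps].

    Returns ``(fa, clipped)``; ``clipped`` flags values that hit a bound.
    Scalars in, scalars out.
    """
    rv_arr = np.asarray(rv, dtype=float)
    if not np.all(np.isfinite(rv_arr)):
        raise InvalidInputError("rv must be finite")
    fa = 1.0 - rv_arr
    clipped = (fa < eps) | (fa > 1.0 - eps)
    fa = np.clip(fa, eps, 1.0 - eps)
    if np.isscalar(rv) or rv_arr.ndim == 0:
        return float(fa), bool(clipped)
    return fa, clipped


def _four_pl(log_dose, bottom, top, log_ec50, hill):
    # response = bottom + (top - bottom) / (1 + (dose/ec50)**hill), on log10 dose
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_dose - log_ec50)))


@dataclass
class FourPLResults:
    """Four-parameter logistic fit of response (e.g. RV) against dose."""

    bottom: float
    top: float
    ec50: float
    hill_slope: float
    ec_max: float
    rss: float
    ic50: float
    n_points: int

    def predict(self, doses):
        doses = np.asarray(doses, dtype=float)
        return _four_pl(
            np.log10(doses), self.bottom, self.top, np.log10(self.ec50), self.hill_slope
        )

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic fit",
            "===========================",
            f"bottom plateau   {self.bottom: .6g}",
            f"top plateau      {self.top: .6g}",
            f"EC50             {self.ec50: .6g}",
            f"hill slope       {self.hill_slope: .6g}",
            f"ECmax            {self.ec_max: .6g}",
            f"IC50 (RV = 0.5)  {self.ic50: .6g}",
            f"RSS              {self.rss: .6g}   n = {self.n_points}",
        ]
        return "\n".join(lines)


class FourPLModel:
    """Least-squares 4PL model of a monotone dose-response series.

    Parameters
    ----------
    doses : array-like
        Strictly positive doses.
    response : array-like
        Response per dose; either 1-D (one value per dose) or 2-D with
        replicates along the second axis (averaged before fitting).
    """

    def __init__(self, doses, response):
        doses = np.asarray(doses, dtype=float)
        response = np.asarray(response, dtype=float)
        if doses.ndim != 1 or np.any(doses <= 0):
            raise InvalidInputError("doses must be a 1-D array of positive values")
        if response.ndim == 2:
            self._noise = float(np.mean(np.std(response, axis=1, ddof=0)))
            response = response.mean(axis=1)
        else:
            self._noise = 0.0
        if response.shape != doses.shape:
            raise InvalidInputError("doses and response lengths differ")
        order = np.argsort(doses)
        self.doses = doses[order]
        self.response = response[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose", response_col: str = "rv"):
        grouped = df.groupby(dose_col)[response_col]
        doses = np.array(sorted(grouped.groups))
        reps = [grouped.get_group(d).to_numpy() for d in doses]
        width = min(len(r) for r in reps)
        if width > 1 and all(len(r) == width for r in reps):
            return cls(doses, np.vstack(reps))
        return cls(doses, np.array([r.mean() for r in reps]))

    def fit(self) -> FourPLResults:
        doses, response = self.doses, self.response
        if len(np.unique(doses)) < 4:
            raise InsufficientDataError("need at least 4 distinct positive doses")
        dyn = response.max() - response.min()
        if dyn < max(2.0 * self._noise, 1e-9):
            raise DegenerateFitError(
                "response is flat: top and bottom plateaus are indistinguishable "
                f"(dynamic range {dyn:.3g} < 2 x noise {self._noise:.3g})"
            )
        log_d = np.log10(doses)
        p0 = (response.min(), response.max(), float(np.median(log_d)), 1.0)
        try:
            popt, _ = optimize.curve_fit(
                _four_pl,
                log_d,
                response,
                p0=p0,
                bounds=([-np.inf, -np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf, 100.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            raise DegenerateFitError(f"4PL fit did not converge: {exc}") from exc
        bottom, top, log_ec50, hill = (float(v) for v in popt)
        if top < bottom:
            # same curve with mirrored parameterization; normalize
            bottom, top, hill = top, bottom, -hill
        ec50 = 10.0 ** log_ec50
        resid = response - _four_pl(log_d, *popt)
        rss = float(resid @ resid)
        ic50 = self._solve_ic50(bottom, top, ec50, hill)
        ec_max = self._ec_max(bottom, top, log_ec50, hill)
        return FourPLResults(
            bottom=bottom,
            top=top,
            ec50=ec50,
            hill_slope=hill,
            ec_max=ec_max,
            rss=rss,
            ic50=ic50,
            n_points=len(doses),
        )

    @staticmethod
    def _solve_ic50(bottom, top, ec50, hill):
        # dose where fitted response crosses 0.5 (meaningful for RV-scaled data)
        if not (bottom < 0.5 < top):
            return float("nan")
        return float(ec50 * ((top - 0.5) / (0.5 - bottom)) ** (1.0 / hill))

    def _ec_max(self, bottom, top, log_ec50, hill):
        # smallest tested dose whose fitted response is within 1% of the
        # maximal-effect plateau; the highest tested dose if none reaches it
        fitted = _four_pl(np.log10(self.doses), bottom, top, log_ec50, hill)
        tol = 0.01 * (top - bottom)
        at_max = np.nonzero(fitted <= bottom + tol)[0]
        if len(at_max):
            return float(self.doses[at_max[0]])
        return float(self.doses[-1])


def fit_4pl(doses, response) -> FourPLResults:
    """Convenience wrapper: ``FourPLModel(doses, response).fit()``."""
    return FourPLModel(doses, response).fit()


@dataclass
class MedianEffectResults:
    """Median-effect (mass-action) fit: log(fa/fu) regressed on log dose."""

    dm: float
    m: float
    r: float
    n_points_used: int
    n_excluded: int = 0
    non_monotone: bool = False
    label: str = ""

    def dose_for_fa(self, fa: float) -> float:
        """Dose achieving fraction affected ``fa``: Dx = Dm (fa/fu)^(1/m)."""
        if not 0.0 < fa < 1.0:
            raise InvalidInputError(f"fa must be in (0, 1), got {fa}")
        return float(self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m))

    def fa_at_dose(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)

    def summary(self) -> str:
        lines = [
            f"Median-effect fit {self.label}".rstrip(),
            "=================",
            f"Dm (half-effect dose)  {self.dm: .6g}",
            f"m (slope)              {self.m: .6g}",
            f"r (linear fit)         {self.r: .6g}",
            f"points used            {self.n_points_used} ({self.n_excluded} clipped/excluded)",
        ]
        if self.non_monotone:
            lines.append("warning: non-monotone response (m <= 0)")
        return "\n".join(lines)


class MedianEffectModel:
    """OLS of log10(fa/fu) on log10(dose); points at the fa clip bounds are
    excluded (the log-odds diverges there) and counted."""

    def __init__(self, doses, fa, eps: float = FA_CLIP_EPS, label: str = ""):
        doses = np.asarray(doses, dtype=float)
        fa = np.asarray(fa, dtype=float)
        if doses.shape != fa.shape or doses.ndim != 1:
            raise InvalidInputError("doses and fa must be 1-D arrays of equal length")
        self.doses = doses
        self.fa = fa
        self.eps = eps
        self.label = label

    def fit(self) -> MedianEffectResults:
        usable = (
            np.isfinite(self.doses)
            & np.isfinite(self.fa)
            & (self.doses > 0)
            & (self.fa > self.eps)
            & (self.fa < 1.0 - self.eps)
        )
        n_excluded = int((~usable).sum())
        if usable.sum() < 2:
            raise InsufficientDataError(
                f"median-effect fit needs >= 2 usable points, got {int(usable.sum())}"
            )
        d = self.doses[usable]
        fa = self.fa[usable]
        x = np.log10(d)
        y = np.log10(fa / (1.0 - fa))
        res = stats.linregress(x, y)
        m = float(res.slope)
        non_monotone = m <= 0
        if non_monotone:
            warnings.warn(
                "median-effect slope m <= 0: response is non-monotone in dose",
                stacklevel=2,
            )
            dm = float("nan")
        else:
            dm = float(10.0 ** (-res.intercept / m))
        return MedianEffectResults(
            dm=dm,
            m=m,
            r=float(res.rvalue),
            n_points_used=int(usable.sum()),
            n_excluded=n_excluded,
            non_monotone=non_monotone,
            label=self.label,
        )


def fit_median_effect(doses, fa, eps: float = FA_CLIP_EPS, label: str = "") -> MedianEffectResults:
    """Convenience wrapper: ``MedianEffectModel(doses, fa).fit()``."""
    return MedianEffectModel(doses, fa, eps=eps, label=label).fit()


def dose_for_fa(fit: MedianEffectResults, fa: float) -> float:
    """Single-agent dose achieving ``fa`` under a median-effect fit."""
    return fit.dose_for_fa(fa)


@dataclass
class CombinationIndexPoint:
    fa: float
    ci: float
    d1: float
    d2: float
    dx1: float
    dx2: float


def combination_index(
    fa: float,
    combo_doses: tuple,
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
) -> CombinationIndexPoint:
    """CI = d1/Dx1(fa) + d2/Dx2(fa) for a constant-ratio combination point."""
    if fit_a is None or fit_b is None:
        raise DependencyError("both single-agent median-effect fits are required")
    if not 0.0 < fa < 1.0:
        raise InvalidInputError(f"fa must be in (0, 1), got {fa}")
    d1, d2 = (float(d) for d in combo_doses)
    dx1 = fit_a.dose_for_fa(fa)
    dx2 = fit_b.dose_for_fa(fa)
    return CombinationIndexPoint(
        fa=float(fa), ci=d1 / dx1 + d2 / dx2, d1=d1, d2=d2, dx1=dx1, dx2=dx2
    )


def ci_curve(
    fit_combo: MedianEffectResults,
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
    fraction_a: float,
    fa_grid=None,
) -> list[CombinationIndexPoint]:
    """CI over a fraction-affected grid for a constant-ratio combination.

    The total combination dose achieving each ``fa`` comes from the
    combination's own median-effect fit and is split by the design ratio:
    ``d1 = fraction_a * D``, ``d2 = (1 - fraction_a) * D``.
    """
    if not 0.0 < fraction_a < 1.0:
        raise InvalidInputError("fraction_a must be in (0, 1)")
    if fa_grid is None:
        fa_grid = DEFAULT_FA_GRID
    points = []
    for fa in np.asarray(fa_grid, dtype=float):
        total = fit_combo.dose_for_fa(float(fa))
        points.append(
            combination_index(
                float(fa),
                (fraction_a * total, (1.0 - fraction_a) * total),
                fit_a,
                fit_b,
            )
        )
    return points


def ci_points_to_frame(points: list[CombinationIndexPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fa": [p.fa for p in points],
            "ci": [p.ci for p in points],
            "d1": [p.d1 for p in points],
            "d2": [p.d2 for p in points],
            "dx1": [p.dx1 for p in points],
            "dx2": [p.dx2 for p in points],
        }
    )


def analyze_pair(
    table: pd.DataFrame,
    drug_a: str,
    drug_b: str,
    fa_grid=None,
    eps: float = FA_CLIP_EPS,
):
    """Full constant-ratio synergy analysis of a long-format plate table.

    Expects columns ``drug, dose_a, dose_b, signal, role`` with ``role`` in
    {treated, control}; the combination rows carry ``drug == "{a}+{b}"``.
    Returns ``(fits, ci_points)`` where fits maps series label ->
    MedianEffectResults.
    """
    combo_label = f"{drug_a}+{drug_b}"
    controls = table.loc[table["role"] == "control", "signal"].to_numpy()
    if controls.size == 0:
        raise CalibrationError("no control wells in table")
    treated = table[table["role"] == "treated"]

    def _series(label, dose_of):
        sub = treated[treated["drug"] == label]
        doses, fas = [], []
        for dose, grp in sub.groupby(dose_of):
            rv, _ = relative_viability(grp["signal"].to_numpy(), controls)
            fa, _ = fraction_affected(rv, eps=eps)
            doses.append(float(dose))
            fas.append(fa)
        return np.array(doses), np.array(fas)

    doses_a, fa_a = _series(drug_a, "dose_a")
    doses_b, fa_b = _series(drug_b, "dose_b")
    combo = treated[treated["drug"] == combo_label].copy()
    if combo.empty:
        raise DependencyError(f"no combination rows labeled {combo_label!r}")
    combo["dose_total"] = combo["dose_a"] + combo["dose_b"]
    totals, fa_c = [], []
    for dose, grp in combo.groupby("dose_total"):
        rv, _ = relative_viability(grp["signal"].to_numpy(), controls)
        fa, _ = fraction_affected(rv, eps=eps)
        totals.append(float(dose))
        fa_c.append(fa)
    totals = np.array(totals)
    fraction_a = float(
        (combo["dose_a"] / (combo["dose_a"] + combo["dose_b"])).mean()
    )
    fits = {
        drug_a: fit_median_effect(doses_a, fa_a, eps=eps, label=drug_a),
        drug_b: fit_median_effect(doses_b, fa_b, eps=eps, label=drug_b),
        combo_label: fit_median_effect(totals, np.array(fa_c), eps=eps, label=combo_label),
    }
    points = ci_curve(fits[combo_label], fits[drug_a], fits[drug_b], fraction_a, fa_grid)
    return fits, points
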