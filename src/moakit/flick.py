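"""Cell-death kinetics from lysis-calibrated dead-cell fluorescence.

A plate-reader dye (e.g. SYTOX) reports the dead population over time; total
population size is anchored by two full-lysis measurements (an untreated T0
plate and the endpoint lysis of each well) and extrapolated exponentially in
between.  From live/dead/total three metrics follow:

    FV = live / (live + dead)          fractional viability
    LF = dead / (live + dead)          lethal fraction
    GR = 2 ** ( log2(live_treated/live_T0)
              / log2(live_untreated/live_T0) ) - 1

GR = 1 means no effect, 0 stasis, and GR < 0 population regression.  LF(t)
is summarized by a lag-exponential death (LED) fit with baseline ``lf0``,
plateau ``lf_max``, death onset time and exponential death rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .doseresponse import (
    CombinationIndexPoint,
    MedianEffectResults,
    ci_curve,
    fit_median_effect,
)
from .errors import (
    CalibrationError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedGRError,
)


@dataclass
class PopulationTimecourse:
    """Dead-signal time series for one well/condition plus lysis anchors."""

    condition: str
    dose: float
    timepoints: np.ndarray
    dead_signal: np.ndarray
    t0_lysis_signal: float
    end_lysis_signal: float

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.dead_signal = np.asarray(self.dead_signal, dtype=float)
        if self.timepoints.ndim != 1 or len(self.timepoints) < 2:
            raise InvalidInputError("need >= 2 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        if self.dead_signal.shape != self.timepoints.shape:
            raise InvalidInputError("dead_signal and timepoints lengths differ")


def extrapolate_total(t0_lysis: float, end_lysis: float, timepoints) -> np.ndarray:
    """Exponential total-population extrapolation anchored at the two lysis values.

    total(t) = t0_lysis * exp(k t) with k = ln(end/t0) / T, so both endpoint
    measurements are reproduced exactly.
    """
    t = np.asarray(timepoints, dtype=float)
    if t0_lysis <= 0 or end_lysis <= 0:
        raise CalibrationError("lysis signals must be positive")
    span = t[-1] - t[0]
    if span <= 0:
        raise InvalidInputError("end time must exceed start time")
    k = np.log(end_lysis / t0_lysis) / span
    return t0_lysis * np.exp(k * (t - t[0]))


@dataclass
class KineticMetricSeries:
    """FV/LF (and optionally GR) series; FV + LF = 1 at every timepoint."""

    timepoints: np.ndarray
    fv: np.ndarray
    lf: np.ndarray
    gr: np.ndarray | None = None
    n_clamped: int = 0


def compute_fv_lf(dead_signal, total, timepoints=None, tolerance: float = 0.05) -> KineticMetricSeries:
    """Fractional viability and lethal fraction from dead and total signals.

    ``dead > total`` beyond ``tolerance`` (relative) raises a calibration
    error; smaller excursions are clamped into [0, 1] and counted.
    """
    dead = np.asarray(dead_signal, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise CalibrationError("total population signal must be positive")
    if np.any(dead > total * (1.0 + tolerance)):
        raise CalibrationError(
            "dead signal exceeds total population beyond the "
            f"{tolerance:.0%} clamping tolerance"
        )
    raw_lf = dead / total
    clamped = (raw_lf < 0) | (raw_lf > 1)
    lf = np.clip(raw_lf, 0.0, 1.0)
    t = np.asarray(timepoints, dtype=float) if timepoints is not None else np.arange(len(lf), dtype=float)
    return KineticMetricSeries(
        timepoints=t, fv=1.0 - lf, lf=lf, n_clamped=int(clamped.sum())
    )


def compute_gr(live_treated_end, live_untreated_end, live_t0):
    """Normalized growth-rate inhibition; accepts scalars or arrays."""
    lt = np.asarray(live_treated_end, dtype=float)
    lu = np.asarray(live_untreated_end, dtype=float)
    l0 = np.asarray(live_t0, dtype=float)
    if np.any(lt <= 0) or np.any(lu <= 0) or np.any(l0 <= 0):
        raise InvalidInputError("live population sizes must be positive")
    den = np.log2(lu / l0)
    if np.any(den == 0):
        raise UndefinedGRError("untreated population did not grow; GR undefined")
    gr = 2.0 ** (np.log2(lt / l0) / den) - 1.0
    return float(gr) if gr.ndim == 0 else gr


def metrics_from_timecourse(
    tc: PopulationTimecourse,
    untreated: PopulationTimecourse | None = None,
    tolerance: float = 0.05,
) -> KineticMetricSeries:
    """FV/LF for one well; GR(t) too when an untreated well is supplied.

    Each condition uses its own endpoint lysis for the growth model; the
    untreated well supplies the GR denominator.  GR at the first timepoint is
    undefined (denominator 0) and reported as NaN.
    """
    total = extrapolate_total(tc.t0_lysis_signal, tc.end_lysis_signal, tc.timepoints)
    series = compute_fv_lf(tc.dead_signal, total, tc.timepoints, tolerance=tolerance)
    if untreated is not None:
        u_total = extrapolate_total(
            untreated.t0_lysis_signal, untreated.end_lysis_signal, untreated.timepoints
        )
        u_series = compute_fv_lf(untreated.dead_signal, u_total, untreated.timepoints, tolerance=tolerance)
        live_t = total * series.fv
        live_u = u_total * u_series.fv
        live_t0 = live_u[0]
        gr = np.full(len(tc.timepoints), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            den = np.log2(live_u / live_t0)
            ok = den != 0
            gr[ok] = 2.0 ** (np.log2(live_t[ok] / live_t0) / den[ok]) - 1.0
        series.gr = gr
    return series


def _led(t, lf0, lf_max, onset, rate):
    lag = np.clip(t - onset, 0.0, None)
    return lf0 + (lf_max - lf0) * (1.0 - np.exp(-rate * lag))


@dataclass
class LedResults:
    """Lag-exponential death fit of a lethal-fraction time series."""

    lf0: float
    lf_max: float
    onset: float
    rate: float
    rss: float
    no_death: bool = False
    onset_observed: bool = True

    def predict(self, t):
        if self.no_death:
            return np.full_like(np.asarray(t, dtype=float), self.lf0)
        return _led(np.asarray(t, dtype=float), self.lf0, self.lf_max, self.onset, self.rate)

    def summary(self) -> str:
        if self.no_death:
            return (
                "Lag-exponential death fit\n=========================\n"
                f"no death detected (LF range < 0.05); baseline LF = {self.lf0:.4g}"
            )
        onset = f"{self.onset:.4g} h" if self.onset_observed else "not observed in window"
        return "\n".join(
            [
                "Lag-exponential death fit",
                "=========================",
                f"LF0 (baseline)   {self.lf0: .4g}",
                f"LFmax (plateau)  {self.lf_max: .4g}",
                f"death onset      {onset}",
                f"death rate       {self.rate: .4g} /h",
                f"RSS              {self.rss: .4g}",
            ]
        )


class LagExpDeathModel:
    """LED model: LF(t) = lf0 for t < onset, then exponential rise to lf_max.

    The onset is initialized by a grid search over the sampled timepoints
    (with conditional inner fits of the three smooth parameters) and refined
    jointly by bounded least squares.
    """

    def __init__(self, timepoints, lf):
        t = np.asarray(timepoints, dtype=float)
        lf = np.asarray(lf, dtype=float)
        if t.ndim != 1 or t.shape != lf.shape:
            raise InvalidInputError("timepoints and lf must be 1-D arrays of equal length")
        if len(t) < 6:
            raise InsufficientDataError("LED fit needs >= 6 timepoints")
        order = np.argsort(t)
        self.t = t[order]
        self.lf = np.clip(lf[order], 0.0, 1.0)

    def _fit_at_onset(self, onset):
        t, lf = self.t, self.lf
        before = lf[t < onset]
        p0 = (
            float(before.mean()) if len(before) else float(lf[0]),
            float(lf.max()),
            0.1,
        )
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, lf0, lf_max, rate: _led(tt, lf0, lf_max, onset, rate),
                t,
                lf,
                p0=p0,
                bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, 100.0]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            return None
        resid = lf - _led(t, popt[0], popt[1], onset, popt[2])
        return float(resid @ resid), popt

    def fit(self) -> LedResults:
        t, lf = self.t, self.lf
        dyn = lf.max() - lf.min()
        if dyn < 0.05:
            base = float(np.median(lf))
            resid = lf - base
            return LedResults(
                lf0=base,
                lf_max=float(lf.max()),
                onset=float("nan"),
                rate=0.0,
                rss=float(resid @ resid),
                no_death=True,
                onset_observed=False,
            )
        mids = (t[:-1] + t[1:]) / 2.0
        candidates = np.unique(np.concatenate([[0.0], t[:-2], mids[:-1]]))
        best = None
        for onset in candidates:
            res = self._fit_at_onset(float(onset))
            if res is None:
                continue
            rss, popt = res
            if best is None or rss < best[0]:
                best = (rss, float(onset), popt)
        if best is None:  # pragma: no cover - grid always yields a fit
            raise InsufficientDataError("LED fit failed at every candidate onset")
        _, onset0, (lf0, lf_max, rate) = best

        def residuals(params):
            return _led(t, *params) - lf

        sol = optimize.least_squares(
            residuals,
            x0=[lf0, lf_max, onset0, rate],
            bounds=([0.0, 0.0, 0.0, 1e-6], [1.0, 1.0, float(t[-1]), 100.0]),
        )
        lf0, lf_max, onset, rate = (float(v) for v in sol.x)
        rss = float(sol.fun @ sol.fun)
        return LedResults(
            lf0=lf0,
            lf_max=lf_max,
            onset=onset,
            rate=rate,
            rss=rss,
            onset_observed=bool(t[0] <= onset <= t[-1]),
        )


def fit_led(timepoints, lf) -> LedResults:
    """Convenience wrapper: ``LagExpDeathModel(timepoints, lf).fit()``."""
    return LagExpDeathModel(timepoints, lf).fit()


@dataclass
class CurveSummary:
    auc: float
    aoc: float
    lf_max_observed: float
    auc_from_fit: bool = False


def summarize_curves(
    timepoints=None,
    lf=None,
    led: LedResults | None = None,
    doses=None,
    fv=None,
) -> CurveSummary:
    """AUC of LF over the assay window, AOC of endpoint FV over log dose.

    AUC integrates the fitted LED curve when a converged fit is supplied
    (noise robustness), otherwise the raw points.  AOC = 1 minus the mean FV
    over the tested log-dose range, so FV = 1 everywhere gives 0 and FV = 0
    gives 1.
    """
    auc = float("nan")
    lf_max_observed = float("nan")
    auc_from_fit = False
    if lf is not None:
        lf = np.asarray(lf, dtype=float)
        t = np.asarray(timepoints, dtype=float)
        if len(lf) < 2:
            raise InsufficientDataError("AUC needs >= 2 LF points")
        if led is not None and not led.no_death:
            dense = np.linspace(t[0], t[-1], 512)
            auc = float(np.trapezoid(led.predict(dense), dense))
            auc_from_fit = True
            lf_max_observed = float(max(lf.max(), led.lf_max))
        else:
            auc = float(np.trapezoid(lf, t))
            lf_max_observed = float(lf.max())
    aoc = float("nan")
    if fv is not None:
        fv = np.asarray(fv, dtype=float)
        d = np.asarray(doses, dtype=float)
        if len(fv) < 2:
            raise InsufficientDataError("AOC needs >= 2 FV points")
        if np.any(d <= 0):
            raise InvalidInputError("doses must be positive for log-dose AOC")
        x = np.log10(d)
        aoc = float(1.0 - np.trapezoid(fv, x) / (x[-1] - x[0]))
    return CurveSummary(auc=auc, aoc=aoc, lf_max_observed=lf_max_observed, auc_from_fit=auc_from_fit)


def ci_from_lf(
    doses_a,
    lf_a,
    doses_b,
    lf_b,
    combo_total_doses,
    lf_combo,
    fraction_a: float,
    fa: float = 0.5,
) -> CombinationIndexPoint:
    """Combination index at ``fa`` using endpoint lethal fraction as the effect.

    LF per dose plays the role of fraction affected; the median-effect
    machinery then yields CI exactly as in the viability-based analysis.
    """
    fit_a = fit_median_effect(np.asarray(doses_a, float), np.asarray(lf_a, float), label="A (LF)")
    fit_b = fit_median_effect(np.asarray(doses_b, float), np.asarray(lf_b, float), label="B (LF)")
    fit_c = fit_median_effect(
        np.asarray(combo_total_doses, float), np.asarray(lf_combo, float), label="combo (LF)"
    )
    points = ci_curve(fit_c, fit_a, fit_b, fraction_a, fa_grid=[fa])
    return points[0]


def ci_from_lf_results(fit_a: MedianEffectResults, fit_b: MedianEffectResults,
                       fit_combo: MedianEffectResults, fraction_a: float,
                       fa: float = 0.5) -> CombinationIndexPoint:
    """CI at ``fa`` from pre-computed LF-based median-effect fits."""
    return ci_curve(fit_combo, fit_a, fit_b, fraction_a, fa_grid=[fa])[0]
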