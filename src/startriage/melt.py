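"""Thermal-shift (DSF) melt-curve analysis.

Fits two-state (optionally biphasic) sigmoidal unfolding transitions to
temperature/fluorescence traces, computes compound-induced melting-temperature
shifts (dTm) against a no-compound reference, and applies the integer
stabilization-score rubric used to rank screening hits:

    score  4  for dTm >  3 degC
    score  2  for dTm >  2 degC
    score  1  for dTm >  1 degC
    score  0  for dTm in [-1, 1]
    mirrored negative scores for destabilization.

The melting temperature Tm is the fitted sigmoid midpoint (the temperature at
which half the protein is unfolded), not the derivative maximum; the midpoint
is the standard DSF readout and is robust to moderate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MeltCurve",
    "MeltFit",
    "StabilityScore",
    "DoseResponseTm",
    "fit_melt_curve",
    "delta_tm",
    "score_delta_tm",
    "combine_scores",
    "best_of_concentrations",
    "dose_response_tm",
]


@dataclass(frozen=True)
class MeltCurve:
    """A single thermal-denaturation trace.

    temperature is in degC and must be strictly increasing; fluorescence is in
    arbitrary units and has the same length.
    """

    temperature: np.ndarray
    fluorescence: np.ndarray
    replicate_id: int = 0
    protein_label: str = "WT"
    compound_label: str = ""
    compound_conc_um: float = 0.0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence must be equal-length 1-D series")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class MeltFit:
    """Fitted unfolding transition; tm2 is set only for biphasic fits."""

    tm: float
    amplitude: float
    baseline: float
    baseline_slope: float
    width: float
    tm2: float | None = None
    amplitude2: float | None = None
    width2: float | None = None
    fit_rmse: float = 0.0
    converged: bool = True
    reason: str = ""
    protein_label: str = ""


@dataclass(frozen=True)
class StabilityScore:
    delta_tm: float
    score: int
    variant_label: str = ""


@dataclass(frozen=True)
class DoseResponseTm:
    concentrations_um: tuple[float, ...]
    delta_tm_per_conc: tuple[float, ...]
    monotone_flag: bool
    spearman_rho: float
    plateau_flag: bool


def _sigmoid(t: np.ndarray, f0: float, slope: float, amp: float, tm: float, w: float) -> np.ndarray:
    return f0 + slope * (t - t[0]) + amp / (1.0 + np.exp((tm - t) / w))


def _sigmoid2(
    t: np.ndarray,
    f0: float,
    slope: float,
    amp: float,
    tm: float,
    w: float,
    amp2: float,
    tm2: float,
    w2: float,
) -> np.ndarray:
    return _sigmoid(t, f0, slope, amp, tm, w) + amp2 / (1.0 + np.exp((tm2 - t) / w2))


def _noise_estimate(f: np.ndarray) -> float:
    # second differences cancel smooth trend; var(d2) = 6 sigma^2 for white noise
    if f.size < 3:
        return 0.0
    return float(np.std(np.diff(f, 2)) / np.sqrt(6.0))


def _transition_guess(t: np.ndarray, f: np.ndarray) -> float:
    # midpoint guess from the steepest (smoothed) slope
    df = np.gradient(f, t)
    if df.size >= 5:
        kernel = np.ones(5) / 5.0
        df = np.convolve(df, kernel, mode="same")
    return float(t[int(np.argmax(np.abs(df)))])


def fit_melt_curve(curve: MeltCurve, model: str = "monophasic") -> MeltFit:
    """Fit a sigmoidal unfolding transition by nonlinear least squares.

    Returns a MeltFit with ``converged=False`` (never raises) when the curve
    has no detectable transition, the optimizer fails, or the midpoint pins to
    the edge of the observed temperature range.
    """
    if model not in ("monophasic", "biphasic"):
        raise ValueError(f"unknown model {model!r}")
    t, f = curve.temperature, curve.fluorescence
    if t.size < 10:
        raise ValueError("need at least 10 temperature points to fit a transition")

    span = float(np.ptp(f))
    noise = _noise_estimate(f)
    if span <= max(6.0 * noise, 1e-12):
        return MeltFit(
            tm=float("nan"), amplitude=0.0, baseline=float(np.mean(f)),
            baseline_slope=0.0, width=float("nan"), converged=False,
            reason="no transition", protein_label=curve.protein_label,
        )

    tm0 = _transition_guess(t, f)
    f0_0, amp0 = float(f[0]), float(f[-1] - f[0])
    t_lo, t_hi = float(t[0]), float(t[-1])

    try:
        if model == "monophasic":
            p0 = [f0_0, 0.0, amp0, tm0, 1.0]
            lb = [-np.inf, -np.inf, -np.inf, t_lo, 1e-3]
            ub = [np.inf, np.inf, np.inf, t_hi, (t_hi - t_lo)]
            popt, _ = optimize.curve_fit(_sigmoid, t, f, p0=p0, bounds=(lb, ub), maxfev=20000)
            pred = _sigmoid(t, *popt)
            tm, edge = float(popt[3]), 0.05 * (t_hi - t_lo)
            converged = (t_lo + 1e-6 < tm < t_hi - 1e-6)
            fit = MeltFit(
                tm=tm, amplitude=float(popt[2]), baseline=float(popt[0]),
                baseline_slope=float(popt[1]), width=float(popt[4]),
                fit_rmse=float(np.sqrt(np.mean((pred - f) ** 2))),
                converged=converged, reason="" if converged else "Tm at bound",
                protein_label=curve.protein_label,
            )
        else:
            # two transitions: seed midpoints in the lower/upper thirds
            tm1_0 = t_lo + 0.33 * (t_hi - t_lo)
            tm2_0 = t_lo + 0.67 * (t_hi - t_lo)
            p0 = [f0_0, 0.0, amp0 / 2.0, tm1_0, 1.0, amp0 / 2.0, tm2_0, 1.0]
            lb = [-np.inf, -np.inf, -np.inf, t_lo, 1e-3, -np.inf, t_lo, 1e-3]
            ub = [np.inf, np.inf, np.inf, t_hi, t_hi - t_lo, np.inf, t_hi, t_hi - t_lo]
            popt, _ = optimize.curve_fit(_sigmoid2, t, f, p0=p0, bounds=(lb, ub), maxfev=40000)
            pred = _sigmoid2(t, *popt)
            tm_a, tm_b = float(popt[3]), float(popt[6])
            # order the two transitions so tm < tm2
            if tm_a <= tm_b:
                tm, amp, w = tm_a, float(popt[2]), float(popt[4])
                tm2, amp2, w2 = tm_b, float(popt[5]), float(popt[7])
            else:
                tm, amp, w = tm_b, float(popt[5]), float(popt[7])
                tm2, amp2, w2 = tm_a, float(popt[2]), float(popt[4])
            converged = (t_lo + 1e-6 < tm) and (tm2 < t_hi - 1e-6) and tm < tm2
            fit = MeltFit(
                tm=tm, amplitude=amp, baseline=float(popt[0]),
                baseline_slope=float(popt[1]), width=w,
                tm2=tm2, amplitude2=amp2, width2=w2,
                fit_rmse=float(np.sqrt(np.mean((pred - f) ** 2))),
                converged=converged, reason="" if converged else "Tm at bound",
                protein_label=curve.protein_label,
            )
    except (RuntimeError, ValueError):
        return MeltFit(
            tm=float("nan"), amplitude=0.0, baseline=f0_0, baseline_slope=0.0,
            width=float("nan"), converged=False, reason="optimizer failed",
            protein_label=curve.protein_label,
        )
    return fit


def delta_tm(fit: MeltFit, reference: MeltFit) -> float:
    """Thermal shift: Tm with compound minus Tm of the no-compound reference."""
    if not (fit.converged and reference.converged):
        raise ValueError("both fits must have converged")
    if fit.protein_label and reference.protein_label and fit.protein_label != reference.protein_label:
        raise ValueError(
            f"protein labels differ: {fit.protein_label!r} vs {reference.protein_label!r}"
        )
    return float(fit.tm - reference.tm)


def score_delta_tm(delta: float) -> int:
    """Integer stabilization score for a thermal shift (strict thresholds).

    Boundary values take the lower bin: dTm = 2.0 scores 1, not 2.
    Destabilization mirrors the positive rubric with negative scores.
    """
    if not np.isfinite(delta):
        raise ValueError("delta_tm must be finite")
    if delta > 3.0:
        return 4
    if delta > 2.0:
        return 2
    if delta > 1.0:
        return 1
    if delta < -3.0:
        return -4
    if delta < -2.0:
        return -2
    if delta < -1.0:
        return -1
    return 0


def combine_scores(per_variant: Iterable[StabilityScore | int]) -> int:
    """Sum per-variant stabilization scores into a compound-level score."""
    scores = [s.score if isinstance(s, StabilityScore) else int(s) for s in per_variant]
    if not scores:
        raise ValueError("need at least one per-variant score")
    return int(sum(scores))


def best_of_concentrations(
    delta_tms: Sequence[float] | Mapping[float, float],
    variant_label: str = "",
) -> StabilityScore:
    """Score a compound/variant pair from the highest dTm across the tested
    concentrations (the screening convention: one score per pair)."""
    values = list(delta_tms.values()) if isinstance(delta_tms, Mapping) else list(delta_tms)
    if not values:
        raise ValueError("need at least one concentration")
    best = float(max(values))
    return StabilityScore(delta_tm=best, score=score_delta_tm(best), variant_label=variant_label)


def dose_response_tm(
    concentrations_um: Sequence[float],
    delta_tms: Sequence[float],
    rho_threshold: float = 0.8,
    plateau_fraction: float = 0.1,
) -> DoseResponseTm:
    """Summarize dTm versus compound concentration.

    monotone_flag is set when the Spearman rank correlation of dTm with
    concentration is at least ``rho_threshold``; a plateau is called when the
    change over the top two concentrations is below ``plateau_fraction`` of
    the maximum shift.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    dtm = np.asarray(delta_tms, dtype=float)
    if conc.size != dtm.size or conc.size < 3:
        raise ValueError("need >= 3 matched (concentration, delta_tm) pairs")
    if np.ptp(dtm) == 0.0:
        rho = 0.0  # constant response carries no trend
    else:
        rho = float(stats.spearmanr(conc, dtm).statistic)
    order = np.argsort(conc)
    dtm_sorted = dtm[order]
    max_shift = float(np.max(np.abs(dtm_sorted)))
    plateau = bool(
        max_shift > 0
        and abs(dtm_sorted[-1] - dtm_sorted[-2]) <= plateau_fraction * max_shift
    )
    return DoseResponseTm(
        concentrations_um=tuple(float(c) for c in conc[order]),
        delta_tm_per_conc=tuple(float(d) for d in dtm_sorted),
        monotone_flag=bool(rho >= rho_threshold),
        spearman_rho=rho,
        plateau_flag=plateau,
    )
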