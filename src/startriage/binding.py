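"""Binding quantification from tryptophan-quenching titrations and ITC.

Two orthogonal binding readouts feed the triage:

* Quenching: intrinsic tryptophan fluorescence of the protein, normalized to
  the compound-free signal (F/F0), decreases approximately linearly with
  compound concentration over the titrated range. The binding-affinity proxy
  KB is the inverse magnitude of the fitted slope (per-uM quenching); a slope
  whose 95% confidence interval covers zero is called "no binding".

* ITC: integrated injection heats are fit to the single-site binding isotherm
  with explicit displaced-volume dilution bookkeeping, yielding Kd, binding
  enthalpy dH and stoichiometry N, from which dG = RT ln Kd and
  -T dS = dG - dH follow at the experiment temperature (default 20 degC).

The injection bookkeeping uses the discrete perfusion convention: each
injection of volume dV displaces an equal volume of well-mixed cell content,
so protein (and previously formed complex) is diluted by (1 - dV/V0) per
injection while titrant accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "R_KCAL_PER_MOL_K",
    "TitrationSeries",
    "InjectionSeries",
    "QuenchFit",
    "BindingThermodynamics",
    "itc_molar_heats",
    "fit_quench",
    "fit_itc",
    "binding_evidence",
]

#: Gas constant in kcal/(mol K).
R_KCAL_PER_MOL_K = 1.9872e-3


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration-indexed response (quenching F/F0, % activity, peak area)."""

    concentration_um: np.ndarray
    response: np.ndarray
    response_sd: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration_um, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1-D series")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "concentration_um", c)
        object.__setattr__(self, "response", r)
        if self.response_sd is not None:
            sd = np.asarray(self.response_sd, dtype=float)
            if sd.shape != r.shape:
                raise ValueError("response_sd must match response length")
            object.__setattr__(self, "response_sd", sd)


@dataclass(frozen=True)
class InjectionSeries:
    """Per-injection molar heats from an ITC run.

    heat_kcal_per_mol is the integrated heat of each injection normalized per
    mole of injectant; molar_ratio is total titrant over total protein in the
    cell after the injection.
    """

    heat_kcal_per_mol: np.ndarray
    molar_ratio: np.ndarray
    cell_conc_um: float
    syringe_conc_um: float
    inj_vol_ul: float
    cell_vol_ul: float = 200.0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.heat_kcal_per_mol, dtype=float)
        mr = np.asarray(self.molar_ratio, dtype=float)
        if q.shape != mr.shape or q.ndim != 1:
            raise ValueError("heats and molar ratios must be equal-length 1-D series")
        if not np.all(np.diff(mr) > 0):
            raise ValueError("molar ratios must be strictly increasing")
        object.__setattr__(self, "heat_kcal_per_mol", q)
        object.__setattr__(self, "molar_ratio", mr)

    @property
    def n_injections(self) -> int:
        return int(self.heat_kcal_per_mol.size)


@dataclass(frozen=True)
class QuenchFit:
    slope_per_um: float
    slope_se: float
    kb_um: float | None
    r_squared: float
    binding_call: str  # "binder" | "no_binding"


@dataclass(frozen=True)
class BindingThermodynamics:
    kd_um: float | None
    dh_kcal_per_mol: float | None
    n_sites: float | None
    dg_kcal_per_mol: float | None
    minus_tds_kcal_per_mol: float | None
    temperature_k: float
    binding_call: str  # "binder" | "no_binding" | "insoluble/unmeasured"
    c_parameter: float | None = None
    low_confidence: bool = False
    fit_rmse: float | None = None


def _itc_totals(
    cell_conc_um: float, syringe_conc_um: float, n_inj: int, inj_vol_ul: float, cell_vol_ul: float
) -> tuple[np.ndarray, np.ndarray]:
    """Total protein and titrant concentrations (uM) in the cell after each
    injection under the discrete perfusion convention."""
    d = inj_vol_ul / cell_vol_ul
    pt = np.empty(n_inj)
    lt = np.empty(n_inj)
    p, l = cell_conc_um, 0.0
    for i in range(n_inj):
        p = p * (1.0 - d)
        l = l * (1.0 - d) + syringe_conc_um * d
        pt[i], lt[i] = p, l
    return pt, lt


def _bound_complex(pt: np.ndarray, lt: np.ndarray, kd_um: float, n: float) -> np.ndarray:
    """Equilibrium complex concentration (uM of occupied sites) from the
    one-site quadratic with site concentration n*Pt."""
    sites = n * pt
    b = sites + lt + kd_um
    disc = np.maximum(b * b - 4.0 * sites * lt, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def itc_molar_heats(
    kd_um: float,
    dh_kcal_per_mol: float,
    n: float,
    cell_conc_um: float,
    syringe_conc_um: float,
    n_inj: int,
    inj_vol_ul: float,
    cell_vol_ul: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward one-site isotherm: per-injection heat (kcal per mole of
    injectant) and molar ratio after each injection.

    The heat of injection i is V0 * dH * (PL_i - PL_{i-1} * (1 - dV/V0));
    complex displaced out of the cell by the injection releases no further
    heat.
    """
    pt, lt = _itc_totals(cell_conc_um, syringe_conc_um, n_inj, inj_vol_ul, cell_vol_ul)
    pl = _bound_complex(pt, lt, kd_um, n)
    d = inj_vol_ul / cell_vol_ul
    prev = np.concatenate([[0.0], pl[:-1]])
    delta_pl_um = pl - prev * (1.0 - d)
    v0_l = cell_vol_ul * 1e-6
    moles_injected = syringe_conc_um * 1e-6 * inj_vol_ul * 1e-6
    heats = v0_l * dh_kcal_per_mol * (delta_pl_um * 1e-6) / moles_injected
    return heats, lt / pt


def fit_quench(series: TitrationSeries, alpha: float = 0.05) -> QuenchFit:
    """Binding affinity from a quenching titration: KB = 1 / |OLS slope|.

    The series must contain at least 5 concentrations including zero, with
    responses normalized to F/F0. If the slope is statistically
    indistinguishable from zero at level ``alpha`` the call is "no_binding"
    and KB is left unset.
    """
    c, r = series.concentration_um, series.response
    if c.size < 5:
        raise ValueError("need at least 5 concentrations")
    if not np.any(c == 0):
        raise ValueError("titration must include the zero-compound point")
    if np.ptp(r) == 0.0:
        return QuenchFit(0.0, 0.0, None, 0.0, "no_binding")
    res = stats.linregress(c, r)
    slope, se = float(res.slope), float(res.stderr)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, c.size - 2)
    if se > 0 and abs(slope) <= tcrit * se:
        return QuenchFit(slope, se, None, float(res.rvalue**2), "no_binding")
    kb = 1.0 / abs(slope) if slope != 0 else None
    return QuenchFit(slope, se, kb, float(res.rvalue**2),
                     "binder" if kb is not None else "no_binding")


def _thermo(kd_um: float, dh: float, n: float, temperature_k: float,
            c_param: float | None, low_conf: bool, rmse: float | None) -> BindingThermodynamics:
    dg = R_KCAL_PER_MOL_K * temperature_k * np.log(kd_um * 1e-6)
    return BindingThermodynamics(
        kd_um=kd_um, dh_kcal_per_mol=dh, n_sites=n,
        dg_kcal_per_mol=float(dg), minus_tds_kcal_per_mol=float(dg - dh),
        temperature_k=temperature_k, binding_call="binder",
        c_parameter=c_param, low_confidence=low_conf, fit_rmse=rmse,
    )


def fit_itc(
    series: InjectionSeries,
    temperature_k: float = 293.15,
    noise_sd: float | None = None,
    drop_first: bool = False,
) -> BindingThermodynamics:
    """Fit (Kd, dH, N) to per-injection molar heats by nonlinear least squares.

    The model and dilution bookkeeping are identical to the forward isotherm
    in :func:`itc_molar_heats`; the fit is parameterized in log Kd for
    conditioning. A run whose largest heat is below three times the injection
    noise is called "no_binding". Wiseman c (N Pt / Kd) outside [0.5, 5000]
    sets the low-confidence flag; ``drop_first`` excludes the first injection
    from the residuals (common practice for the diffusion-compromised first
    injection) while keeping the bookkeeping intact.
    """
    q = series.heat_kcal_per_mol
    if series.n_injections < 10:
        raise ValueError("need at least 10 injections")
    if noise_sd is None:
        # late injections approach the dilution baseline; their scatter
        # estimates per-injection noise
        tail = q[-4:]
        noise_sd = float(np.std(tail, ddof=1))
    if np.max(np.abs(q)) < 3.0 * noise_sd or np.ptp(q) == 0.0:
        return BindingThermodynamics(
            kd_um=None, dh_kcal_per_mol=None, n_sites=None, dg_kcal_per_mol=None,
            minus_tds_kcal_per_mol=None, temperature_k=temperature_k,
            binding_call="no_binding",
        )

    n_inj = series.n_injections
    mask = np.ones(n_inj, dtype=bool)
    if drop_first:
        mask[0] = False

    def model(params: np.ndarray) -> np.ndarray:
        log_kd, dh, n = params
        heats, _ = itc_molar_heats(
            np.exp(log_kd), dh, n, series.cell_conc_um, series.syringe_conc_um,
            n_inj, series.inj_vol_ul, series.cell_vol_ul,
        )
        return heats

    def residuals(params: np.ndarray) -> np.ndarray:
        return (model(params) - q)[mask]

    # initial guesses: N from the molar ratio at half cumulative heat, dH from
    # the first injections; several Kd starts to avoid shallow basins
    cum = np.cumsum(q)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(np.sort(cum / cum[-1]), 0.5)) if cum[-1] != 0 else n_inj // 2
    n0 = float(np.clip(series.molar_ratio[min(idx, n_inj - 1)], 0.2, 5.0))
    dh0 = float(q[0])
    best = None
    for kd0 in (0.1, 1.0, 10.0, 100.0):
        try:
            sol = optimize.least_squares(
                residuals, x0=[np.log(kd0), dh0, n0],
                bounds=([np.log(1e-6), -1e3, 0.01], [np.log(1e6), 1e3, 100.0]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return BindingThermodynamics(
            kd_um=None, dh_kcal_per_mol=None, n_sites=None, dg_kcal_per_mol=None,
            minus_tds_kcal_per_mol=None, temperature_k=temperature_k,
            binding_call="no_binding", low_confidence=True,
        )
    kd = float(np.exp(best.x[0]))
    dh, n = float(best.x[1]), float(best.x[2])
    c_param = n * series.cell_conc_um / kd
    rmse = float(np.sqrt(np.mean((model(best.x) - q)[mask] ** 2)))
    return _thermo(kd, dh, n, temperature_k, float(c_param),
                   not (0.5 <= c_param <= 5000.0), rmse)


def binding_evidence(
    quench: QuenchFit | None = None,
    itc: BindingThermodynamics | None = None,
    kb_cutoff_um: float = 100.0,
) -> bool:
    """Binding evidence per the triage rule: an ITC binder call, or a
    quenching-derived KB strictly below the cutoff (default 100 uM)."""
    if quench is None and itc is None:
        raise ValueError("need at least one of quench or itc")
    if itc is not None and itc.binding_call == "binder":
        return True
    if quench is not None and quench.kb_um is not None and quench.kb_um < kb_cutoff_um:
        return True
    return False
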