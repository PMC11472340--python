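"""Synthetic assay-signal generators with known ground truth.

Every wet-lab assay in the triage cascade has a forward model here, so each
analysis stage can be exercised against data whose generating parameters are
known exactly:

* thermal melts — two-state sigmoid F(T) = baseline + dF / (1 + exp((Tm-T)/w)),
  optionally biphasic, with linear pre-transition baseline;
* quenching titrations — normalized fluorescence F/F0 = 1 - c/KB, clipped at
  zero (matching the linear-regression analysis of the quenching readout);
* ITC runs — single-site isotherm with discrete perfusion dilution
  bookkeeping (see :mod:`startriage.binding`);
* initial-rate series — general modifier Michaelis-Menten with competitive /
  noncompetitive / uncompetitive / mixed terms;
* dose-response curves — four-parameter logistic.

Noise is Gaussian and homoscedastic per assay; seeds are explicit arguments
(via GroundTruth), never global state, so identical (parameters, seed)
reproduce bit-identical output. Default grids mirror the screening protocol:
melts from 25 to 60 degC at a 1 degC/min ramp, 16 quenching concentrations
from 0 to 100 uM, 19 x 2 uL ITC injections of 500 uM titrant into 30 uM
protein, substrate from 0 to 1.5 mM, and doses from 0.25 to 125 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding import InjectionSeries, TitrationSeries, itc_molar_heats
from .kinetics import RateSeries, inhibited_rate
from .melt import MeltCurve
from .panel import AssayPanel, load_table1_fixture  # re-exported fixture loader

__all__ = [
    "GroundTruth",
    "MELT_TEMP_GRID",
    "QUENCH_CONCENTRATIONS_UM",
    "SUBSTRATE_GRID_MM",
    "DOSE_CONCENTRATIONS_UM",
    "gen_melt_curve",
    "gen_quench_titration",
    "gen_itc_experiment",
    "gen_rate_series",
    "gen_dose_response",
    "load_table1_fixture",
]

#: screening melt grid: 25-60 degC ramp read every 0.5 degC
MELT_TEMP_GRID: np.ndarray = np.arange(25.0, 60.0 + 0.25, 0.5)

#: the 16 titrated quenching concentrations (uM)
QUENCH_CONCENTRATIONS_UM: tuple[float, ...] = (
    0, 1, 3, 5, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50, 75, 100,
)

#: 0 plus 11 log-spaced substrate levels up to the 1.5 mM protocol ceiling;
#: log spacing is the standard design when Km sits far below the range top
SUBSTRATE_GRID_MM: np.ndarray = np.concatenate(
    [[0.0], np.geomspace(1.5e-3, 1.5, 11)]
)

#: dose-response concentrations, 0.25-125 uM
DOSE_CONCENTRATIONS_UM: np.ndarray = np.geomspace(0.25, 125.0, 10)

_REQUIRED_PARAMS: dict[str, set[str]] = {
    "melt": {"tm", "amplitude"},
    "quench": {"kb_um"},
    "itc": {"kd_um", "dh_kcal_per_mol", "n_sites"},
    "rate": {"km_um", "vmax_um_per_s"},
    "dose_response": {"ic50_um"},
}


@dataclass(frozen=True)
class GroundTruth:
    """Generating truth for one synthetic assay.

    ``parameters`` must contain every symbol the named assay's forward model
    requires (melt: tm, amplitude [f0, width, baseline_slope, tm2,
    amplitude2, width2]; quench: kb_um; itc: kd_um, dh_kcal_per_mol, n_sites;
    rate: km_um, vmax_um_per_s [ki_um, ki_prime_um]; dose_response: ic50_um
    [top, bottom, hill]). ``noise_sd`` is in the assay's response units.
    """

    assay_kind: str
    parameters: Mapping[str, float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay_kind not in _REQUIRED_PARAMS:
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        missing = _REQUIRED_PARAMS[self.assay_kind] - set(self.parameters)
        if missing:
            raise ValueError(
                f"{self.assay_kind} truth missing parameters: {sorted(missing)}"
            )
        object.__setattr__(self, "parameters", dict(self.parameters))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def get(self, key: str, default: float | None = None) -> float:
        value = self.parameters.get(key, default)
        if value is None:
            raise KeyError(f"parameter {key!r} not in truth")
        return float(value)


def gen_melt_curve(
    truth: GroundTruth,
    temp_grid: Sequence[float] | np.ndarray = MELT_TEMP_GRID,
    replicate_id: int = 0,
    protein_label: str = "WT",
    compound_label: str = "",
    compound_conc_um: float = 0.0,
) -> MeltCurve:
    """Two-state (optionally biphasic) sigmoidal melt with Gaussian noise.

    Refuses grids shorter than 10 points (unfittable); a generating Tm
    outside the grid range is flagged in ``warnings`` on the output.
    """
    if truth.assay_kind != "melt":
        raise ValueError("truth must be a melt GroundTruth")
    t = np.asarray(temp_grid, dtype=float)
    if t.size < 10:
        raise ValueError("temperature grid must have at least 10 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    tm = truth.get("tm")
    amp = truth.get("amplitude")
    w = truth.get("width", 1.0)
    f0 = truth.get("f0", 0.0)
    slope = truth.get("baseline_slope", 0.0)
    f = f0 + slope * (t - t[0]) + amp / (1.0 + np.exp((tm - t) / w))
    warnings: list[str] = []
    if "tm2" in truth.parameters:
        tm2 = truth.get("tm2")
        amp2 = truth.get("amplitude2", amp)
        w2 = truth.get("width2", w)
        if not tm < tm2:
            raise ValueError("biphasic truth requires tm < tm2")
        f = f + amp2 / (1.0 + np.exp((tm2 - t) / w2))
        if not (t[0] <= tm2 <= t[-1]):
            warnings.append("tm2 outside temperature grid")
    if not (t[0] <= tm <= t[-1]):
        warnings.append("tm outside temperature grid")
    if truth.noise_sd > 0:
        f = f + truth.rng().normal(0.0, truth.noise_sd, size=t.size)
    return MeltCurve(
        temperature=t, fluorescence=f, replicate_id=replicate_id,
        protein_label=protein_label, compound_label=compound_label,
        compound_conc_um=compound_conc_um, warnings=tuple(warnings),
    )


def gen_quench_titration(
    truth: GroundTruth,
    concentrations_um: Sequence[float] = QUENCH_CONCENTRATIONS_UM,
    label: str = "",
) -> TitrationSeries:
    """Linear quenching series F/F0 = 1 - c/KB (clipped at zero) plus noise."""
    if truth.assay_kind != "quench":
        raise ValueError("truth must be a quench GroundTruth")
    kb = truth.get("kb_um")
    if kb <= 0:
        raise ValueError("KB must be positive")
    c = np.asarray(concentrations_um, dtype=float)
    if np.any(c < 0) or not np.any(c == 0):
        raise ValueError("concentrations must be nonnegative and include 0")
    r = np.clip(1.0 - c / kb, 0.0, None)
    if truth.noise_sd > 0:
        r = r + truth.rng().normal(0.0, truth.noise_sd, size=c.size)
    return TitrationSeries(concentration_um=c, response=r, label=label)


def gen_itc_experiment(
    truth: GroundTruth,
    cell_conc_um: float = 30.0,
    syringe_conc_um: float = 500.0,
    n_inj: int = 19,
    inj_vol_ul: float = 2.0,
    cell_vol_ul: float = 200.0,
) -> InjectionSeries:
    """One-site ITC experiment: per-injection molar heats plus noise.

    Defaults follow the screening protocol (19 injections of 2 uL of 500 uM
    titrant into 30 uM protein). A syringe concentration at or below the cell
    concentration is allowed but flagged (the titration cannot saturate).
    """
    if truth.assay_kind != "itc":
        raise ValueError("truth must be an itc GroundTruth")
    if min(cell_conc_um, syringe_conc_um, inj_vol_ul, cell_vol_ul) <= 0:
        raise ValueError("concentrations and volumes must be positive")
    heats, molar_ratio = itc_molar_heats(
        truth.get("kd_um"), truth.get("dh_kcal_per_mol"), truth.get("n_sites"),
        cell_conc_um, syringe_conc_um, n_inj, inj_vol_ul, cell_vol_ul,
    )
    warnings: tuple[str, ...] = ()
    if syringe_conc_um <= cell_conc_um:
        warnings = ("syringe concentration <= cell concentration: titration will not saturate",)
    if truth.noise_sd > 0:
        heats = heats + truth.rng().normal(0.0, truth.noise_sd, size=heats.size)
    return InjectionSeries(
        heat_kcal_per_mol=heats, molar_ratio=molar_ratio,
        cell_conc_um=cell_conc_um, syringe_conc_um=syringe_conc_um,
        inj_vol_ul=inj_vol_ul, cell_vol_ul=cell_vol_ul, warnings=warnings,
    )


def gen_rate_series(
    truth: GroundTruth,
    substrate_grid_mm: Sequence[float] | np.ndarray = SUBSTRATE_GRID_MM,
    inhibitor_concs_um: Sequence[float] = (0.0,),
    model: str = "none",
    protein_label: str = "WT",
    compound_label: str = "",
) -> list[RateSeries]:
    """Initial-rate series per inhibitor concentration from the general
    modifier Michaelis-Menten model, one RateSeries per inhibitor level."""
    if truth.assay_kind != "rate":
        raise ValueError("truth must be a rate GroundTruth")
    s_mm = np.asarray(substrate_grid_mm, dtype=float)
    if np.any(s_mm < 0):
        raise ValueError("substrate concentrations must be nonnegative")
    km = truth.get("km_um")
    vmax = truth.get("vmax_um_per_s")
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    ki = truth.get("ki_um", np.inf) if model != "none" else np.inf
    kip = truth.get("ki_prime_um", ki) if model == "mixed" else ki
    if model != "none" and not ki > 0:
        raise ValueError("Ki must be positive for inhibition models")
    rng = truth.rng()
    out: list[RateSeries] = []
    for i_um in inhibitor_concs_um:
        v = inhibited_rate(s_mm * 1e3, np.full(s_mm.size, float(i_um)), km, vmax,
                           model, ki, kip)
        if truth.noise_sd > 0:
            v = v + rng.normal(0.0, truth.noise_sd, size=v.size)
        out.append(RateSeries(
            substrate_mm=s_mm, rate_um_per_s=v, inhibitor_conc_um=float(i_um),
            protein_label=protein_label, compound_label=compound_label,
        ))
    return out


def gen_dose_response(
    truth: GroundTruth,
    concentrations_um: Sequence[float] | np.ndarray = DOSE_CONCENTRATIONS_UM,
    label: str = "",
) -> TitrationSeries:
    """Four-parameter logistic dose-response (% activity) plus noise.

    Defaults: top 100%, bottom 0%, Hill slope 1.
    """
    if truth.assay_kind != "dose_response":
        raise ValueError("truth must be a dose_response GroundTruth")
    c = np.asarray(concentrations_um, dtype=float)
    ic50 = truth.get("ic50_um")
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    top = truth.get("top", 100.0)
    bottom = truth.get("bottom", 0.0)
    hill = truth.get("hill", 1.0)
    r = np.full(c.size, top, dtype=float)
    nz = c > 0
    r[nz] = bottom + (top - bottom) / (1.0 + (c[nz] / ic50) ** hill)
    if truth.noise_sd > 0:
        r = r + truth.rng().normal(0.0, truth.noise_sd, size=c.size)
    return TitrationSeries(concentration_um=c, response=r, label=label)
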