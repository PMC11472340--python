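"""CSV readers/writers and pipeline configuration.

All tables are comma-separated UTF-8 with a mandatory header row; units are
encoded in column names (conc_uM, substrate_mM, heat_ucal). Readers validate
required columns (missing columns raise a named error), collect malformed
rows into a rejects list instead of silently dropping them, and raise on
header-only files. Generator output round-trips through these readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import InjectionSeries, TitrationSeries
from .kinetics import RateSeries
from .melt import MeltCurve
from .panel import AssayPanel

__all__ = [
    "PipelineConfig",
    "read_melt_csv",
    "write_melt_csv",
    "read_quench_csv",
    "write_quench_csv",
    "read_itc_csv",
    "write_itc_csv",
    "read_rates_csv",
    "write_rates_csv",
    "read_panel_csv",
]


class MissingColumnError(ValueError):
    pass


class EmptyFileError(ValueError):
    pass


def _load_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise EmptyFileError(f"{path}: empty file (header only)")
    return df


def _split_rejects(df: pd.DataFrame, numeric_cols: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    coerced = df.copy()
    for col in numeric_cols:
        coerced[col] = pd.to_numeric(coerced[col], errors="coerce")
    bad = coerced[numeric_cols].isna().any(axis=1)
    return coerced.loc[~bad], df.loc[bad]


# ---------------------------------------------------------------------------
# melt curves (long format)

_MELT_COLS = ("temperature", "fluorescence", "protein", "compound", "conc_uM", "replicate")


def write_melt_csv(curves: list[MeltCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "temperature": c.temperature, "fluorescence": c.fluorescence,
            "protein": c.protein_label, "compound": c.compound_label,
            "conc_uM": c.compound_conc_um, "replicate": c.replicate_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melt_csv(path: str | Path) -> tuple[list[MeltCurve], pd.DataFrame]:
    """Read long-format melt traces; returns (curves, rejected_rows)."""
    df = _load_table(path, _MELT_COLS)
    good, rejects = _split_rejects(df, ["temperature", "fluorescence", "conc_uM"])
    curves = []
    for (protein, compound, conc, rep), grp in good.groupby(
        ["protein", "compound", "conc_uM", "replicate"], dropna=False, sort=True
    ):
        grp = grp.sort_values("temperature")
        curves.append(MeltCurve(
            temperature=grp["temperature"].to_numpy(float),
            fluorescence=grp["fluorescence"].to_numpy(float),
            replicate_id=int(rep), protein_label=str(protein),
            compound_label="" if pd.isna(compound) else str(compound),
            compound_conc_um=float(conc),
        ))
    return curves, rejects


# ---------------------------------------------------------------------------
# quench / dose-response titrations

_QUENCH_COLS = ("conc_uM", "F_over_F0")


def write_quench_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame({
        "conc_uM": series.concentration_um, "F_over_F0": series.response,
    }).to_csv(path, index=False)


def read_quench_csv(path: str | Path) -> tuple[TitrationSeries, pd.DataFrame]:
    df = _load_table(path, _QUENCH_COLS)
    good, rejects = _split_rejects(df, list(_QUENCH_COLS))
    return TitrationSeries(
        concentration_um=good["conc_uM"].to_numpy(float),
        response=good["F_over_F0"].to_numpy(float),
    ), rejects


# ---------------------------------------------------------------------------
# ITC

_ITC_COLS = ("injection", "volume_uL", "heat_ucal")


def write_itc_csv(series: InjectionSeries, path: str | Path) -> None:
    """Write per-injection integrated heats (ucal) with a # key=value header
    block carrying cell/syringe concentrations and cell volume."""
    moles_injected = series.syringe_conc_um * 1e-6 * series.inj_vol_ul * 1e-6
    heat_ucal = series.heat_kcal_per_mol * moles_injected * 1e9  # kcal -> ucal
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cell_conc_uM={series.cell_conc_um}\n")
        fh.write(f"# syringe_conc_uM={series.syringe_conc_um}\n")
        fh.write(f"# cell_vol_uL={series.cell_vol_ul}\n")
        pd.DataFrame({
            "injection": np.arange(1, series.n_injections + 1),
            "volume_uL": series.inj_vol_ul,
            "heat_ucal": heat_ucal,
        }).to_csv(fh, index=False)


def read_itc_csv(path: str | Path) -> InjectionSeries:
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            header[key.strip()] = float(value)
            body_start = i + 1
        else:
            break
    for key in ("cell_conc_uM", "syringe_conc_uM", "cell_vol_uL"):
        if key not in header:
            raise MissingColumnError(f"{path}: missing header entry {key}")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    missing = [c for c in _ITC_COLS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise EmptyFileError(f"{path}: empty file (header only)")
    df = df.sort_values("injection")
    inj_vol = float(df["volume_uL"].iloc[0])
    cell, syr, v0 = header["cell_conc_uM"], header["syringe_conc_uM"], header["cell_vol_uL"]
    moles_injected = syr * 1e-6 * inj_vol * 1e-6
    heats = df["heat_ucal"].to_numpy(float) * 1e-9 / moles_injected
    from .binding import _itc_totals  # dilution bookkeeping shared with the fit

    pt, lt = _itc_totals(cell, syr, len(df), inj_vol, v0)
    return InjectionSeries(
        heat_kcal_per_mol=heats, molar_ratio=lt / pt,
        cell_conc_um=cell, syringe_conc_um=syr, inj_vol_ul=inj_vol, cell_vol_ul=v0,
    )


# ---------------------------------------------------------------------------
# rates

_RATE_COLS = ("substrate_mM", "inhibitor_uM", "rate", "protein", "compound", "replicate")


def write_rates_csv(series_list: list[RateSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "substrate_mM": s.substrate_mm, "inhibitor_uM": s.inhibitor_conc_um,
            "rate": s.rate_um_per_s, "protein": s.protein_label,
            "compound": s.compound_label, "replicate": 0,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rates_csv(path: str | Path) -> tuple[list[RateSeries], pd.DataFrame]:
    df = _load_table(path, _RATE_COLS)
    good, rejects = _split_rejects(df, ["substrate_mM", "inhibitor_uM", "rate"])
    out = []
    for (protein, compound, i_um), grp in good.groupby(
        ["protein", "compound", "inhibitor_uM"], dropna=False, sort=True
    ):
        grp = grp.sort_values("substrate_mM")
        out.append(RateSeries(
            substrate_mm=grp["substrate_mM"].to_numpy(float),
            rate_um_per_s=grp["rate"].to_numpy(float),
            inhibitor_conc_um=float(i_um), protein_label=str(protein),
            compound_label="" if pd.isna(compound) else str(compound),
        ))
    return out, rejects


# ---------------------------------------------------------------------------
# panel

def read_panel_csv(path: str | Path) -> AssayPanel:
    df = pd.read_csv(path, dtype={"compound": str, "scaffold": str})
    if df.empty:
        raise EmptyFileError(f"{path}: empty file (header only)")
    return AssayPanel(table=df)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end triage configuration; defaults match the screening
    protocol's printed choices wherever one is printed."""

    panel_csv: str = "table1"  # "table1" -> packaged fixture
    seed: int = 0
    # docking / screening thresholds
    docking_score_cutoff: float = -18.0
    clustering_threshold: float = 0.7
    # lead-selection thresholds
    kb_cutoff_um: float = 100.0
    activity_change_pct: float = 25.0
    activity_floor_pct: float = 10.0
    stability_score_min: int = 3
    require_significance: bool = True
    alpha: float = 0.05
    n_replicates: int = 3
    # assay toggles
    temperature_k: float = 293.15
    include_biphasic_variants: bool = False
    itc_drop_first_injection: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
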