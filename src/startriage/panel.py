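"""The multi-assay compound panel and the packaged 25-compound fixture.

An :class:`AssayPanel` is one row per compound carrying the triage-relevant
assay summaries: scaffold group, relative enzymatic activity (% of vehicle
control, mean +/- sd), the four per-variant thermal-stability scores
(wild type, R88C, V400M, A433E), the quenching binding constant KB (uM), and
the ITC outcome (a fitted Kd, "no binding", or "insoluble"). The packaged
fixture ships the published 25-compound characterization panel as versioned
CSV data so every downstream selection rule is runnable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SCORE_COLUMNS",
    "VARIANT_LABELS",
    "AssayPanel",
    "load_table1_fixture",
]

SCORE_COLUMNS = ("score_wt", "score_r88c", "score_v400m", "score_a433e")
VARIANT_LABELS = ("WT", "R88C", "V400M", "A433E")
_VALID_SCORES = {-4, -2, -1, 0, 1, 2, 4}

_REQUIRED = (
    "compound", "scaffold", "rel_activity_mean", "rel_activity_sd",
    *SCORE_COLUMNS, "kb_um", "itc_status",
)


@dataclass(frozen=True)
class AssayPanel:
    """Per-compound assay summary table (one row per compound)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel missing required columns: {missing}")
        if self.table["compound"].duplicated().any():
            raise ValueError("panel must have one row per compound")
        scores = self.table[list(SCORE_COLUMNS)].to_numpy()
        bad = set(np.unique(scores)) - _VALID_SCORES
        if bad:
            raise ValueError(f"invalid stability scores: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def compounds(self) -> list[str]:
        return list(self.table["compound"])

    def combined_scores(self) -> pd.Series:
        """Sum of the per-variant stability scores, indexed by compound."""
        out = self.table[list(SCORE_COLUMNS)].sum(axis=1)
        out.index = self.table["compound"]
        return out

    def kb_binders(self, cutoff_um: float = 100.0) -> list[str]:
        """Compounds whose quenching KB is strictly below the cutoff."""
        mask = self.table["kb_um"] < cutoff_um
        return list(self.table.loc[mask, "compound"])

    def kb_binder_fraction_by_scaffold(self, cutoff_um: float = 100.0) -> dict[str, float]:
        """Per-scaffold fraction of compounds with KB below the cutoff."""
        out: dict[str, float] = {}
        for scaffold, grp in self.table.groupby("scaffold", sort=True):
            out[str(scaffold)] = float((grp["kb_um"] < cutoff_um).mean())
        return out

    def stabilized_compounds(self, min_score: int = 2) -> list[str]:
        """Compounds with a stability score >= min_score for at least one
        variant (score 2 corresponds to a shift greater than 2 degC)."""
        mask = (self.table[list(SCORE_COLUMNS)] >= min_score).any(axis=1)
        return list(self.table.loc[mask, "compound"])

    def itc_kd_values(self) -> pd.Series:
        """Numeric ITC Kd values (uM), indexed by compound."""
        mask = self.table["itc_status"] == "kd"
        out = self.table.loc[mask, "itc_kd_um"].astype(float)
        out.index = self.table.loc[mask, "compound"]
        return out


def load_table1_fixture() -> AssayPanel:
    """Load the packaged 25-compound characterization panel.

    Values are shipped as package data (never fetched); relative activity was
    measured at 10 uM compound against a DMSO control (n = 3), and each
    stability score is the rubric image of the best shift over the three
    screened concentrations (10/30/100 uM).
    """
    ref = resources.files("startriage.data").joinpath("table1_panel.csv")
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, dtype={"compound": str, "scaffold": str})
    return AssayPanel(table=table)
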