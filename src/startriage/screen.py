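"""In-silico screening rules and the multi-assay lead-selection rule.

Covers the computational side of the triage cascade: pharmacophore-restraint
checking on docked poses, the docking-score cutoff and heavy-atom-normalized
ranking, drug-likeness interval filters, reactive/frequent-hitter
substructure flags, MACCS-key Tanimoto similarity with leader (sphere
exclusion) clustering and SAR-by-catalogue analogue retrieval, binding-site
geometry utilities, the LC-MS apparent-solubility formula, and the final
rule that promotes panel compounds to leads.

Poses are abstract typed feature points plus scores (docking itself is out
of scope); compound chemistry goes through RDKit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from scipy import stats

from .binding import BindingThermodynamics, QuenchFit, binding_evidence
from .kinetics import relative_activity_from_summary
from .panel import SCORE_COLUMNS, AssayPanel

__all__ = [
    "PharmacophorePoint",
    "PharmacophoreModel",
    "DockedPose",
    "CompoundRecord",
    "SiteDefinition",
    "FilterResult",
    "ClusterResult",
    "LeadCriteria",
    "LeadSelection",
    "check_pharmacophore",
    "rank_poses",
    "property_filter",
    "DEFAULT_PROPERTY_RULES",
    "load_flag_patterns",
    "substructure_flags",
    "tanimoto",
    "cluster_library",
    "sar_by_catalogue",
    "parse_residue_list",
    "load_allosteric_site",
    "site_residue_count",
    "centroid_distance",
    "solubility_from_lcms",
    "select_leads",
    "correlate_solubility_effects",
]


# ---------------------------------------------------------------------------
# pharmacophore restraints and pose ranking

@dataclass(frozen=True)
class PharmacophorePoint:
    feature_type: str  # "HBA" | "hydrophobic"
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pharmacophore radius must be positive")


@dataclass(frozen=True)
class PharmacophoreModel:
    """Typed restraint spheres; a pose must satisfy ``mandatory_count`` of
    them (the screening model: one H-bond acceptor plus three hydrophobic
    groups, all four mandatory)."""

    points: tuple[PharmacophorePoint, ...]
    mandatory_count: int

    def __post_init__(self) -> None:
        if self.mandatory_count > len(self.points):
            raise ValueError("mandatory_count cannot exceed the number of points")


@dataclass(frozen=True)
class DockedPose:
    compound_id: str
    intermolecular_score: float
    heavy_atom_count: int
    feature_coords: tuple[tuple[str, tuple[float, float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.heavy_atom_count < 1:
            raise ValueError("heavy_atom_count must be >= 1")

    @property
    def normalized_score(self) -> float:
        """Intermolecular docking score per non-hydrogen atom."""
        return self.intermolecular_score / self.heavy_atom_count


def check_pharmacophore(pose: DockedPose, model: PharmacophoreModel) -> tuple[int, bool]:
    """Count satisfied restraint points; pass iff count >= mandatory_count.

    A point is satisfied when at least one pose feature of matching type
    lies within its radius.
    """
    if not model.points:
        raise ValueError("pharmacophore model has no points")
    satisfied = 0
    for point in model.points:
        c = np.asarray(point.center, dtype=float)
        for ftype, xyz in pose.feature_coords:
            if ftype != point.feature_type:
                continue
            if np.linalg.norm(np.asarray(xyz, dtype=float) - c) <= point.radius:
                satisfied += 1
                break
    return satisfied, satisfied >= model.mandatory_count


def rank_poses(poses: Iterable[DockedPose], score_cutoff: float = -18.0) -> list[DockedPose]:
    """Keep poses with intermolecular score strictly below the cutoff and
    rank ascending by normalized (per-heavy-atom) score; ties break by
    compound id, so the ordering is invariant to input order."""
    kept = [p for p in poses if np.isfinite(p.intermolecular_score) and p.intermolecular_score < score_cutoff]
    return sorted(kept, key=lambda p: (p.normalized_score, p.compound_id))


# ---------------------------------------------------------------------------
# compound records, property filters and substructure flags

@dataclass(frozen=True)
class CompoundRecord:
    id: str
    smiles: str
    scaffold_label: str = ""
    heavy_atom_count: int = 1
    descriptors: dict[str, float] = field(default_factory=dict)
    fingerprint: np.ndarray | None = None  # MACCS keys, boolean

    @classmethod
    def from_smiles(cls, id: str, smiles: str, scaffold_label: str = "") -> "CompoundRecord":
        """Build descriptors and the MACCS fingerprint from a SMILES string.

        Descriptors: MW (Da), logP (Crippen), HBA/HBD counts, rotatable
        bonds, TPSA (A^2), and an ESOL-style logS estimate. Raises
        ValueError for unparsable structures.
        """
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {id!r}: {smiles!r}")
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        rot = Lipinski.NumRotatableBonds(mol)
        heavy = mol.GetNumHeavyAtoms()
        aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
        ap = aromatic / heavy if heavy else 0.0
        desc = {
            "MW": float(mw),
            "logP": float(logp),
            "HBA": float(Lipinski.NumHAcceptors(mol)),
            "HBD": float(Lipinski.NumHDonors(mol)),
            "rotatable_bonds": float(rot),
            "TPSA": float(rdMolDescriptors.CalcTPSA(mol)),
            # ESOL (Delaney) aqueous-solubility estimate
            "logS": float(0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rot - 0.74 * ap),
        }
        fp_bits = MACCSkeys.GenMACCSKeys(mol)
        fp = np.zeros(fp_bits.GetNumBits(), dtype=bool)
        fp[list(fp_bits.GetOnBits())] = True
        return cls(
            id=id, smiles=smiles, scaffold_label=scaffold_label,
            heavy_atom_count=heavy, descriptors=desc, fingerprint=fp,
        )


#: conventional drug-likeness intervals (inclusive bounds)
DEFAULT_PROPERTY_RULES: dict[str, tuple[float, float]] = {
    "MW": (0.0, 500.0),
    "logP": (-5.0, 5.0),
    "HBA": (0.0, 10.0),
    "HBD": (0.0, 5.0),
    "rotatable_bonds": (0.0, 10.0),
    "TPSA": (0.0, 140.0),
}


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    failed_rules: tuple[str, ...]
    unevaluated: tuple[str, ...]


def property_filter(
    compound: CompoundRecord,
    rules: Mapping[str, tuple[float, float]] = DEFAULT_PROPERTY_RULES,
    optional: Iterable[str] = (),
) -> FilterResult:
    """Interval test per descriptor; pass iff every evaluable rule passes.

    A rule whose descriptor is missing is reported as unevaluated; it only
    leaves the pass verdict unaffected when listed in ``optional``,
    otherwise the compound fails that rule.
    """
    optional = set(optional)
    failed: list[str] = []
    unevaluated: list[str] = []
    for name, (lo, hi) in rules.items():
        value = compound.descriptors.get(name)
        if value is None:
            unevaluated.append(name)
            if name not in optional:
                failed.append(name)
            continue
        if not (lo <= value <= hi):
            failed.append(name)
    return FilterResult(passed=not failed, failed_rules=tuple(failed),
                        unevaluated=tuple(unevaluated))


def load_flag_patterns() -> list[tuple[str, str, str]]:
    """Packaged (name, class, SMARTS) substructure patterns for reactive
    (REOS-style) and frequent-hitter (PAINS-style) flags."""
    ref = resources.files("startriage.data").joinpath("substructure_flags.smarts")
    patterns: list[tuple[str, str, str]] = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, cls, smarts = line.split("\t")
        patterns.append((name, cls, smarts))
    return patterns


def substructure_flags(
    compound: CompoundRecord | str,
    patterns: Sequence[tuple[str, str, str]] | None = None,
) -> list[str]:
    """Names of every flag pattern the structure matches.

    Flagging is advisory: compounds are reported, not auto-rejected.
    Unparsable structures raise ValueError (callers scanning a library
    should collect these as record-level errors and continue).
    """
    smiles = compound if isinstance(compound, str) else compound.smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure: {smiles!r}")
    if patterns is None:
        patterns = load_flag_patterns()
    flags: list[str] = []
    for name, _cls, smarts in patterns:
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            flags.append(name)
    return flags


# ---------------------------------------------------------------------------
# fingerprint similarity, clustering, analogue retrieval

def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b| in [0, 1]; two empty
    fingerprints are defined to have similarity 0."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # cluster index per input fingerprint
    leaders: tuple[int, ...]  # input index of each cluster's leader

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)


def cluster_library(
    fingerprints: Sequence[np.ndarray],
    threshold: float = 0.7,
) -> ClusterResult:
    """Leader (sphere-exclusion) clustering at a Tanimoto threshold.

    Leaders are chosen in descending order of neighbor count (ties to the
    lowest input index); every unassigned fingerprint within the threshold
    of the leader joins its cluster. Deterministic under fixed input order.
    """
    n = len(fingerprints)
    if n == 0:
        raise ValueError("need at least one fingerprint")
    sim = np.empty((n, n))
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    neighbor_counts = np.count_nonzero(sim >= threshold, axis=1)
    labels = np.full(n, -1, dtype=int)
    leaders: list[int] = []
    unassigned = set(range(n))
    while unassigned:
        leader = max(unassigned, key=lambda i: (neighbor_counts[i], -i))
        members = [i for i in unassigned if sim[leader, i] >= threshold]
        cluster_id = len(leaders)
        for i in members:
            labels[i] = cluster_id
        leaders.append(leader)
        unassigned.difference_update(members)
    return ClusterResult(labels=labels, leaders=tuple(leaders))


def sar_by_catalogue(
    hit_fps: Sequence[np.ndarray],
    library_fps: Sequence[np.ndarray],
    similarity_cutoff: float = 0.7,
) -> list[tuple[int, float]]:
    """Analogue retrieval: library entries whose best Tanimoto similarity to
    any hit reaches the cutoff, ranked by that similarity (descending; ties
    by library index)."""
    if not hit_fps:
        raise ValueError("need at least one hit fingerprint")
    out: list[tuple[int, float]] = []
    for idx, fp in enumerate(library_fps):
        best = max(tanimoto(fp, h) for h in hit_fps)
        if best >= similarity_cutoff:
            out.append((idx, best))
    return sorted(out, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# binding-site geometry

@dataclass(frozen=True)
class SiteDefinition:
    """A binding site as a list of residue labels (e.g. 'Thr109'), optionally
    with one 3-D coordinate per residue (A)."""

    residues: tuple[str, ...]
    coordinates: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("site must contain at least one residue")


_RESIDUE_RE = re.compile(r"[A-Z][a-z]{2}\s?\d+")


def parse_residue_list(text: str) -> SiteDefinition:
    """Parse a prose residue list ('Gly107, Pro108, ...') into a site."""
    residues = tuple(m.group(0).replace(" ", "") for m in _RESIDUE_RE.finditer(text))
    return SiteDefinition(residues=residues)


def load_allosteric_site() -> SiteDefinition:
    """The packaged 18-residue allosteric-site definition (full-length
    numbering), shipped as plain text."""
    ref = resources.files("startriage.data").joinpath("allosteric_site_residues.txt")
    body = "\n".join(
        ln for ln in ref.read_text(encoding="utf-8").splitlines()
        if not ln.startswith("#")
    )
    return parse_residue_list(body)


def site_residue_count(site: SiteDefinition) -> int:
    return len(site.residues)


def centroid_distance(site_a: SiteDefinition, site_b: SiteDefinition) -> float:
    """Euclidean distance (A) between the unweighted residue-coordinate
    centroids of two sites."""
    for site in (site_a, site_b):
        if not site.coordinates:
            raise ValueError("both sites need residue coordinates")
    ca = np.mean([site_a.coordinates[r] for r in site_a.residues], axis=0)
    cb = np.mean([site_b.coordinates[r] for r in site_b.residues], axis=0)
    return float(np.linalg.norm(ca - cb))


def site_from_pdb(path: str, residue_numbers: Iterable[int], chain: str = "A") -> SiteDefinition:
    """Build a SiteDefinition with C-alpha coordinates from a PDB file."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1  # noqa: F401  (validates import)

    structure = PDBParser(QUIET=True).get_structure("site", path)
    wanted = set(int(n) for n in residue_numbers)
    residues: list[str] = []
    coords: dict[str, tuple[float, float, float]] = {}
    for res in structure[0][chain]:
        num = res.get_id()[1]
        if num in wanted and "CA" in res:
            name = res.get_resname().capitalize() + str(num)
            residues.append(name)
            coords[name] = tuple(float(x) for x in res["CA"].coord)
    if not residues:
        raise ValueError("no requested residues found in PDB")
    return SiteDefinition(residues=tuple(residues), coordinates=coords)


# ---------------------------------------------------------------------------
# solubility

def solubility_from_lcms(
    area_sample: float,
    area_std: float,
    inj_vol_sample_ul: float,
    inj_vol_std_ul: float,
    dilution_factor: float,
    std_conc_um: float,
) -> float:
    """Apparent solubility from LC-MS peak areas against a standard:

        S = std_conc * (AREA_sample / AREA_std)
                     * (INJ_VOL_std / INJ_VOL_sample) * DF
    """
    if area_std <= 0:
        raise ValueError("standard peak area must be positive")
    if min(area_sample, inj_vol_sample_ul, inj_vol_std_ul) <= 0:
        raise ValueError("areas and injection volumes must be positive")
    return float(
        std_conc_um * (area_sample / area_std)
        * (inj_vol_std_ul / inj_vol_sample_ul) * dilution_factor
    )


# ---------------------------------------------------------------------------
# lead selection

@dataclass(frozen=True)
class LeadCriteria:
    """Thresholds for the multi-assay lead rule.

    A lead must show (i) an activity change exceeding ``activity_change_pct``
    relative to untreated control, significant when ``require_significance``
    is set; (ii) a summed per-variant stability score strictly above
    ``stability_score_min``; (iii) binding evidence (a numeric ITC Kd or
    quenching KB below ``kb_cutoff_um``); and (iv) residual activity of at
    least ``activity_floor_pct`` — near-total inhibitors are chaperone
    candidates in name only, so the floor keeps them out of the lead list.
    """

    activity_change_pct: float = 25.0
    require_significance: bool = True
    alpha: float = 0.05
    n_replicates: int = 3
    stability_score_min: int = 3
    kb_cutoff_um: float = 100.0
    activity_floor_pct: float = 10.0


@dataclass(frozen=True)
class LeadSelection:
    leads: tuple[str, ...]
    audit: pd.DataFrame  # per-compound criterion outcomes + failed list


_CRITERIA_COLS = ("activity_change", "activity_significant", "stability", "binding", "activity_floor")


def select_leads(panel: AssayPanel, criteria: LeadCriteria = LeadCriteria()) -> LeadSelection:
    """Apply the multi-assay lead rule to a compound panel.

    Returns the sorted lead ids plus a per-compound audit table in which
    every excluded compound lists at least one failed criterion and every
    lead lists none.
    """
    t = panel.table
    rows: list[dict[str, object]] = []
    for _, row in t.iterrows():
        mean = float(row["rel_activity_mean"])
        sd = float(row["rel_activity_sd"])
        change_ok = abs(mean - 100.0) > criteria.activity_change_pct
        act = relative_activity_from_summary(mean, sd, criteria.n_replicates, criteria.alpha)
        sig_ok = act.significant or not criteria.require_significance
        stab_ok = int(row[list(SCORE_COLUMNS)].sum()) > criteria.stability_score_min
        itc_binder = row["itc_status"] == "kd" and np.isfinite(float(row.get("itc_kd_um", np.nan) or np.nan))
        kb = float(row["kb_um"]) if np.isfinite(float(row["kb_um"])) else np.inf
        bind_ok = bool(itc_binder or kb < criteria.kb_cutoff_um)
        floor_ok = mean >= criteria.activity_floor_pct
        checks = {
            "activity_change": change_ok,
            "activity_significant": sig_ok,
            "stability": stab_ok,
            "binding": bind_ok,
            "activity_floor": floor_ok,
        }
        failed = tuple(name for name, ok in checks.items() if not ok)
        rows.append({
            "compound": row["compound"], **checks,
            "is_lead": not failed, "failed_criteria": ";".join(failed),
        })
    audit_cols = ["compound", *_CRITERIA_COLS, "is_lead", "failed_criteria"]
    audit = pd.DataFrame(rows, columns=audit_cols)
    leads = tuple(sorted(audit.loc[audit["is_lead"], "compound"]))
    return LeadSelection(leads=leads, audit=audit)


# ---------------------------------------------------------------------------
# solubility-vs-effect correlation

def correlate_solubility_effects(
    panel_table: pd.DataFrame,
    solubility_col: str,
    effect_cols: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[float | None, float | None]]:
    """Spearman rank correlation of solubility with each assay effect, with
    a seeded two-sided permutation p-value; constant columns are reported as
    undefined (None, None). Requires >= 5 complete pairs per column."""
    rng = np.random.default_rng(seed)
    sol_all = panel_table[solubility_col].to_numpy(dtype=float)
    out: dict[str, tuple[float | None, float | None]] = {}
    for col in effect_cols:
        eff_all = panel_table[col].to_numpy(dtype=float)
        mask = np.isfinite(sol_all) & np.isfinite(eff_all)
        sol, eff = sol_all[mask], eff_all[mask]
        if sol.size < 5:
            raise ValueError(f"need >= 5 complete rows for {col!r}")
        if np.ptp(sol) == 0 or np.ptp(eff) == 0:
            out[col] = (None, None)
            continue
        rho_obs = float(stats.spearmanr(sol, eff).statistic)
        count = 0
        for _ in range(n_permutations):
            rho_perm = stats.spearmanr(sol, rng.permutation(eff)).statistic
            if abs(rho_perm) >= abs(rho_obs) - 1e-12:
                count += 1
        out[col] = (rho_obs, (count + 1) / (n_permutations + 1))
    return out
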