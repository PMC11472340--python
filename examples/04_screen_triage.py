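"""Docking-stage triage: pharmacophore restraints, score ranking, filters,
fingerprint clustering.

Builds a tiny compound library from SMILES, checks abstract docked poses
against a four-point pharmacophore (one H-bond acceptor + three hydrophobic
spheres, all mandatory), applies the -18.0 docking-score cutoff with
per-heavy-atom normalization, and clusters the survivors by MACCS Tanimoto
similarity.
"""

from startriage import (
    CompoundRecord,
    DockedPose,
    PharmacophoreModel,
    PharmacophorePoint,
    check_pharmacophore,
    cluster_library,
    rank_poses,
    tanimoto,
)
from startriage.screen import property_filter, substructure_flags

model = PharmacophoreModel(
    points=(
        PharmacophorePoint("HBA", (0.0, 0.0, 0.0), 1.5),
        PharmacophorePoint("hydrophobic", (3.0, 0.0, 0.0), 2.0),
        PharmacophorePoint("hydrophobic", (0.0, 3.0, 0.0), 2.0),
        PharmacophorePoint("hydrophobic", (0.0, 0.0, 3.0), 2.0),
    ),
    mandatory_count=4,
)

library = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "naphthol": "Oc1ccc2ccccc2c1",
    "nitro": "O=[N+]([O-])c1ccccc1O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}
records = [CompoundRecord.from_smiles(cid, smi) for cid, smi in library.items()]

poses = []
for r, score in zip(records, (-20.5, -19.0, -18.4, -16.0)):
    feats = [(p.feature_type, p.center) for p in model.points]
    if r.id == "caffeine":  # one hydrophobic group drifted out of its sphere
        feats[-1] = ("hydrophobic", (0.0, 0.0, 8.0))
    poses.append(DockedPose(r.id, score, r.heavy_atom_count, tuple(feats)))
for pose in poses:
    count, ok = check_pharmacophore(pose, model)
    print(f"{pose.compound_id:>9}: {count}/4 restraints, pass={ok}")

ranked = rank_poses(poses, score_cutoff=-18.0)
print("ranked survivors (score < -18, by per-atom score):",
      [(p.compound_id, round(p.normalized_score, 2)) for p in ranked])

for r in records:
    flags = substructure_flags(r)
    verdict = property_filter(r)
    print(f"{r.id:>9}: drug-like={verdict.passed} flags={flags or 'none'}")

fps = [r.fingerprint for r in records]
clusters = cluster_library(fps, threshold=0.7)
print(f"{clusters.n_clusters} clusters at Tanimoto 0.7; "
      f"aspirin~naphthol similarity = {tanimoto(fps[0], fps[1]):.2f}")
print("-> hits passing restraints and filters are clustered so each chemical")
print("   series is represented before compounds are purchased and assayed.")
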