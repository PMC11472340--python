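"""The full panel-to-leads step on the packaged 25-compound panel.

Loads the packaged characterization panel (relative activity, per-variant
stability scores, quenching KB, ITC Kd), reproduces the triage counts, and
applies the multi-assay lead rule.
"""

from startriage import PipelineConfig, load_table1_fixture, run_pipeline, select_leads

panel = load_table1_fixture()
print(f"panel: {len(panel)} compounds")
print(f"KB < 100 uM binders: {len(panel.kb_binders())}")
print(f"stabilized (>2 degC for >=1 variant): {len(panel.stabilized_compounds())}")
print(f"single-digit-uM ITC Kd: {int((panel.itc_kd_values() < 10).sum())}")

selection = select_leads(panel)
print(f"leads: {', '.join(selection.leads)}")
excluded = selection.audit[~selection.audit["is_lead"]]
print("example exclusions:")
for _, row in excluded.head(3).iterrows():
    print(f"  {row['compound']}: failed {row['failed_criteria']}")

# the same thing end-to-end, with report output
report = run_pipeline(PipelineConfig())
print("stage counts:", report.stage_counts)
print("-> a lead must change activity by >25% (significantly), sum stability")
print("   scores above 3, show binding evidence, and keep >=10% residual")
print("   activity; the audit trail records why each compound was excluded.")
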