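"""Does the window length matter?

Repeats the subject and group analysis for windows of 6, 8 and 10 TRs
on the same cohort and compares the condition ordering of group-mean
integration — the qualitative result should not depend on L.
"""

import dynconn as dc

cohort = dc.simulate_cohort(dc.study_cohort_specs(n_subjects=6, seed=12))
config = dc.PipelineConfig(n_perm=200, seed=12)

out = dc.run_sensitivity(cohort, config, lengths=(6, 8, 10))

print("group-mean integration (nats) per window length:")
print(out["integration_table"].round(3).to_string(index=False))
for L, ordering in sorted(out["orderings"].items()):
    print(f"L={L:2d}: {' < '.join(ordering)}")
print("condition ordering identical across lengths:",
      out["ordering_agreement"])
# Absolute levels shrink as L grows (longer windows average more
# volumes, reducing the small-sample upward bias of log-det
# integration), but the before > during > after > baseline ordering is
# the planted, L-independent structure.
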