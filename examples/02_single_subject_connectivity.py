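"""One subject through the full estimation chain.

Tapered windows around each discharge -> weighted window covariances ->
cross-validated graphical-lasso penalty -> per-window sparse precision
fits -> Fisher-z -> condition-mean matrices -> graph metrics.
"""

import numpy as np

import dynconn as dc

spec = dc.study_cohort_specs(1, seed=3)[0]
series, events = dc.simulate_subject(spec)

result = dc.run_subject(series, events, dc.PipelineConfig())

print(f"subject {result.subject_id}: {result.n_valid_events} valid events, "
      f"{sum(result.window_counts.values())} windows")
print(f"cross-validated penalty lambda = {result.lambda_selected:.4f} "
      f"({result.n_nonconverged_fits} non-converged window fits)")

print("\nestimated network integration (nats) per condition:")
for cond in dc.CONDITIONS:
    print(f"  {cond:>8}: {result.metric_sets[cond].integration:.3f}")
# Values sit above the planted population levels (log-det estimates from
# 8-sample windows are upward-biased) but their ordering reflects the
# planted decaying elevation: before > during > after > baseline.

ms = result.metric_sets["before"]
top = np.argsort(ms.strength)[::-1][:3]
print("\nstrongest nodes before the discharge (signed strength):")
for i in top:
    print(f"  region {i:2d}: strength {ms.strength[i]:.2f}, "
          f"clustering {ms.clustering[i]:.2f}")
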