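"""Export a condition-difference graph for BrainNet Viewer.

Writes the text .node/.edge pair (MNI coordinates, node sizes, edge
weight matrix) that BrainNet Viewer renders on a glass brain.
"""

from pathlib import Path

import numpy as np

import dynconn as dc

spec = dc.study_cohort_specs(1, seed=5)[0]
series, events = dc.simulate_subject(spec)
result = dc.run_subject(series, events)

# difference of tanh-backtransformed condition matrices (correlation scale)
diff = (np.tanh(result.condition_matrices["before"].matrix)
        - np.tanh(result.condition_matrices["baseline"].matrix))

table = dc.load_region_table()
out = Path("scratch_brainnet")
out.mkdir(exist_ok=True)
dc.export_brainnet(
    diff, table,
    node_path=out / "before_minus_baseline.node",
    edge_path=out / "before_minus_baseline.edge",
    node_sizes=np.abs(diff).sum(axis=1),
)
print(f"wrote {out / 'before_minus_baseline.node'} (14 regions: "
      "x y z color size label)")
print(f"wrote {out / 'before_minus_baseline.edge'} (14 x 14 weights)")
print(f"mean edge difference: {diff[np.triu_indices(14, 1)].mean():+.3f} "
      "(positive = stronger coupling before the discharge)")
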