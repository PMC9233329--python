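"""Generate a balanced incomplete block design for best-worst scaling tasks.

Builds three questionnaire versions of 16 tasks, each showing 6 of the 16
OxCAP-MH items, and reports the balance achieved: every item should appear
r = 6 times per version, and ideally every pair of items co-occurs
lambda = 2 times (pair variance 0, the (16, 6, 2) biplane).
"""

import numpy as np

import capbws as cb

design = cb.generate_design(
    n_items=16, set_size=6, n_tasks=16, n_versions=3, n_iterations=30, seed=7
)
report = cb.validate_design(design)

params = cb.bibd_parameters(16, 6, 16)
print(f"target replication r = {params['r']:g}, "
      f"pair co-occurrence lambda = {params['lambda']:g}")
for v in range(1, design.n_versions + 1):
    freqs = np.unique(report.item_frequencies[v - 1])
    print(
        f"version {v}: item frequencies {freqs.tolist()}, "
        f"pair variance {report.pair_variance(v):.3f}, "
        f"strict BIBD: {bool(report.is_bibd[v - 1])}"
    )
print("\nfirst three tasks of version 1 (1-based item numbers):")
print(design.tasks(1)[:3])
# Pair variance 0 means every pair of items appears together exactly twice,
# so no item comparison is over- or under-represented in the questionnaire.
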