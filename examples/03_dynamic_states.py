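"""Sliding-window dynamic FNC: states, fraction time, dwell time.

Windows of 22 TRs (44 s) tapered by a 3-TR Gaussian slide in 1-TR steps
over each subject's conditioned time courses; each window yields a sparse
partial-correlation matrix (graphical lasso, penalty chosen per subject by
cross-validation), and all windows are clustered with Manhattan-distance
k-means. State 1 is the most frequent state by convention.
"""

import warnings

import numpy as np

from dfnckit import cluster_windows, temporal_properties, windowed_connectivity
from dfnckit.dynamic import WindowSpec, state_entry_percentage
from dfnckit.pipeline import RunConfig, _preprocess_subject, scaled_cohort_config
from dfnckit.synth import default_ground_truth, simulate_cohort_dataset

warnings.simplefilter("ignore")

rc = RunConfig(subjects_per_group=5, n_timepoints=240)
cohort, tcs, _, truth = simulate_cohort_dataset(
    scaled_cohort_config(5), default_ground_truth(), n_timepoints=240, seed=9)

spec = WindowSpec()
print(f"window {spec.width_tr} TR = {spec.width_seconds:.0f} s, "
      f"taper sigma {spec.taper_sigma_tr:.0f} TR = {spec.taper_seconds:.0f} s")

rng = np.random.default_rng(0)
windowed = [windowed_connectivity(_preprocess_subject(tcs[s], rc), spec, seed=rng)
            for s in cohort.subject_id]
print(f"{len(windowed)} subjects x {windowed[0].n_windows} windows, "
      f"median selected lambda {np.median([w.lambda_selected for w in windowed]):.3f}")

model = cluster_windows(windowed, k=3, seed=1)
tp = temporal_properties(model, spec)
groups = dict(zip(cohort.subject_id, cohort.group))

summary = tp.per_state.assign(group=lambda d: d.subject.map(groups))
print("\ngroup-mean fraction time per state:")
print(summary.groupby(["group", "state"]).fraction_time.mean()
      .unstack().round(2).to_string())
print("\nsubjects entering each state (%):")
print(state_entry_percentage(model.assignments, groups, k=3)
      .pivot(index="group", columns="state", values="entry_pct").round(0).to_string())
print("\nRecovered states are numbered by pooled frequency (State 1 = most")
print("frequent). Healthy females concentrate in a different state than the")
print("other three groups, reflecting the planted occupancy shift.")
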