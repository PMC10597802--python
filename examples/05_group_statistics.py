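"""Covariate-adjusted group statistics, Mann-Whitney tests and ROC.

Demonstrates the inference layer on a synthetic cohort: static FNC entries
are compared between the four groups with age, mean framewise displacement
and site as covariates (BH-FDR within each contrast); State 1 temporal
metrics are compared with Mann-Whitney U tests; and the State 1 fraction
time is scored as a diagnostic marker for female patients with ROC/AUC.
"""

import warnings

from dfnckit.pipeline import RunConfig, run_pipeline

warnings.simplefilter("ignore")
bundle = run_pipeline(RunConfig(seed=3, subjects_per_group=10,
                                n_timepoints=240, n_components=8))

st = bundle["sfnc_tests"]
print("significant adjusted sFNC differences per contrast (of "
      f"{st.outcome_id.nunique()} pairs):")
print(st.groupby("contrast").significant.sum().to_string())

tt = bundle["temporal_tests"]
focus = tt[(tt.contrast == "RRMS-F vs HC-F") & (tt.state == 1)]
print("\nState 1 temporal metrics, female patients vs female controls:")
print(focus[["metric", "median_a", "median_b", "U", "p"]]
      .round(4).to_string(index=False))

for name, roc in bundle["roc"].items():
    lo, hi = roc.ci
    print(f"\nROC {name}: AUC = {roc.auc:.3f} (95% bootstrap CI {lo:.3f}-{hi:.3f})")
print("\nThe planted occupancy shift makes State 1 fraction time a strong")
print("discriminator of female patients. The male patient-vs-control sFNC")
print("differences reflect the planted strength reduction; the female-contrast")
print("differences are the static footprint of the occupancy shift.")
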