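"""Patient-level classification of a planted-effect synthetic cohort.

Simulates a control-vs-tumor feature cohort (tumor nuclei 1.3x larger,
1.2x more heterochromatin, 1.5x the foci rate), prunes correlated
features, runs leave-one-patient-out random-forest classification with a
label-permutation null, and prints the biomarker rankings.
"""

from chromascope import (
    RFConfig,
    gini_ranking,
    lopo_cv_rfc,
    patient_majority_vote,
    permutation_baseline,
    prune_correlated,
    simulate_feature_cohort,
    welch_screen_bh,
)

table = simulate_feature_cohort(
    n_patients_per_condition=5, cells_per_patient=80,
    condition_effects={"tumor": {"volume": 1.3, "hc_fraction": 1.2, "foci_rate": 1.5}},
    n_noise_features=20, seed=23,
)
pruned, removed = prune_correlated(table)
print(f"cohort: {len(pruned)} cells, {pruned['patient_id'].nunique()} patients; "
      f"{len(removed)} correlated features removed")

rf = RFConfig(n_estimators=60)
cv = lopo_cv_rfc(pruned, rf=rf, seed=23)
vote = patient_majority_vote(cv)
null = permutation_baseline(pruned, n_perm=10, rf=rf, seed=23, real_cv=cv)

print(f"balanced accuracy (cell level): {cv.mean_score:.3f} +/- {cv.sd_score:.3f}")
print(f"patient-level majority-vote accuracy: {vote['correct'].mean():.2f}")
print(f"permutation null: {null.null_mean:.3f} (Wilcoxon p = {null.p_value:.2g})")

print("\ntop-5 Gini importances:")
print(gini_ranking(cv, top_n=5).round(4).to_string(index=False))

screen = welch_screen_bh(pruned)
print(f"\nWelch/BH-significant features: {screen.significant_features}")

# The cell-level accuracy should clearly exceed the ~0.5 permutation
# null, and both biomarker strategies should converge on the three
# planted-effect features (volume, HC fraction, foci count).
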