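"""Correlation analysis and mean-absolute-correlation (MAC) elimination.

Indices built from five shared bands are massively collinear: most of the
465 pairwise correlations exceed |r| = 0.8. The MAC filter repeatedly
takes the most correlated surviving pair and discards the member with the
larger mean absolute correlation, leaving a small, weakly correlated
predictor set (canopy cover and plant height are kept unconditionally).
"""

from uavbiomass import filtering, indices, pipeline, synthetic

trial = synthetic.make_trial(synthetic.default_calibration_design(seed=42))
table = pipeline.build_predictor_table(trial)

names = indices.default_registry().names
report = filtering.correlation_report(table, names)
high = sum(abs(r) > 0.8 for _, _, r, _ in report.pairs())
print(f"{report.n_pairs} unique pairs among {len(names)} indices; "
      f"{high} exceed |r| = 0.8")

result = filtering.select_predictors(table, names, cutoff=0.8)
print(f"retained predictors: {', '.join(result.retained)}")
print(f"eliminations: {len(result.log)} (first: "
      f"{result.log[0].pair} r={result.log[0].r:+.3f} -> removed {result.log[0].removed})")
print()
print("The surviving indices carry non-redundant spectral information;")
print("every removed one was an |r|>0.8 near-copy of something kept.")
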