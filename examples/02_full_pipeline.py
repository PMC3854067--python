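"""Full analysis of a marker-coupled (RIM1alpha-like) experiment.

Simulates a 500-bouton field whose marker content is linearly coupled to
vesicular release efficiency, runs the complete pipeline (segmentation,
kinetic quality control, rolling-ball background subtraction, channel
alignment, edge-ROI removal, immunoreactivity quantification,
normalization, grouping, kinetics, group statistics), and prints the
stratified result: boutons with high marker content should unload more.
"""

from fmposthoc import PipelineConfig, SimulationConfig, run_pipeline, simulate_experiment

config = SimulationConfig(seed=7, n_boutons=500, image_shape=(512, 512), marker_slope=1.0)
stack, marker_a, marker_b, truth = simulate_experiment(config)

result = run_pipeline(stack, {"marker_a": marker_a, "marker_b": marker_b}, PipelineConfig())

meta = result.metadata
print(f"candidate ROIs:        {meta['n_candidate_rois']}")
print(f"quality-passing:       {meta['n_quality_passed']}")
print(f"after edge removal:    {meta['n_final_rois']}")
print(f"recovered shifts (px): {meta['shifts_px']}  (planted {truth.channel_shift_px})")
qc = meta["linearity_qc"]
print(f"two-channel linearity: slope {qc['slope']:.3f}, r {qc['pearson_r']:.3f} "
      f"-> {'valid' if qc['passed'] else 'INVALID'} experiment")
print()
print("unloaded fraction by marker-A group (mean +/- SEM):")
s = result.summary
for group in ("whole", "high", "low"):
    print(f"  {group:>5}: {s.unloaded_pct_mean[group]:5.2f} +/- "
          f"{s.unloaded_pct_sem[group]:4.2f} %   (n = {s.group_n[group]})")
print()
print(f"one-way ANOVA (whole/high/low): F = {s.anova_f:.2f}, p = {s.anova_p:.2e}")
print(s.pairwise.to_string(index=False))
print()
print("a high > whole > low ordering with a significant ANOVA is the")
print("signature of marker content stratifying release efficiency")
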