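"""Null-marker (Munc13-1-like) control: no planted coupling, no effect.

With marker_slope = 0 the marker level carries no information about
release efficiency, so the high- and low-IR groups should unload like the
whole population and the ANOVA should stay non-significant (at the 5%
false-positive rate).
"""

from fmposthoc import SimulationConfig, run_pipeline, simulate_experiment

config = SimulationConfig(seed=8, n_boutons=500, image_shape=(512, 512), marker_slope=0.0)
stack, marker_a, marker_b, _ = simulate_experiment(config)
result = run_pipeline(stack, {"marker_a": marker_a, "marker_b": marker_b})

s = result.summary
for group in ("whole", "high", "low"):
    print(f"{group:>5}: {s.unloaded_pct_mean[group]:5.2f} +/- "
          f"{s.unloaded_pct_sem[group]:4.2f} %   (n = {s.group_n[group]})")
print(f"ANOVA p = {s.anova_p:.3f} -> "
      f"{'no' if s.anova_p >= 0.05 else 'spurious'} group difference, as planted")
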