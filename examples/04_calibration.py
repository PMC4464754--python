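"""Calibrating the kill model to per-section histology data.

Generates the study-shaped 11-point kill dataset (5 drug-sensitive + 6
drug-resistant sections), rescales the resistant points by the in-vitro
ratio, and fits the two free parameters by bounded multistart least squares.
"""

from killfrac import (
    SyntheticConfig,
    fit_kill_model,
    generate_kill_dataset,
    rescale_resistant,
)

config = SyntheticConfig(seed=42)
data, truth = generate_kill_dataset(config)
print(f"dataset: {len(data.points)} per-section (BVF, dead-fraction) points")
print(f"true parameters: fkill_m={truth['true_fkill_m']}, "
      f"r_b/L={truth['true_rb_over_L']}")

pooled = rescale_resistant(data, config.kill_ratio)
result = fit_kill_model(pooled, seed=42)
print(f"\nfitted  fkill_m = {result.fkill_m_hat:.3f}")
print(f"fitted  r_b/L   = {result.rb_over_L_hat:.3f}")
print(f"R^2             = {result.r_squared:.3f}")
print(f"converged       = {result.converged} "
      f"({len(result.restart_costs)} restarts)")

noiseless, _ = generate_kill_dataset(SyntheticConfig(seed=42, dead_noise_sd=0.0))
exact = fit_kill_model(rescale_resistant(noiseless, 3.5), seed=42)
print(f"\nnoiseless check: fkill_m={exact.fkill_m_hat:.6f}, "
      f"r_b/L={exact.rb_over_L_hat:.6f}, R^2={exact.r_squared:.6f}")
print("\nWith measurement noise the estimates scatter around the truth;")
print("without it the fit recovers both parameters exactly (R^2 = 1).")
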