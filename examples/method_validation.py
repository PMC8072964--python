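"""Method-validation computations on a synthetic fixture.

Builds calibration curves and spiked triplicates (2.5, 5.0 and 50 µg/g in
tobacco and filter-tip matrix), then computes the validation metrics: OLS
calibration with the R² > 0.999 linearity gate, signal-to-noise detection
limits, spike recovery and relative standard deviation with the < 10% gate.
"""

from flavorisk import fit_calibration, lod_loq_from_noise, recovery_pct, rsd_pct
from flavorisk.synthetic import ValidationFixtureConfig, generate_validation_fixture

calib, spikes = generate_validation_fixture(
    ValidationFixtureConfig(recovery_bias=0.95, noise_cv=0.03), seed=7
)

one = calib[calib["compound"] == "Menthol"]
curve = fit_calibration(one["level_ng_per_ml"], one["response"], "Menthol")
print(
    f"menthol calibration: slope={curve.slope:.4f} "
    f"R²={curve.r_squared:.6f} passes_linearity={curve.passes_linearity}"
)

lod, loq = lod_loq_from_noise(noise_level=1.0, slope=curve.slope)
print(f"S/N detection limits at unit baseline noise: LOD={lod:.3f} "
      f"LOQ={loq:.3f} ng/mL (LOQ/LOD = 10/3 by definition)")

print("\nspike recovery and precision (menthol, tobacco matrix):")
m = spikes[(spikes["compound"] == "Menthol") & (spikes["matrix"] == "tobacco")]
for spike, grp in m.groupby("spike_ug_per_g"):
    vals = grp["measured_ug_per_g"]
    print(
        f"  {spike:5.1f} µg/g: recovery={recovery_pct(vals.mean(), spike):6.1f}% "
        f"RSD={rsd_pct(vals):.2f}% (n={len(vals)})"
    )
print(
    "\nRecovery near the configured 95% bias and RSD near the configured 3%"
    "\nnoise confirm the fixture drives the metrics as designed; real data"
    "\nare accepted when recovery is ~80–110% and RSD < 10%."
)
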