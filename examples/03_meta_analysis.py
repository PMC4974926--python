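"""Combining a path coefficient across bee species.

Seven species each yield an estimate of the stability effect on mean
brood cells per nest, from different numbers of sites.  The estimates
are Fisher-z transformed, weighted by w = N - 3, and averaged; a
percentile bootstrap over species (resampling with replacement 100,000
times) gives the 95% interval.  An interval excluding zero indicates a
consistent cross-species effect.
"""

from beesem import MetaInput, bootstrap_ci, weighted_mean_z

species_estimates = [
    ("Anthidium-like sp. 1", -0.42, 12),
    ("Anthidium-like sp. 2", -0.10, 9),
    ("Anthidium-like sp. 3", -0.31, 11),
    ("Megachile-like sp. 1", -0.25, 14),
    ("Megachile-like sp. 2", -0.05, 13),
    ("Trichothurgus-like sp.", -0.38, 8),
    ("Xylocopa-like sp.", -0.18, 14),
]
inputs = [MetaInput(name, r, n) for name, r, n in species_estimates]

z_w = weighted_mean_z(inputs)
result = bootstrap_ci(inputs, B=100_000, seed=7)

print("species  r  N  z  weight")
for i in inputs:
    print(f"  {i.species:24s} {i.r:+.2f}  {i.N:2d}  {i.z:+.3f}  {i.weight:.0f}")
print(f"\nweighted mean z = {z_w:.4f} (r = {result.r_mean:+.4f})")
print(f"95% percentile bootstrap CI for z: "
      f"[{result.ci_lower:.4f}, {result.ci_upper:.4f}]  "
      f"(B = {result.B:,}, seed = {result.seed})")
if result.ci_upper < 0:
    print("The interval lies below zero: the negative stability effect "
          "is consistent across species.")
else:
    print("The interval includes zero: no consistent cross-species effect.")
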