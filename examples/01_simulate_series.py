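"""Generate a small synthetic Laue pseudo-rotation series with ground truth.

Builds the reference experiment (orthorhombic 34/45/99 A crystal, pink beam
with a 5.5% FWHM Gaussian spectrum around 1.05 A, one panel at 200 mm) and
forward-models ten 1-degree stills with realistic mosaic spread, beam
divergence, and centroid noise.
"""

import numpy as np

import pinklaue as pl

experiment = pl.reference_experiment(n_images=10)
config = pl.reference_config(n_images=10, seed=42)
observed, truth = pl.generate_series(experiment, config)

print(f"images:                {experiment.n_images}")
print(f"observed strong spots: {len(observed)}  (~{len(observed) / 10:.0f}/image)")
print(f"ground-truth members:  {len(truth)}")
print(f"harmonic stack rows:   {int(truth['is_harmonic_member'].sum())}")
lam = truth["lambda_true"]
print(f"wavelength range:      {lam.min():.3f} - {lam.max():.3f} A")
d = truth["d_true"]
print(f"resolution range:      {d.min():.2f} - {d.max():.2f} A")

# Each observed row is what a spot finder would report (centroid, intensity);
# each truth row records which reciprocal-lattice point produced it, at which
# wavelength, and where it would have landed without noise.
print("\nfirst observed spots:")
print(observed.head(3).to_string(index=False))
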