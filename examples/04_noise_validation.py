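"""Validate the classifier by perturbing atom coordinates with Gaussian noise.

Leave-one-out cross-validation destroys the covariance structure of small
ligand groups, so robustness is probed instead by simulation: every atom
coordinate is shifted by N(0, τ²) noise, the perturbed sites are re-encoded
and classified against the ORIGINAL models, and the error is tracked over a
grid of τ values (Å).  The error should rise with τ — by τ ≈ 1 Å the
perturbation is large against the 5.3 Å site radius.
"""

import warnings

import numpy as np

import cdpa
from cdpa.robustness import NoiseConfig, run_noise_validation

warnings.filterwarnings("ignore")

dataset = cdpa.make_preset_dataset("default", seed=1)
vectors = cdpa.encode_sites(dataset.sites)
models = cdpa.fit_group_models(vectors, dataset.labels)

config = NoiseConfig(
    tau_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    replications=20,  # the full protocol uses 100; 20 keeps this demo quick
    seed=1,
)
experiment = run_noise_validation(dataset.sites, models, config)

print("tau (Å)   mean error   95% band")
for tau, m, lo, hi in zip(
    config.tau_grid, experiment.mean_curve, experiment.band_low, experiment.band_high
):
    print(f"  {tau:4.1f}      {m:6.3f}     [{lo:.3f}, {hi:.3f}]")

print("\nThe mean error rises with the noise level: small perturbations leave")
print("classification nearly intact, while Å-scale noise erodes the sites'")
print("second-order structure that the descriptor encodes.")

# render the curve like the published validation figures
from cdpa.plotting import plot_noise_curve

plot_noise_curve(experiment, path="noise_curve.png")
print("wrote noise_curve.png")
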