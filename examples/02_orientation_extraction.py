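"""Extracting structural parameters from an orientation intensity plot.

Renders a synthetic collagen-orientation map (depth x angle) with known
mean fibre angle and in-plane dispersion, then recovers both by the
maximum-likelihood pi-periodic von Mises fit.  The printed errors show
the binning/extraction accuracy of the imaging pipeline.
"""

import numpy as np

from artmech.imaging import angular_marginal, fit_fibre_distribution
from artmech.synthdata import CohortConfig, render_intensity_plot, sample_ground_truth

rng = np.random.default_rng(5)
config = CohortConfig(seed=5)
truth = sample_ground_truth(config, rng, sample_id="demo")
plot = render_intensity_plot(truth, config, rng)

fit = fit_fibre_distribution(angular_marginal(plot))
print(f"true  alpha = {np.rad2deg(truth.alpha):6.2f} deg, "
      f"kappa_ip = {truth.kappa_ip:.4f}")
print(f"fitted alpha = {fit.alpha_deg:6.2f} deg, "
      f"kappa_ip = {fit.kappa_ip:.4f} (concentration a = {fit.concentration:.3f})")
print(f"errors: {abs(fit.alpha_deg - np.rad2deg(truth.alpha)):.3f} deg, "
      f"{abs(fit.kappa_ip - truth.kappa_ip):.4f}")
print("\n(the small kappa_ip bias comes from the waviness of the fibre "
      "angle over depth, which broadens the depth-averaged distribution)")
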