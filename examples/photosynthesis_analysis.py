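"""Microsensor physiology: O2 flux, light-dark shift and PI curves.

Builds synthetic microsensor data (an O2 depth microprofile across the
diffusive boundary layer, a darkening time series, and photosynthesis rates
at the experiment's four irradiance levels) and runs the standard analyses.
"""

import numpy as np

from coralight import phantoms, physiology as phys
from coralight.phantoms import PhantomConfig

# net photosynthesis from the linear O2 gradient in the DBL (Fick's law)
profile = phantoms.make_o2_profile(J=0.25, config=PhantomConfig(seed=3, noise_rel=0.01))
flux = phys.diffusive_flux(profile)
print(f"net O2 flux: {flux.J:.3f} +- {flux.J_err:.3f} nmol O2 cm^-2 s^-1 "
      f"(truth 0.25; linear window {flux.window_um} um, R^2={flux.r_squared:.3f})")
print("positive flux = O2 leaving the tissue surface = net photosynthesis")

# gross photosynthesis by the light-dark shift
t = np.arange(0.0, 10.0, 0.05)
conc = np.where(t < 5.0, 250.0, 250.0 - 0.8 * (t - 5.0))
conc += np.random.default_rng(4).normal(0, 0.05, t.size)
rate, se = phys.gross_photosynthesis(t, conc, darkening_time=5.0)
print(f"gross photosynthesis (initial O2 decline after darkening): "
      f"{rate:.3f} +- {se:.3f} umol L^-1 s^-1 (truth 0.8)")

# photosynthesis-irradiance curve at the experiment's light levels
pi_df = phantoms.make_pi_data(
    Pmax=2.0, Ek=150.0, config=PhantomConfig(seed=5, noise_rel=0.05), replicates=3
)
fit = phys.fit_pi_curve(pi_df["rate"], pi_df["irradiance"])
print(f"PI fit: Pmax = {fit.Pmax:.2f} (truth 2.0), "
      f"Ek = {fit.Ek:.0f} umol photons m^-2 s^-1 (truth 150)")
print("Ek is the irradiance where the curve reaches 63% of saturation.")
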