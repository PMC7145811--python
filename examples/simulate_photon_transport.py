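"""Monte Carlo photon transport through the bionic-coral layer stack.

Simulates a collimated beam entering a 1 mm forward-scattering tissue layer
printed on a 1 mm diffusely backscattering skeleton layer, both immersed in
seawater, and compares the scalar-irradiance (fluence-rate) depth profile
against a non-scattering slab with the same algal density.
"""

import numpy as np

from coralight.geometry import LayeredSlab
from coralight.materials import WATER_N, gelma, skeleton, tissue
from coralight.mc_transport import fluence_depth_profile, simulate, tpsf_snapshot

two_layer = LayeredSlab(
    [(tissue(5e6), 1.0), (skeleton(), 1.0)], n_above=WATER_N, n_below=WATER_N
)
clear_slab = LayeredSlab([(gelma(5e6), 1.0)], n_above=WATER_N, n_below=WATER_N)

res = simulate(two_layer, n_photons=200_000, seed=42)
ref = simulate(clear_slab, n_photons=200_000, seed=43)

print("two-layer energy partition:")
print(f"  transmitted {res.T_total:.3f}  reflected {res.R_total:.3f}  "
      f"absorbed {res.A_total:.3f}")

prof = fluence_depth_profile(res)
prof_ref = fluence_depth_profile(ref)
for depth in (0.1, 0.5, 0.75, 1.0):
    e0 = np.interp(depth, prof.depth_mm, prof.values)
    e0r = np.interp(depth, prof_ref.depth_mm, prof_ref.values)
    print(f"  E0 at {depth*1000:4.0f} um: {e0:6.1f}% of E_d   "
          f"(clear slab {e0r:5.1f}%, ratio {e0/e0r:.2f})")
print("E0 > 100% means the diffused light field delivers more photons to a")
print("point than the incident collimated beam would - the photon-trapping")
print("effect the layered design is built for.")

snap = tpsf_snapshot(res, 0.05)
print(f"fluence in the 0.05-0.10 ns time gate peaks at "
      f"{snap.depth_mm[np.argmax(snap.values)]*1000:.0f} um depth - "
      "late-arriving photons are the multiply scattered ones lingering deep")
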