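"""Helix splay profile of a synthetic six-helix carrier bundle.

Builds a bundle whose helices stand on a 20 Å circle, computes the
R_XY(z) profile (in-plane radius of gyration of the per-helix mean CA
positions in a running 12 Å window) and compares it with the generator's
closed-form truth.  A flat profile at the circle radius means the bundle
is a straight cylinder; real carriers funnel open toward one side, which
shows up as R_XY rising on that side.
"""

import numpy as np

from carriermd import BundleSpec, generate_bundle_trajectory, helix_splay_profile

bundle = generate_bundle_trajectory(BundleSpec(radius=20.0, noise_sd=0.3,
                                               seed=1))
profile = helix_splay_profile(bundle.topology, bundle.frames,
                              bundle.truth.helix_ranges)

print("   z (Å)   R_XY (Å)   truth (Å)")
for z, value, truth in zip(profile.z_grid[::5], profile.values[::5],
                           bundle.truth.splay_r_xy[::5]):
    print(f"{z:8.1f} {value:10.3f} {truth:11.3f}")
err = np.nanmax(np.abs(profile.values - bundle.truth.splay_r_xy))
print(f"\nmax |measured - truth| = {err:.3f} Å "
      "(noise-limited; exactly 0 at noise_sd=0)")
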