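"""Steric accommodation of glycan conformers in a constricted channel.

A glycosylated 8-subunit wide-like filament is docked through a synthetic
channel with a single Gaussian constriction.  Grafting a self-avoiding
conformer ensemble at every site and rejecting conformers whose ring
oxygens come within a threshold distance of any environment α-carbon gives
an acceptance/rejection profile along the filament axis; the rejection peak
localises the constriction.  Thresholds 3.25 and 3.75 Å act as proxies for
lower/higher filament stiffness.
"""

import numpy as np

from piluskit import (
    GeneratorConfig,
    StericCriterion,
    WIDE_HELICAL_PARAMS,
    accommodation_profile,
    aperture_profile,
    apply_helical_symmetry,
    make_channel,
    make_synthetic_subunit,
    sample_conformer_library,
    wide_config,
    wide_site_map,
)

filament = apply_helical_symmetry(
    make_synthetic_subunit(wide_config(seed=21)), WIDE_HELICAL_PARAMS, 8
)
library = sample_conformer_library(
    GeneratorConfig(seed=22, conformer_count=200, monomers_per_conformer=4)
)
z_mid = 0.5 * float(filament.coords()[:, 2].max())
channel = make_channel(
    GeneratorConfig(
        seed=0, channel_radius_A=40.0, constriction_depth_A=22.0,
        constriction_z_A=0.0, constriction_sigma_A=6.0, channel_length_A=140.0,
    )
).translated([0.0, 0.0, z_mid])

centers, radii = aperture_profile(channel, bin_width_A=10.0)
print(f"channel aperture: {np.nanmin(radii):.1f} A at z = "
      f"{centers[np.nanargmin(radii)]:.0f} A (open radius 40.0 A)")

for threshold in (3.25, 3.75):
    profile = accommodation_profile(
        filament, wide_site_map(), library, StericCriterion(threshold_A=threshold),
        environment=channel, bin_width_A=10.0, subsample=100, seed=1,
    )
    rej = profile.rejection_rate
    peak = np.nanargmax(rej)
    print(f"threshold {threshold:.2f} A: overall acceptance "
          f"{profile.n_accepted.sum() / profile.n_total.sum():.2f}, "
          f"rejection peak {np.nanmax(rej):.2f} at z = "
          f"{profile.bin_centers_A[peak]:.0f} A")
# The rejection peak coincides with the aperture minimum, and the higher
# threshold (stiffer filament proxy) rejects at least as many conformers.
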