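"""Convert a particle surface density into sample molarity.

Counts particles inside an inclusive molecular-volume window around the
complex peak (991-1209 nm^3) over the total scanned area, extrapolates
to the whole mica deposit and divides by the deposited droplet volume
and Avogadro's number.
"""

import numpy as np

from afmstoich import CountingWindow, aggregate_series, estimate_concentration

rng = np.random.default_rng(11)
# volumes measured over 50 scans of 4 um^2 (total 200 um^2)
volumes = np.concatenate(
    [rng.normal(417.0, 60.0, 1160), rng.normal(1174.0, 120.0, 840)]
)

estimate = estimate_concentration(
    volumes,
    window=CountingWindow(991.0, 1209.0, species="P2X4/5HT3A"),
    scanned_area=200.0,        # um^2 imaged
    total_mica_area=1e7,       # um^2 wetted by the deposit
    elution_volume=50.0,       # ul adsorbed
)
print(f"particles in window : {estimate.n_particles}")
print(f"surface density     : {estimate.density_per_um2:.2f} per um^2")
print(f"complex molarity    : {estimate.molarity_pM:.2f} pM")

mean, se = aggregate_series([3.1, 3.7, 2.9, 3.5, 3.4])  # five purification series
print(f"across replicates   : {mean:.2f} +/- {se:.2f} pM")
# Picomolar concentrations are typical for single-particle AFM
# preparations: a few particles per square micrometre of mica.
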