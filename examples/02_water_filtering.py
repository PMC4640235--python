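"""Model an FID as damped sinusoids and subtract the residual water.

Fits a Hankel-SVD model of rank 8 to a synthetic brain FID, lists the
recovered components, and removes the ones falling in the 4.2-5.2 ppm
water region.  The spectral maximum moves from water to a metabolite.
"""

import numpy as np

from mrsxml import (
    AcquisitionParams,
    PpmRange,
    fit_components,
    gen_brain_like_sv,
    hlsvd_filter,
    to_frequency_domain,
)

params = AcquisitionParams(63.86, 1300.0, 2048, 4.7)
fid, truth = gen_brain_like_sv(params, seed=7)

components = fit_components(fid, 8)
print("rank-8 components (amplitude-sorted):")
print("   ppm     amplitude  damping 1/s")
for c in components:
    print(f" {c.ppm(params):6.2f}  {c.amplitude:9.3f}  {c.damping:10.1f}")

water_region = PpmRange(upper=5.2, lower=4.2)
filtered = hlsvd_filter(fid, 8, [water_region])

for label, sig in (("before", fid), ("after ", filtered)):
    spec = to_frequency_domain(sig)
    i = int(np.argmax(np.abs(spec.intensities)))
    print(f"{label} filtering: global maximum at {spec.axis.values[i]:.2f} ppm")

# The dominant ~4.7 ppm component is the residual water; after subtraction
# the strongest signal is the NAA singlet near 2.0 ppm, so the metabolite
# pattern is no longer dwarfed by the water tail.
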