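"""Generate one synthetic RAGT fNIRS recording and write it to SNIRF.

Builds the default study probe (16 sources, 10 detectors, 34 long + 4 short
channels) and block paradigm (10 x 30 s active / 30 s rest), simulates a
two-wavelength recording with known per-channel activation amplitudes, and
saves it.
"""

import numpy as np

from gaitnirs import GroundTruth, default_montage, default_paradigm, generate_recording
from gaitnirs.io import write_snirf

montage = default_montage()
paradigm = default_paradigm()
truth = GroundTruth.default(montage, seed=1)

rec = generate_recording(montage, paradigm, truth, fs=10.0, seed=1, subject="S01")
path = write_snirf(rec, "S01_T0.snirf")

print(f"montage: {len(montage.sources)} sources, {len(montage.detectors)} detectors, "
      f"{montage.n_long} long + {montage.n_short} short channels")
print(f"paradigm: {paradigm.n_blocks} blocks, {paradigm.span:.0f} s total")
print(f"intensity array: {rec.intensity.shape}  (samples x channels x wavelengths)")
print(f"true HbO activation range: {truth.beta_hbo.min():.2f}-{truth.beta_hbo.max():.2f} uM")
print(f"injected artifacts at t = {np.round(rec.meta['artifact_times'], 1)} s")
print(f"wrote {path}")
# The intensity series embeds activation, systemic physiology, artifacts and
# noise; beta_hbo is the ground truth the downstream pipeline must recover.
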