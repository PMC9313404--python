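"""Simulate the five hippocampal activity regimes.

Generates one 5-s segment pair (DC-preserved z and AC-coupled EEG y) per
activity type and prints amplitude statistics.  The inhibition/excitation
ratio B/A rises from Type I (fast low-amplitude epileptiform oscillation)
through rhythmic spiking (II, III) and irregular escape spiking (IV) to
Normal background activity.
"""

import numpy as np

from epikf import default_presets, generate_type_set

pairs = generate_type_set(default_presets(), n_segments=1, duration=5.0, fs=480.0, seed=0)

print(f"{'type':>8} {'B/A':>5} {'z mean (mV)':>12} {'z p-p (mV)':>11} {'y p-p (mV)':>11}")
for (z, y), preset in zip(pairs, default_presets()):
    print(
        f"{z.label:>8} {preset.ratio:5.1f} {np.mean(z.samples):12.2f} "
        f"{np.ptp(z.samples):11.2f} {np.ptp(y.samples):11.2f}"
    )

# The DC level of z falls as inhibition rises, while the AC-coupled y keeps
# only the oscillatory part -- the feature that later limits observability.
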