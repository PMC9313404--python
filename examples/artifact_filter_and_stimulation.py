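"""Stimulation waveforms and the artifact-removal filter.

Designs the 209-order equiripple low-pass used to strip electrical
stimulation artifacts from 3840 Hz recordings, and builds the two
stimulation waveforms whose effects the severity indicators evaluate.
"""

import numpy as np

from epikf import FirSpec, StimulationSpec, design_artifact_filter, filter_report, make_stimulation

spec = FirSpec()
rep = filter_report(design_artifact_filter(spec), spec)
print(f"artifact filter: stopband attenuation {rep['stopband_atten_db']:.2f} dB "
      f"(target >= {spec.stopband_atten_db}), passband ripple "
      f"{rep['passband_ripple_db']:.3f} dB (target <= {spec.passband_ripple_db})")

fs = 15360.0
rps = make_stimulation(StimulationSpec(kind="RPS"), fs, duration=1.0)
q_pos = rps[rps > 0].sum() / fs
q_net = rps.sum() / fs
print(f"RPS pulse train: peak +{rps.max():.1f} / {rps.min():.2f} uA, "
      f"net charge imbalance {abs(q_net) / q_pos * 100:.3f}% per second")

rns = make_stimulation(StimulationSpec(kind="RNS"), 3840.0, duration=2.0, seed=0)
print(f"RNS noise: extremes {rns.min():.1f} / {rns.max():.1f} uA (rescaled to +/-500)")

sham = make_stimulation(StimulationSpec(kind="sham_RPS"), fs, duration=1.0)
print(f"sham RPS peak: {sham.max():.3f} uA (1% of the real amplitude)")

# Charge-balanced biphasic pulses avoid net charge injection into tissue;
# the sham waveform keeps the same shape at 1% height as a control.
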