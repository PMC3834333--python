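# striacal

Quantitative analysis of stimulus-evoked cytoplasmic-calcium transients and
immunofluorescence cell-type classification for cultured striatal neurons.

Cultured striatal GABAergic neurons (mostly medium spiny neurons) respond to
electrical field stimulation with a rapid rise in cytoplasmic Ca²⁺ followed
by a slow decay. Recorded with a calcium-sensitive dye at 100 frames/s, this
appears as a fluorescence transient; its peak amplitude, decay kinetics and
cumulative area are compact readouts of neuronal excitability, and
immunostaining intensity identifies which cell types produced them. This
package implements that whole measurement chain as a tested, reusable
library, together with a seeded synthetic-data generator so every stage can
be validated against known ground truth without any recordings.

## What it computes

**ΔF/F₀ extraction.** Shutter-closed (dark) frames are averaged and
subtracted, the baseline F₀ is the pixelwise mean over the 1 s before the
first stimulus, and the signal is the fold change ΔF/F₀ = (F − F₀)/F₀. No
photobleach correction is applied.

**Dendritic ROI traces.** Three contiguous 2×2-pixel ROIs per dendrite
(1.18 μm/pixel), the most proximal pixel 6 pixels (~7 μm) from the
soma-dendrite border; their 12 pixels are averaged into one trace. Dendrites
are rejected if they are ≤12 pixels long, narrower than the ROI extent, or
carry a branch point under the ROI span.

**Transient metrics.** Baseline noise is the RMS over [−1000, −104] ms
relative to the first stimulus; a per-pulse peak is detected when its
amplitude over the local baseline reaches 5×RMS (traces Gaussian-filtered at
15 Hz). Decay constants come from an unconstrained least-squares fit of

    F(t) = a · exp(−t/τ)

to the 80%→20% segment of the falling phase (5 Hz filtering), with fits
discarded at r² < 0.990. Cumulative calcium load is ∫|ΔF/F₀| from the first
stimulus to 1 s after each pulse. Closed-form decay impact: a unit-peak
exponential has total area τ and stays above a fractional threshold for
T = τ·ln(1/threshold), so ratios of both quantities equal the τ ratio.

**Subcellular gradients.** Single-pixel traces along a nucleus→soma→dendrite
path give per-pixel peak amplitudes (highest point 10–70 ms post-stimulus)
and max-normalized F₀ profiles; amplitude grows distally while F₀ falls.

**Cell-type classification.** Somatic staining intensity (peak of the
7-pixel running average along a line through the soma) is thresholded
against the upper limit of the 95% *uniform* (Working–Hotelling/Scheffé
simultaneous) confidence band of negative-control intensity regressed on
log₁₀ somatic area:

    threshold(x) = b₀ + b₁x + sqrt(2·F₀.₉₅(2, n−2)) · SE(fit at x)

Medium spiny neuron = GAD65⁺/DARPP-32⁺, GABAergic interneuron =
GAD65⁺/DARPP-32⁻, cholinergic interneuron = (GAD65⁻ or VGAT⁻)/VAChT⁺.

**Statistics.** Group comparisons use two-tailed Student's t-tests on
log-transformed values with raw-scale means ± SEM reported; Pearson
correlations with two-tailed p.

## Worked example

```python
import numpy as np
from striacal import synth, preprocess, rois, transients

protocol = preprocess.StimulusProtocol.train()   # 10 pulses at 1 Hz
geom = synth.make_geometry(seed=1)
kin = synth.KineticsParams()                     # calibrated defaults
noise = synth.NoiseParams(seed=1)

stack = synth.simulate_stack(geom, kin, protocol, noise)
dark_sub = preprocess.subtract_dark(stack)
f0 = preprocess.compute_f0(dark_sub, protocol)
dff = preprocess.compute_dff(dark_sub, f0)

roi_set = rois.place_rois(geom, dendrite_id=0)
trace = rois.extract_roi_trace(dff, roi_set)
metrics = transients.analyze_trace(trace, protocol)

print(f"responder: {metrics.responder}")
print(f"baseline RMS noise: {metrics.rms_noise:.4f} dF/F0")
print(f"pulse-1 amplitude: {metrics.peaks[0].amplitude:.3f} dF/F0")
print(f"pulse-1 tau: {metrics.fits[0].tau:.3f} s "
      f"(r^2 = {metrics.fits[0].r_squared:.4f})")
print(f"cumulative load after pulse 10: "
      f"{metrics.cumulative_load[-1] / trace.frame_interval:.1f} a.u.")
```

Output:

```
responder: True
baseline RMS noise: 0.0041 dF/F0
pulse-1 amplitude: 0.306 dF/F0
pulse-1 tau: 0.724 s (r^2 = 0.9965)
cumulative load after pulse 10: 210.7 a.u.
```

The neuron responded to every pulse; the per-pulse peak (~0.3 ΔF/F₀) is ~75×
the baseline RMS, so detection at 5×RMS is unambiguous. The fitted decay
constant recovers the generator's τ = 0.7 s within a few percent at this
noise level, and the load accumulated over the train (in ΔF/F₀·frames) sits
in the ~200 a.u. regime the generator is calibrated to.

A command-line interface mirrors the library:

```bash
striacal simulate --seed 1 --out runs/sim        # stacks + sidecars (TIFF/YAML)
striacal analyze  --stacks runs/sim --out runs/m # per-dendrite metrics CSV
striacal classify --seed 1 --out runs/calls      # bands + cell-type tables
striacal report   --in runs/m                    # per-pulse group comparisons
```

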