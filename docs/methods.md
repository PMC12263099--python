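# Methods

`catrans` operates downstream of CNMF-style source extraction for
single-photon miniScope recordings. Its inputs are the per-cell temporal
variables such pipelines produce — the denoised dynamics `C`, the
deconvolved rising-slope signal `S`, optionally the residual trace `YrA`
and ΔF/F — and its task is to decide, frame by frame, which stretches of
each trace are the rising phase of a Ca²⁺ transient. A transient is
represented by its rising segment only: the onset frame (fluorescence still
at its pre-rise value) through the peak frame, both inclusive, 0-based.
Seconds are frames divided by the frame rate (30 Hz default).

## ΔF/F, noise and SNR

ΔF/F = (F − F₀)/F₀ with F₀ a per-frame moving-percentile baseline
(default: 8th percentile over a centered 600-frame ≈ 20 s window). Windows
are truncated at the trace edges rather than padded, so no boundary values
are fabricated; F₀ is clamped to a machine-positive floor before division
and clamped frames are counted in a warning. Whether the upstream
convention is a centered or trailing window is not fixed by the data model,
so both the window and the percentile are configuration keys.

Noise is local, not global: a z-score against whole-trace variance rejects
valid transients whenever noise drifts over a session. Instead the noise at
frame *t* is the rolling statistic (mean, median or max; default mean over
20 frames) of the absolute Savitzky–Golay residual |x − savgol(x)|, floored
at 0.1. SNR(t) = savgol(x)(t) / max(noise(t), floor). The floor is applied
to the denominator, not to the quotient — the alternative reading (capping
SNR itself) would flatten exactly the high-SNR peaks the threshold is meant
to pass. SavGol defaults are window 31, polyorder 3: wide enough to
suppress frame-level noise, short enough to preserve 10–15-frame rises at
30 Hz; the filter reproduces polynomials up to its order exactly, which the
tests exploit as an oracle.

Session metadata travels as flat INI files (one per recording) or a
hierarchical JSON grouping animal → day → session stage. The INI key
schema (`[session] animal_id/day/session_stage`, `[data] trace_path/
behavior_path/...`) is a reconstruction of the demo-file layout of
upstream GUI tools, which specify it only by example; unrecognized keys
survive round trips in an extras map, and video paths are recorded but
never opened.

## Parameter-based detection

Candidate peaks are the local maxima of `C` (plateaus count once, at their
leftmost frame; trace endpoints are never peaks). Each peak must be backed
by a positive run of `S`; a peak on `S = 0` may look back up to 5 frames
(configurable) for the end of its run, absorbing deconvolution lag, and is
otherwise discarded as spurious. The event's onset is the frame *before*
the first positive `S` increment — `S(t) > 0` records a rise from frame
t−1 to t, so the pre-rise value sits at t−1 — and its peak frame is the
`C` maximum.

Candidates are swept left to right. While the next candidate's onset is
closer than `interval_threshold` frames to the current event's onset (the
inter-transient interval is measured onset-to-onset), the two are merged:
the taller `C` peak wins, the earliest onset is kept, and the merged event
is re-tested against the following candidate. Only after merging are the
thresholds applied: an event is accepted iff the in-segment maxima of ΔF/F
and SNR reach `peak_threshold` and `snr_threshold`. This ordering means a
candidate that would individually fail can still contribute its onset to a
surviving merged event.

Amplitudes: `peak_amplitude` is ΔF/F at the peak, except for an event
riding the decay of its predecessor — onset ΔF/F above 25% of the previous
peak amplitude (configurable trigger) — which is measured from its own
onset. `total_amplitude` is the rectified sum of (ΔF/F − onset value) over
the rising segment, an area under the rise.

These choices make three monotonicity properties exact: raising any of the
three thresholds never adds an event, and the surviving set under a higher
peak/SNR threshold is a subset of the lower-threshold set.

Manual annotation support is limited to the snapping primitive: a
hand-placed frame moves to the argmax (or argmin) of the trace within a
±10-frame window, ties resolved toward the input frame, then leftward.

## Sequence-labeling detectors

Frame classification uses two channels, `C` and ΔF/F, each divided by its
per-cell maximum. Training samples are 200-frame cores flanked by 50
context frames per side (zero-padded at the recording edges); the slack
informs the prediction but carries no loss. Because rising frames are only
2–3% of the data, windows whose core holds neither a ground-truth positive
nor a positive `C` value are dropped (stratification). Loss re-weighting is
deliberately not used: it over-promotes noisy segments whose shape
resembles transients, costing precision. Stratification never removes a
window containing a ground-truth positive.

Four architectures share a per-frame logit head and BCE-with-logits loss
under Adam at learning rate 10⁻³:

* **gru / lstm** — 3 stacked bidirectional layers, hidden size 30;
  forward/backward states are concatenated before the head. The GRU has
  strictly fewer parameters than the LSTM at equal width (3 vs 4 gates).
* **transformer** — encoder of width 42, 3 layers, 2 heads, with a
  preliminary 2→42 dimension-expansion layer (attention cannot encode
  position usefully in 2 channels) and trainable position embeddings.
* **local_transformer** — width 32, 1 head, attention restricted to a band
  of 10-frame windows with a 5-window look forward/backward, implemented as
  an additive mask.

The networks run on a small in-package reverse-mode autodiff core
(`catrans.nn`): numpy tensors, fused hand-differentiated kernels for the
recurrent cells and scaled-dot-product attention (composing them from
primitive ops makes the graph itself the bottleneck over 300-frame
windows), float32 storage, and fully deterministic CPU execution — a model
is a pure function of its seed, and identical seeds reproduce training
bit-for-bit. Gradients of every layer are verified against central finite
differences in float64.

Training shuffles windows each epoch (seeded), batch size 8 — small
annotated corpora are the realistic regime, and more updates per epoch
matter more than smoother gradients; validation macro-F1 is monitored each
epoch with the best snapshot restored and early stopping at patience 5
(cap 50 epochs). Inference slides windows at half the core length and
averages sigmoid probabilities over every window covering a frame; a
trailing window anchored at the recording end guarantees full coverage.
Probabilities ≥ 0.5 become positive frames; runs shorter than 2 frames are
discarded before events are extracted. The 0.5/2-frame binarization and
the half-length stride are configuration keys.

## Evaluation

All metrics are frame-level. Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 their harmonic mean, each computed with either class as positive;
macro F1 is the mean of the two class F1 scores and is invariant to the
choice of positive class (the two confusion tables are permutations of one
another). Empty denominators define a metric as 0 and set an explicit flag
rather than propagating NaN. Cells are split 80/10/10 into
train/validation/test by seeded shuffle, flooring the validation and test
sizes with the remainder to training — 282 cells split 226/28/28.

The experiment harness sweeps training-set size × test source (same or
different session stage, day, animal, region — encoded as dataset tags),
redrawing training and test cells each repeat (redraw of both is the
default; a fixed-training-draw mode exists), and emits a long-format table
one row per repeat × condition × metric, with under-populated grid points
skipped and the reason recorded. Significance testing over that table is
left to external statistics software.

## Synthetic data

The generator emulates the study regime the detectors target: 30 Hz,
27,000 frames (15 min) per cell, sparse transients. Onsets form a renewal
process (exponential gaps shifted by a 90-frame minimum, censored at the
recording end); each event rises linearly for 5–15 frames and decays
exponentially with τ = 45 frames; peak ΔF/F amplitudes are log-normal
(median ≈ 1.5). Defaults give an expected rising-frame occupancy of
4.5/min × 10.5 frames ≈ 2.6%. `C` is the noiseless kernel sum; `S` is its
positive first difference, so `S > 0` exactly on rising frames; raw
fluorescence is baseline × (1 + C) plus Gaussian noise (σ = 0.03 of
baseline), with optional slow baseline drift and slowly varying noise σ to
exercise the local noise estimator; ΔF/F comes from the raw trace through
`compute_dff`.

Ground truth is the *realized* rising phase of the noiseless `C`: the
`S > 0` run ending at each planted peak plus its onset frame. An event
whose rise is entirely cancelled by a preceding decay (vanishingly rare at
the defaults) is censored. On noiseless traces this makes exact recovery by
the parameter-based detector an identity, which anchors the end-to-end
tests.

What the generator does not emulate: crosstalk between overlapping cells,
deconvolution artifacts in `S`, photobleaching, motion, or non-Gaussian
sensor noise. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated kinetics — not performance
on recorded data, where `C`/`S` quality depends on the upstream extraction.

## Problem sizes in the test suite

The in-vivo corpus behind the published-scale experiments (hundreds of
manually annotated cells) is not distributable, so the stochastic checks
run on scaled synthetic conditions chosen once: the detector-quality run
trains the GRU on 10 cells of 5,000 frames (8/1/1 split); the
architecture comparison trains GRU, LSTM and the standard transformer for
an equal 8-epoch budget on the same corpus; the training-set-size sweep
uses a 10-cell pool of 3,000-frame cells with sizes 1/2/5 × 3 repeats at a
fixed 30-epoch budget — enough gradient updates that the mid-sized
training sets escape the degenerate all-negative solution, so the sweep
measures data diversity rather than optimization stalls. The acceptance
script uses an 8-cell, 3,000-frame corpus for its GRU quantity.

## Known limitations

* The ML detectors and generator assume CNMF-like `C`/`S` semantics;
  traces from other extraction methods need equivalent variables.
* The local transformer is the slowest architecture per epoch (dense
  banded attention), mirroring its cost ranking on GPU frameworks.
* `run_experiment` trains one model per grid cell per repeat; large grids
  are CPU-expensive by design and meant for scripted batch runs.
* Event-level matching metrics (onset tolerance windows etc.) are out of
  scope; evaluation is strictly per frame.
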