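# Methods

`spikecube` implements a brain-templated spiking-neural-network (SNN)
reservoir pipeline for two-class classification of multichannel EEG with
optional heart-rate-variability (HRV) fusion, together with the synthetic
cohort generator used to validate it.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Spike encoding

Continuous signals are turned into ternary event trains by Step-Forward (SF)
encoding.  Each channel keeps a running *base*; at sample *t* (t ≥ 1), a value
above `base + threshold` emits +1 and raises the base one threshold step, a
value below `base − threshold` emits −1 and lowers it, anything else emits 0.
Ties at a cutoff emit nothing (strict inequalities).  The initial base
defaults to the channel's first sample, so t = 0 never spikes.

The threshold defaults to **0.5 × the per-channel standard deviation of the
encoded window**, making the encoder scale-free across channels of different
gain.  Two consequences worth knowing:

* SF is a slope tracker, not an interpolator.  The base moves at most one
  threshold per sample, so for signals whose inter-sample jumps exceed the
  threshold the base lags, reconstruction error grows beyond one threshold,
  and a *larger* threshold can transiently emit *more* spikes after a sharp
  reversal (the lagging base overshoots).  The encoder's tracking guarantees
  (reconstruction error ≤ jump + threshold, spike count monotone in
  threshold) hold in the regime where jumps do not exceed the threshold, and
  the tests assert them there.
* Because the threshold is relative, a pure gain change of a channel does not
  change its spike count; changes in *spectral shape* do.  A strong
  band-limited oscillation added to broadband noise lowers the relative
  threshold-crossing rate — which is exactly how class differences reach the
  spike domain in the synthetic cohorts.

## Reservoir

The reservoir is 1471 leaky integrate-and-fire (LIF) neurons, one per cm³ of
an anatomically shaped volume.  The packaged coordinate asset is a synthetic
stand-in for an atlas-derived table: every integer-cm grid point inside an
ellipsoid fitted to adult brain dimensions (semi-axes ≈ 6.7 × 9.0 × 5.9 cm,
chosen so the count is exactly 1471), plus 32 scalp positions of the 10-10
system exported from a standard montage.  Each channel's input neuron is the
nearest grid point (ties → lowest index; collisions → next nearest free
neuron), so all 32 input neurons are distinct.

Ordered pairs (i, j) connect independently with probability
`P_ij = C·exp(−(d_norm/λ)²)` for `d_norm ≤ d_thresh`, else 0, where `d_norm`
is Euclidean distance over the template's maximum pairwise distance.
Defaults: `C = 0.7`, `λ = 0.15`, `d_thresh = 0.2`, giving on the order of
30–40 connections per neuron.  Sparser settings (e.g. C ≈ 0.15) leave each
input neuron with only a handful of outgoing synapses, which makes the
knowledge-discovery statistics (below) too noisy to be useful — connection
density was chosen for stable recovery on synthetic cohorts, not for
classification accuracy, which is insensitive to it.  Weight magnitudes are
uniform on (0, `w_init_scale` = 1]; a neuron is inhibitory (all outgoing
weights negative) with probability 0.2.  Synaptic delays are
`1 + floor(d_norm · delay_max)` steps (`delay_max` = 5).

LIF dynamics are discrete-time: potential decays multiplicatively by
`1 − leak` per step (leak = 0.1), integrates delayed weighted input, fires at
`v_threshold` = 0.5, resets to 0, and stays silent for `refractory` = 2
steps.  Input neurons are clamped to their event trains; inhibitory (−1)
input events inject negative current downstream.

## STDP training and cube subtraction

Unsupervised training applies spike-timing-dependent plasticity.  Each
postsynaptic spike pairs with the nearest presynaptic spike within a window
of 3·t⁺ steps: a causal pair (pre first, gap s) adds `A⁺·exp(−s/t⁺)`, an
anti-causal one subtracts `A⁻·exp(−s/t⁺)`; simultaneous spikes and
equidistant ties resolve to the causal branch.  A single time constant
(t⁺ = 3 steps) serves both branches, with a config hook for a second one.
Amplitudes default to `A± = 0.002`: with ~10³ steps per window and hundreds
of pairings per synapse, the earlier-considered 0.01 drove most weights into
the ±10·`w_init_scale` clip and erased class structure.  One training pass
over the samples, in order, is the default.

One reservoir per class is trained from a *shared* random initialization;
the class-difference (subtracted) cube `Δw = w_A − w_B` is defined only for
cubes sharing that initialization and localizes class-discriminative
connectivity.  The convention is affected − control (descending label).

## Knowledge discovery

Cluster assignment spreads from each input neuron along directed paths of up
to 2 hops, scoring a neuron by Σ|w| of direct links plus 0.5 × the 2-hop
path-product mass; for subtracted cubes |Δw| is used (sign encodes direction
of difference, not strength).  A neuron joins the channel with maximal
score, with one deliberate refinement: neurons whose winning score falls
below the **75th percentile** of positive winning scores stay unassigned.
Without this cutoff, cluster sizes measure how much of the volume a channel
can *reach* — essentially local neuron density and centrality — rather than
how strongly it is connected, and planted-channel recovery on synthetic
cohorts fails; with it, recovery is stable.  The exact cluster-spread rule
of the original architecture is not published, so this stand-in is validated
purely by those recovery properties.

Neuron proportion is 100 × cluster size / 1471.  The feature interaction
network (FIN) sums |w| over connections whose endpoints lie in different
clusters, symmetrized, zero diagonal; it is exportable as node/edge text
files for brain-network viewers.  Top-k channel selection sorts by
descending proportion with ties broken by canonical channel order.

## deSNN feature vectors

One output neuron is materialized per sample as its synapse-weight vector.
Rank-order initialization sets `w_init = mod^order` (mod = 0.9), where order
is the 0-based competition rank of the synapse's first spike among all
connected synapses (ties share the lower rank; never-spiking synapses stay
at 0).  Spike-driven plasticity then drifts each weight from its first spike
onward: +`drift_up` on spike steps, −`drift_down` on silent steps (both
default 0.08), frozen on touching `w_high` or `w_low` (bi-stability).  The
drift is gated on the first spike: an all-silent synapse never starts
drifting and keeps its initial weight.

The bounds default to ±20.  The net drift of a synapse with per-step spike
probability p over T steps is ≈ `drift·T·(2p − 1)` — about ±8 for a balanced
1000-step train — so bounds at the conventional 2.0/0.0 absorb essentially
every synapse within the first second and collapse the vector to its bounds;
±20 keeps typical channels in the informative drifting regime while strongly
rate-biased channels still freeze.  Anyone changing the sampling rate or
window length should rescale the bounds in proportion to `drift·T`.

Connection strategies: all-32 or top-5 channel sets, each either input-only
(vector length 32 / 5) or full (reservoir + inputs, 1471+32 / 1471+5).
Input-only synapses read the sample's own event trains; reservoir synapses
read the simulated firing record.

## Classification

The modified KNN weighs features uniformly or by signal-to-noise ratio
`|μ₁ − μ₂|/(σ₁ + σ₂)` (normalized to sum 1), measures Manhattan or Euclidean
distance on the weighted differences, takes the k nearest overall or per
class, and weighs votes uniformly, by inverse distance, or by the range
function `(d_max − (d_i − d_min))/d_max` over the neighbour set (uniform when
all neighbour distances are zero).  Neighbour ties at equal distance break by
training index; vote ties go to the smaller label.  Evaluation is
leave-one-out cross-validation with SNR weights recomputed inside each fold,
so the held-out sample never leaks into the weighting; the grid search is
global (parameters chosen on the full LOOCV), with the caveat that global
selection reports an optimistic accuracy for the chosen cell.

## HRV and fusion

Time-domain parameters per segment (2 min / 30 s / 10 s): SDNN (sample SD),
RMSSD (root mean square of successive differences), mean HR, and Baevsky's
stress index `SI = AMo/(2·Mo·MxDMn)` computed from a 50 ms interval
histogram aligned to 50 ms multiples (Mo modal-bin midpoint in s, AMo modal
share in %, MxDMn range in s; zero range → +∞).  PNS and SNS composites are
the mean z-scores of (mean RR, RMSSD) and (mean HR, SI) respectively,
z-scored against the cohort under analysis — monotone analogues of the
commercial indices of the same names, **not** numerically comparable to
them.  10-s segments populate RMSSD only; the other parameters are
statistically unreliable at that length and are left NaN.  Intervals are
assigned to a segment by their starting R-peak.  Fusion appends selected,
training-set-z-scored HRV fields to a feature vector; the subset search
enumerates all non-empty parameter subsets (≤ 63) by LOOCV, preferring
higher accuracy, then smaller subsets, then canonical order.

## Time-segment scan

The baseline is partitioned into 2/5/10 s windows (stride = length by
default; an overlapping stride is available).  Every
(segment × channel mode × strategy × SDSP grid point) cell trains class
cubes, subtracts, derives features, and scores LOOCV; for input-only
strategies an exhaustive I–O feature-subset search runs when there are at
most 10 features (2³² subsets for the 32-channel case is refused without an
explicit override).  A grid constraint restricts to `drift_up > drift_down`
when requested.  Cells are independent and emitted in canonical order, so
the result table is deterministic.  Per-cube simulations are shared across
SDSP grid points (the firing record does not depend on mod/drift), and each
subject's recording is generated once per scan.

## Synthetic cohorts

The generator emulates the target study design: two groups of n = 32, 32
channels at 500 samples/s, 2-min baseline + 2-min stimulus.  EEG is pink
(1/f) noise per channel plus a shared-source field mixed by electrode
distance, normalized to unit SD; affected subjects add a 10 Hz oscillation of
amplitude `effect_size` × background SD on the effect channels (default
{Cz, O2, F7, P4, Fz}, effect 2.0) within the effect windows (whole recording
by default), so the affected/control variance ratio there is
**1 + effect_size²**.  Onsets are log-normal with median 39 s after stimulus
start, clipped to the stimulus window.  RR intervals are AR(1) Gaussian
(mean 850 ms, SD 50 ms, coefficient 0.6); the affected class has the mean
shortened by 60 ms and SD scaled by 0.7 as a sympathetic-shift analogue,
clipped positive with out-of-range flagging.  Recordings are generated
deterministically per subject on demand (a full cohort held in memory would
be ~2 GB).

What the generator does *not* emulate: biophysical forward modelling and
volume conduction, artifacts (blinks, EMG, drift), non-stationarity beyond
the planted windows, inter-subject anatomical variability, and
respiration–HRV coupling.  Passing recovery tests therefore show that the
pipeline finds the kind of spatially localized oscillatory-power and
autonomic differences it was designed for — not that it would perform
equally on real recordings.

## Problem sizes and numerical choices

Validation runs use windows of 2 s at 500 samples/s (1000 steps).  Recovery
experiments run the full 1471-neuron reservoir at n = 32+32 over three
seeds; the permutation null (20 label permutations) and the segment scan
(ten seeds, n = 12+12, planted 110–112 s window) use a 2-cm-subsampled
reservoir (~195 neurons), a deliberately scaled-down configuration whose
recovery behaviour matches the full one.  All randomness flows through
explicit integer seeds; identical inputs reproduce results bit-for-bit.
Weight clipping (±10·w_init_scale), the SDSP bounds above, and the
strict-inequality tie rules are the only places the implementation
disambiguates behaviour the formulas leave open; each is a config key.

## Known limitations

* The cluster-spread rule, LIF constants, SF threshold and SWC density are
  defensible defaults validated on synthetic recovery, not published values.
* SI/PNS/SNS are analogues; absolute values are not comparable to
  commercial HRV software.
* EDF input requires the optional mne dependency and is read-only; the
  native interchange formats are CSV (EEG) and single-column text (RR).
* The grid search is exhaustive and therefore expensive for large spaces;
  the scan's I–O subset search is guarded above 10 features by design.
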