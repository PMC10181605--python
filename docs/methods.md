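# Methods

This note records the scientific model the package implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical choices a maintainer would otherwise have
to reverse-engineer.

## Timing model

All intervals are half-open `[start, stop)` on a continuous clock in
seconds. Sample `i` of a record starting at `t0` covers
`(t0 + i/fs, t0 + (i+1)/fs]`; its timestamp is the right edge. A window
`(a, b]` with edges on the sample grid therefore maps to the slice
`[(a−t0)·fs : (b−t0)·fs]`, which keeps the 40 s period of interest
`(−30, +10]` at exactly 5000 samples at 125 Hz and makes the sliding
windows `(t−D, t]` exact slices. Simulated event edges are snapped to
the sample grid so that interval arithmetic and per-sample masks agree
to machine precision.

## Synthetic interventions

The generator emulates the statistical structure the method assumes
rather than any particular patient population:

- **VF**: a narrowband stochastic process — complex-envelope Gaussian
  noise of 1–2 Hz spectral width carried at a dominant frequency that
  drifts smoothly inside 3–8 Hz (around a per-record draw from
  4–6.5 Hz) — so fibrillatory waves wax and wane without any repeating
  QRS pattern, and different records' spectra overlap as real VF
  spectra do. The trace is rescaled so its peak-to-peak amplitude lies
  in 450–1400 µV, well above the 200 µV coarse-VF criterion. The
  3–8 Hz range is the conventional dominant-frequency band of VF and is
  a tunable parameter, not a claim about any proprietary recordings.
- **NSR**: Gaussian-bump P-QRS-T templates repeated at a rate drawn from
  50–95 bpm (inside the 40–100 bpm criterion) with 2% RR jitter and an
  R amplitude of 0.5–1.4 mV.
- **ONR**: one of three organised non-sinus morphologies per record —
  irregular-RR without P waves (atrial-fibrillation-like), wide-QRS
  bradycardia at 25–38 bpm, or sinus beats with ~25% wide ectopic
  beats.
- **ASYS**: band-limited low-frequency noise rescaled so the largest
  peak-to-peak deflection over *every* 4 s sub-interval is 30–85 µV
  (criterion: ≤ 100 µV).

All rhythm traces are band-limited to 1–30 Hz with a zero-phase
4th-order Butterworth band-pass (applied forward-backward), matching the
stated defi-lead bandwidth.

**CC artefact.** No artefact morphology is published for the data the
method was designed on, so the artefact is a declared parametric model:
within each compression episode, a harmonic series (2–4 harmonics,
amplitudes ∝ 1/h^1.2 with a dominant fundamental) of the compression
rate (drawn uniformly from 100–120 min⁻¹ per record), with slow phase
noise and per-compression log-normal amplitude jitter (σ = 0.25), a
0.15 s cosine ramp at episode edges, and strictly zero output outside
episodes. Each episode's waveform is normalised so that the scale
parameter is its actual peak amplitude; the per-record peak is drawn
log-uniformly from 0.2–3 mV, spanning weak to strong artefacts relative
to the rhythm amplitudes.
Mixing is strictly additive, so a zero artefact scale reproduces the
clean rhythm trace bit-exactly.

**Protocol.** Records follow 30:2 CPR: episodes of exactly 30
compressions, insufflation pauses drawn uniformly from 2–8 s (published
pause interquartile ranges in 30:2 CPR are ~2.5–11.4 s), a short
0.3–1.2 s gap before the regular-analysis start, and a CC-free 10 s
analysis window terminating the record. Two cycles precede the analysis
by default, guaranteeing ≥ 30 s of anterior signal. The ground-truth
label of a period is the rhythm during the analysis window (0, 10]; the
generator emits single-rhythm records, so every generated period passes
the Sh/NSh consistency check by construction (the check itself also
handles multi-segment timelines, where transitions between different
non-shockable classes remain consistent).

**Cohort.** `make_dataset` draws one period per patient with class
probabilities (VF 6%, NSR 3%, ONR 28%, ASYS 63%) — the real-life OHCA
rhythm distribution — and splits patients 50/50 into learning and test
parts, never letting a patient contribute to both.

What the generator does **not** emulate: real CC artefact spectra and
their nonstationarity, electrode motion and handling noise, rhythm
transitions inside a period, pad impedance physiology, or inter-patient
morphology correlation. Passing tests therefore demonstrate that the
pipeline's mechanics and learning dynamics behave as designed on data
with the assumed structure — not clinical performance on real OHCA
recordings.

## sHOT

A hands-off (HOT) episode is a CC interruption whose full length
strictly exceeds 1 s (an interruption of exactly 1.0 s does not
qualify). sHOT of the window `(t−D, t]` is the summed overlap of
qualifying episodes with the window: qualification uses the episode's
full length, the contribution is the clipped overlap, so a qualifying
episode can contribute less than 1 s at a window edge and
sHOT ∈ [0, D]. Interruptions straddling the recorded extent are clipped
to the extent *before* qualification — no hands-off time is claimed
outside recorded evidence. These two boundary readings (strict > 1 s;
clipped-overlap contribution) are the package's resolution of genuinely
open definitional questions and are pinned by tests against a
per-sample mask oracle.

## Classifier and training

The architecture is fixed (it was optimised elsewhere, for VF detection
during uninterrupted compressions): Conv1D blocks with kernels
{10, 20, 20} and filters {5, 25, 50}, each followed by ReLU,
MaxPool(2) and Dropout(0.3); global average pooling; one dense unit
with sigmoid output. The implementation is NumPy throughout
(`cprshock.nn`): convolutions are lowered to one GEMM per layer via
im2col, in float32.

Numerical/protocol choices:

- "Same" convolution padding (left `(K−1)//2`), so pooled lengths
  divide cleanly; the parameter count (27,681) is padding-independent.
- Max pooling drops a trailing odd sample; global average pooling makes
  the network length-agnostic above its 131-sample receptive field.
- Kernel initialisation: uniform(−0.05, 0.05); biases zero.
- Inputs arrive in µV and are scaled to mV inside the classifier so raw
  defi-lead amplitudes match the initialisation scale.
- Loss: class-weighted BCE with w_Sh + w_NSh = 1 and weights
  proportional to the opposite class prevalence, computed from
  period-level counts (the 26× window expansion leaves the ratio
  unchanged). Training uses the fused logit-space form; the
  probability-space form clips at ε = 1e−7.
- Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−7), batch 128; patient-wise
  70/30 train/validation split (patient-wise to prevent leakage of a
  period's 26 windows across subsets); early stopping restores the
  best-validation-loss weights; several independent runs (default 5),
  keeping the run with minimum validation loss. Everything is
  deterministic under a fixed seed.
- The decision rule at the operating point is inclusive: advise shock
  iff pSh ≥ θ. θ is chosen on the validation set by maximising Se + Sp
  over the finite candidate set of observed scores plus {0, 1}; ties
  break toward higher sensitivity (the smallest maximising θ).

## Evaluation

Se is reported for VF and Sp for each non-shockable class, with
two-sided 90% Wilson score intervals (z = 1.6449; the Wilson form is
the package's choice where the interval construction is otherwise
unspecified, delegated to `statsmodels` and pinned against the closed
form in tests). Undefined metrics (empty groups) are reported as
missing, never as zero. Two stratifications: per decision time (one
observation per period per time) and per sHOT bin (all 26 decisions per
period pooled; 12 bins 0, (0–1], …, (9–10], >10 s, with bins beyond D
structurally empty for the 5 s and 10 s models). AED performance goals
are flagged per class with boundary values passing (a printed 99.0% for
NSR counts as meeting the "> 99%" goal, matching how such tables are
conventionally flagged).

## Problem sizes and what desk-scale cohorts can show

The full clinical-scale protocol (750 epochs, patience 150, batch 128, 5 runs)
remains the `TrainConfig` default; the shipped experiments use reduced
budgets sized for a single CPU core. Two empirical facts govern those
sizes, and both are findings about the method worth stating plainly:

1. **The optimizer has a ~150-step warm-up.** With uniform(±0.05)
   initialisation the net spends the first ~150 Adam steps near the
   weighted base rate before features form. Early-stopping patience is
   counted in epochs, so on small cohorts (few batches per epoch) a
   patience scaled proportionally from the full protocol fires inside
   the warm-up and restore-best returns the initial model. Reduced
   budgets therefore use absolute patience values that clear the
   warm-up (patience 10 at ~21 batches/epoch; effectively none for the
   smallest cohorts).

2. **Learning the shockable class needs ~20 distinct VF records.** With
   the real-life class mix (6% VF) and one period per patient, a
   300-patient cohort leaves only ~5–7 distinct VF records in the
   training subset. The class-weighted loss is then minimised by
   separating those records on per-record traits (amplitude, compression
   rate, artefact morphology) rather than on the rhythm: training loss
   falls while validation loss rises from the first epoch. The
   information is present — a six-feature spectral logistic baseline on
   the same windows generalises — but this architecture at this sample
   size memorises. A cohort of identical total size with an enriched VF
   share (100 patients, 30% VF → ~20 distinct VF learning records)
   trains cleanly: validation ROC-AUC ≈ 0.97, held-out window ROC-AUC
   ≈ 0.94, with the expected performance recovery once compressions
   stop. Clinical OHCA databases at the scale this method is designed
   for hold hundreds of VF periods from over a hundred patients,
   comfortably past this threshold.

The enriched-VF cohort (100 patients, mix VF 0.30 / NSR 0.05 /
ONR 0.25 / ASYS 0.40, one run, 70 epochs) is therefore the package's
demonstration experiment (examples/, scripts/acceptance.py). A
default-mix 300-patient experiment is retained in the test suite with
its outcome asserted as the qualitative shape described above; at that
scale the VF-diversity floor is not met and those assertions document
the limitation rather than the method.

## Known limitations

- The NumPy training loop is single-core and unbatched across runs;
  wall-clock cost grows linearly with cohort size and epochs.
- The synthetic task is easier than real OHCA analysis: synthetic VF is
  spectrally narrow and artefacts are strictly additive harmonics, so
  absolute Se/Sp values on synthetic data overstate what any model
  would achieve on real recordings; only the qualitative structure
  (performance vs. sHOT and vs. decision time) is meaningful.
- Impedance is carried for illustration only; no CC detection from
  impedance is implemented — ground-truth timelines drive everything.
- Shockable ventricular tachycardia is not modelled as a class.
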