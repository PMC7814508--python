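# Methods

## The model

`ecgmotif` implements a personalized monitoring model (PMM) for
single-lead ECG beat classification. A patient's recording of length *L*
samples is treated as a time series; a training ratio *t* ∈ (0,1) selects
the first *S* = ⌊*L·t*⌋ samples, which are cut into *M* = ⌊*S*/*W*⌋
consecutive non-overlapping windows of *W* samples ("pattern units"). With
the reference device rate of 180 Hz and *W* = 180, one window is one
second — roughly one heartbeat. Both divisions floor: a partial trailing
window cannot hold a whole beat and is discarded.

Windows are labeled from beat annotations: a window keeps exactly one
fiducial whose class is retained (N — normal, V — ventricular ectopic, by
default). Windows with no fiducial, several fiducials, or an excluded
pathology label (A/F/S) are treated as noisy, dropped, and reported with a
reason. The one-fiducial rule is our operationalisation of "noisy beat
removal": it is deterministic and auditable, at the cost of discarding
windows that straddle beats when the rhythm and the fixed grid disagree.

**Motif discovery.** For each class separately, all pairwise distances
between training pattern units are computed. A *motif circle* with center
*c* is the set of training units strictly within distance *r* of *c*.
Discovery selects circles greedily, largest first; a selected circle's
members leave the pool, so circles never share a unit, and member counts
are non-increasing with rank. The first *k* circle centers (actual
training subsequences, not averages) are the patient's class motifs. Two
centers may be closer than 2*r* provided their member sets are disjoint.

Ties in circle size are resolved by lexicographic lookahead: among tied
maximum-count circles (grouped by distinct member set) the branch whose
full continuation of counts is lexicographically largest wins, with
remaining ties going to the center with the smaller window index. This
makes the discovered member-count sequence the lexicographic maximum over
all admissible center sequences — a myopic index tie-break can otherwise
block a larger later circle — while staying deterministic. The lookahead
is memoized and capped at 200 000 explored pool states; beyond the budget
the tie degrades to the index rule (still deterministic). Because
selection never consults *k*, the motifs at a smaller *k* are a prefix of
those at a larger *k*; the sweep exploits this by discovering once per
(policy, *r*, *t*) at the largest *k*.

**The logical network.** Discovered motifs become class-tagged evaluation
nodes, N motifs first (by rank), then V motifs. A test unit is compared
with every node; if the nearest node lies within *r* it contributes its
label, otherwise the unit is flagged `ANOMALY` for future learning. Exact
distance ties go to the earlier node in the fixed ordering. `add_node`
appends a confirmed anomaly motif after its class's nodes without touching
existing nodes, so past classifications are unaffected.

**Anomaly accounting.** The matching criterion for the anomaly path uses
the same threshold *r* as discovery — one coherent similarity scale and no
extra parameter. Whether a flagged beat counts against accuracy is a
reporting choice: by default `ANOMALY` is incorrect against any true label
(conservative); every result row also carries `accuracy_excl_anomaly`,
which removes flagged beats from the denominator.

## Distance and normalization

Distances are Euclidean. Two modes exist because a radius grid like
0.8–1.6 is only meaningful on a fixed scale:

* `none` — raw Euclidean distance, in the units of the recording.
* `znorm` (default) — Euclidean distance between z-scored copies divided
  by √*W*. This equals √(2(1−ρ)) for Pearson correlation ρ, so it is
  invariant to amplitude scaling, baseline offset and window length, and
  bounded by 2. Radii 0.8–1.6 then correspond to correlation thresholds
  0.68 down to −0.28 for every record regardless of physical units.

A constant (zero-variance) window cannot be z-scored; during discovery
this raises, during classification the beat is flagged `ANOMALY` with
`reason="zero_variance"` rather than crashing a monitoring run.

## Baseline samplers

The two generalized models reuse discovery and classification unchanged
and differ only in training-pool composition: GMM1 pools the first
⌈*t·n*⌉ beats (classes mixed, time order) of every patient; GMM2 pools
⌈*t·n*N⌉ of all N beats and ⌈*t·n*V⌉ of all V beats cohort-wide, drawn
uniformly without replacement under a recorded seed. Per-class quotas use
⌈·⌉ so any class with at least one beat is represented. GMM2 test sets
exclude the drawn beats (no train/test leakage). The asymmetry — GMM1
class-mixed, PMM per-class — is deliberate and mirrors how the samplers
are defined.

## Evaluation

Accuracy is correct/tested per patient; the cohort `AVERAGE` row is the
unweighted mean of per-patient accuracies (patients with empty test sets
are excluded with a warning); a pooled-beat accuracy column is carried for
reference since the two definitions differ under unequal test sizes. The
sweep crosses R ∈ {0.8, 1.0, 1.2, 1.4, 1.6}, K ∈ {2, 4, 6, 8, 10},
T ∈ {0.10, 0.15, 0.20, 0.25} per policy.

Training cost is measured in pairwise-distance evaluations, not seconds:
per-patient discovery does Σ_class n(n−1)/2 pairs per patient (linear in
patient count at fixed record length), pooled discovery does the same on
the summed pool (quadratic), so the pooled/personalized ratio grows about
linearly with cohort size. Wall-clock time is recorded on every row for
context but never asserted — it is hardware-dependent.

## The synthetic cohort generator

No public corpus ships with the package; the generator produces cohorts
with the statistical structure the method targets, so the whole pipeline
is testable offline.

Each patient draws a morphology once: five Gaussian bumps (P, Q, R, S, T)
with per-bump amplitude/width/offset perturbations plus three correlated
axes where real inter-patient variation lives — overall QRS width
(log-normal, ×exp(1.4·σ_inter·z)), R/S balance (deep-S "rS" complexes),
and T-wave polarity (inversion possible beyond |z| ≈ 1.1 at the default
σ_inter). A patient's V beat is their own complex distorted along those
same axes: QRS widened ×2.6 and amplified, P wave absent, T discordant.
Because pathology and inter-patient variation share axes, a pooled model
can confuse one patient's wide-complex normals with another's ectopics
while a per-patient model cannot — the mechanism behind the
personalized-vs-pooled accuracy gap. Shrinking `inter_patient_sd` to zero
makes patients identical and the gap vanishes (verified in tests).

Defaults, chosen once as plausible for a desk-scale cohort and fixed:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 8 | cohort size (32 reproduces the benchmark scale) |
| `duration_min` | 5 | minutes per record (30 at benchmark scale) |
| `fs` | 180 Hz | sampling rate; also the window length |
| `v_fraction` | 0.10 | per-beat probability of a V beat |
| `inter_patient_sd` | 0.35 | morphology divergence across patients |
| `intra_patient_sd` | 0.05 | per-beat amplitude/width/timing jitter |
| `noise_sd` | 0.03 | additive white noise (vs R amplitude ≈ 1) |
| `hr_bpm_range` | 55–95 | per-patient heart rate (complex time-scale) |

At these defaults, z-normalized within-patient same-class distances sit
near 0.2–0.5, cross-patient same-class distances near 0.45–1.3, and
within-patient N-to-V distances above 0.84 — so the personalized model is
essentially exact on the reference radius grid while pooled models lose
accuracy at small K or small R.

What the generator does **not** emulate: rhythm structure (beats are
grid-aligned, one per second — `misalign_jitter` exists only to exercise
the discard rules), baseline wander, electrode artefacts, non-stationary
morphology drift, and any fidelity for A/F/S pathologies (emitted only to
exercise the noisy-beat filter). Passing tests therefore demonstrate the
method's behaviour under its own assumptions, not clinical performance;
the benchmark corpus behind the reference results is not public, so
real-data accuracy is out of scope here.

## Numerical and design choices

* Floor in both sampling divisions; ⌈·⌉ with implicit minimum one for
  per-class training quotas.
* Strict inequality `d < r` for circle membership and node matching; the
  center belongs to its own circle by definition.
* Window coordinates are 0-based; windows are half-open [start, start+W).
* Network JSONs and motif JSONs are written with sorted keys and
  9-decimal floats so retraining under the same configuration is
  byte-identical.
* GMM2's draw takes one cohort-level seed recorded in its outputs; all
  generator randomness derives from (cohort seed, patient index), so any
  patient can be regenerated independently.
* Records whose sampling rate differs from the configured window length
  are not resampled; segmentation is purely index-based, and resampling
  upstream is the documented workaround.

## Test problem sizes

The default test cohort is 8 patients × 5 minutes (300 beats each, 2 400
beats), which the full 100-cell grid sweep across all three policies
covers in a few seconds; discovery-oracle comparisons run on hundreds of
random instances of ≤ 12 subsequences, where exhaustive lexicographic
search is tractable; the cost-scaling check uses 2–16 patients × 2
minutes. These sizes were chosen so the whole suite illustrates every
claim at interactive speed; nothing in the method depends on them.

## Known limitations

* Fixed-grid segmentation assumes the beat period matches the window; on
  real recordings an R-peak-aligned windowing (a possible future addition
  behind the same interface) would discard fewer windows.
* One motif radius *r* serves discovery and matching; heterogeneous
  per-class radii are not supported.
* WFDB support is a minimal native codec (single-signal format 16, MIT
  beat annotations) intended for interchange with MIT-BIH-style tooling,
  not a full implementation of the format family.
* The lookahead tie-break guarantees lexicographically optimal member
  counts only within its node budget; practical pools resolve far below
  it, but adversarial inputs could fall back to the index rule.
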