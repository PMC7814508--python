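"""Synthetic multi-patient ECG cohorts with annotated N and V beats.

The generator emulates the statistical structure the personalized model
assumes of real single-lead ECG: beats are highly self-similar within a
patient but morphologically divergent across patients, and ventricular
ectopic (V) beats are wide, high-amplitude, P-wave-free distortions of the
patient's own normal (N) complex.  Each patient draws a morphology once —
PQRST bump amplitudes, widths and offsets, QRS width, R/S balance, heart
rate — and every beat is that morphology plus small per-beat jitter and
additive sample noise.

Crucially, the V pathology acts along the *same* morphology axes that vary
across patients (QRS widening, amplitude balance), so a pooled model can
confuse one patient's wide-complex normals with another's ectopics while a
per-patient model cannot.  Shrinking ``inter_patient_sd`` toward zero makes
all patients identical and removes that confusion — the dial behind the
personalized-vs-pooled accuracy contrast.

Beats are laid on a fixed grid of one window (``fs`` samples, one second)
per beat with the fiducial at the window center, so fixed-grid segmentation
recovers exactly one fiducial per window; ``misalign_jitter`` perturbs the
fiducials to exercise the labeling discard rules instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .io import BeatAnnotation, EcgRecord, write_annotations, write_record

__all__ = [
    "CohortSpec",
    "PatientMorphology",
    "draw_morphology",
    "make_beat_template",
    "make_patient",
    "make_cohort",
    "write_cohort",
    "load_cohort",
]

# Base PQRST shape: (offset, width, amplitude), offsets and widths as
# fractions of one beat duration, amplitudes in arbitrary units (~mV).
_BASE_BUMPS = {
    "P": (-0.32, 0.045, 0.12),
    "Q": (-0.045, 0.016, -0.18),
    "R": (0.0, 0.022, 1.00),
    "S": (0.045, 0.018, -0.22),
    "T": (0.33, 0.090, 0.30),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    Defaults give a quick 8-patient x 5-minute cohort; ``n_patients=32,
    duration_min=30`` reproduces the benchmark scale (3000 beats/patient).
    """

    n_patients: int = 8
    duration_min: float = 5.0
    fs: int = 180
    v_fraction: float = 0.1
    inter_patient_sd: float = 0.35
    intra_patient_sd: float = 0.05
    noise_sd: float = 0.03
    hr_bpm_range: tuple[float, float] = (55.0, 95.0)
    other_fraction: float = 0.0  # A/F/S beats, only to exercise noise removal
    misalign_jitter: int = 0  # max fiducial shift in samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.v_fraction < 1:
            raise ValueError("v_fraction must be in [0, 1)")
        if not 0 <= self.other_fraction < 1:
            raise ValueError("other_fraction must be in [0, 1)")
        for name in ("inter_patient_sd", "intra_patient_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def window_length(self) -> int:
        return int(self.fs)

    @property
    def n_windows(self) -> int:
        return int(self.duration_min * 60 * self.fs) // self.window_length


@dataclass(frozen=True)
class PatientMorphology:
    """One patient's beat shape: PQRST bump parameters plus heart rate."""

    bumps: dict[str, tuple[float, float, float]] = field(repr=False)
    hr_bpm: float = 70.0


def draw_morphology(rng: np.random.Generator, spec: CohortSpec) -> PatientMorphology:
    """Draw a patient morphology; divergence scales with ``inter_patient_sd``.

    Besides independent per-bump perturbations, two correlated axes are
    drawn because they are where real inter-patient variation lives and
    where pooled-model confusion arises: overall QRS width and R/S balance
    (some patients have deep-S, small-R complexes).
    """
    sd = spec.inter_patient_sd
    qrs_width = float(np.exp(1.4 * sd * rng.normal()))
    rs_balance = float(sd * rng.normal())  # > 0 pushes toward rS morphology
    t_polarity = float(1.0 + 2.5 * sd * rng.normal())  # can invert the T wave
    bumps: dict[str, tuple[float, float, float]] = {}
    for name, (off, width, amp) in _BASE_BUMPS.items():
        amp = amp * float(np.exp(sd * rng.normal()))
        width = width * float(np.exp(0.8 * sd * rng.normal()))
        if name in ("Q", "R", "S"):
            width *= qrs_width
            off *= qrs_width
        else:
            off += float(0.10 * sd * rng.normal())
        if name == "R":
            amp *= float(np.exp(-1.5 * max(rs_balance, 0.0)))
        if name == "S":
            amp *= float(np.exp(2.0 * rs_balance))
        if name == "T":
            amp *= t_polarity
        bumps[name] = (off, width, amp)
    hr = float(rng.uniform(*spec.hr_bpm_range))
    return PatientMorphology(bumps=bumps, hr_bpm=hr)


def _pathology_transform(bumps: dict[str, tuple[float, float, float]],
                         ) -> dict[str, tuple[float, float, float]]:
    """A patient's V morphology: wide bizarre QRS, no P wave, discordant T."""
    out: dict[str, tuple[float, float, float]] = {}
    for name, (off, width, amp) in bumps.items():
        if name == "P":
            continue
        if name in ("Q", "R", "S"):
            off, width = off * 2.6, width * 2.6
            amp = amp * (1.5 if name == "R" else 2.0)
        if name == "T":
            amp, width = -1.2 * amp, 1.1 * width
        out[name] = (off, width, amp)
    return out


def make_beat_template(class_label: str, morph: PatientMorphology,
                       window_length: int = 180) -> np.ndarray:
    """Deterministic beat waveform for one patient and class.

    The complex occupies ``60 / hr_bpm`` of the one-second window, centered
    on the R peak at the window midpoint.  A/F/S templates are rendered as
    mildly rescaled normals — their morphological fidelity is out of scope;
    they exist to exercise the noisy-beat filter.
    """
    if class_label == "V":
        bumps = _pathology_transform(morph.bumps)
        scale = 1.0
    elif class_label == "N":
        bumps, scale = morph.bumps, 1.0
    elif class_label in ("A", "F", "S"):
        bumps, scale = morph.bumps, 0.85
    else:
        raise ValueError(f"unknown class label {class_label!r}")
    beat_s = 60.0 / morph.hr_bpm  # complex duration in seconds
    tau = (np.arange(window_length) - window_length // 2) / window_length  # window is 1 s
    wave = np.zeros(window_length)
    for off, width, amp in bumps.values():
        wave += amp * np.exp(-0.5 * ((tau - off * beat_s) / (width * beat_s)) ** 2)
    return scale * wave


def _jittered(morph: PatientMorphology, rng: np.random.Generator, sd: float,
              ) -> PatientMorphology:
    """Per-beat morphology jitter: small amplitude/width/timing wobble."""
    amp_f = float(np.exp(sd * rng.normal()))
    width_f = float(np.exp(0.5 * sd * rng.normal()))
    shift = float(0.02 * sd * rng.normal())
    bumps = {name: (off + shift, width * width_f, amp * amp_f)
             for name, (off, width, amp) in morph.bumps.items()}
    return replace(morph, bumps=bumps)


def make_patient(spec: CohortSpec, patient_index: int,
                 ) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Generate one patient's record and annotations, deterministic in
    ``(spec.seed, patient_index)``."""
    W = spec.window_length
    M = spec.n_windows
    if M < 1:
        raise ValueError("duration too short for one window")
    rng = np.random.default_rng([spec.seed, patient_index])
    morph = draw_morphology(rng, spec)

    labels = np.full(M, "N", dtype=object)
    u = rng.random(M)
    labels[u < spec.v_fraction] = "V"
    if spec.other_fraction > 0:
        other = (u >= spec.v_fraction) & (u < spec.v_fraction + spec.other_fraction)
        labels[other] = rng.choice(["A", "F", "S"], size=int(other.sum()))

    signal = np.empty(M * W)
    annotations: list[BeatAnnotation] = []
    for w in range(M):
        beat_morph = _jittered(morph, rng, spec.intra_patient_sd)
        signal[w * W:(w + 1) * W] = make_beat_template(str(labels[w]), beat_morph, W)
        fiducial = w * W + W // 2
        if spec.misalign_jitter > 0:
            fiducial += int(rng.integers(-spec.misalign_jitter, spec.misalign_jitter + 1))
        annotations.append(BeatAnnotation(
            sample_index=int(np.clip(fiducial, 0, M * W - 1)), label=str(labels[w])))
    if spec.noise_sd > 0:
        signal += spec.noise_sd * rng.normal(size=signal.size)

    annotations.sort(key=lambda a: a.sample_index)
    annotations = _dedupe(annotations)
    record = EcgRecord(patient_id=f"p{patient_index:02d}", fs=float(spec.fs), signal=signal)
    return record, annotations


def _dedupe(annotations: list[BeatAnnotation]) -> list[BeatAnnotation]:
    """Drop same-sample duplicates (only possible under misalign_jitter)."""
    out: list[BeatAnnotation] = []
    for a in annotations:
        if out and a.sample_index == out[-1].sample_index:
            continue
        out.append(a)
    return out


def make_cohort(spec: CohortSpec) -> dict[str, tuple[EcgRecord, list[BeatAnnotation]]]:
    """Generate all patients of a cohort, keyed by patient id."""
    cohort = {}
    for i in range(spec.n_patients):
        record, annotations = make_patient(spec, i)
        cohort[record.patient_id] = (record, annotations)
    return cohort


def write_cohort(cohort: dict[str, tuple[EcgRecord, list[BeatAnnotation]]],
                 out_dir: str, spec: CohortSpec) -> None:
    """Write a cohort in the CSV dialect plus a ``manifest.yaml``."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "fs": spec.fs,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "patients": {},
    }
    for pid, (record, annotations) in sorted(cohort.items()):
        rec_file, ann_file = f"{pid}.csv", f"{pid}_annotations.csv"
        write_record(os.path.join(out_dir, rec_file), record)
        write_annotations(os.path.join(out_dir, ann_file), annotations)
        manifest["patients"][pid] = {"record": rec_file, "annotations": ann_file}
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_cohort(cohort_dir: str) -> dict[str, tuple[EcgRecord, list[BeatAnnotation]]]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    import os

    from .io import read_annotations, read_record
    with open(os.path.join(cohort_dir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    cohort = {}
    for pid, files in sorted(manifest["patients"].items()):
        record = read_record(os.path.join(cohort_dir, files["record"]),
                             fs=manifest["fs"], patient_id=pid)
        annotations = read_annotations(os.path.join(cohort_dir, files["annotations"]))
        cohort[pid] = (record, annotations)
    return cohort
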