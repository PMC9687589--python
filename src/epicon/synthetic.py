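"""Synthetic resting-state EEG cohorts with known ground-truth coupling.

No public interictal resting-state cohort with the metadata this pipeline
needs exists, so the package ships a generator that emulates the relevant
structure of such recordings:

* a stable order-8 multivariate autoregressive (MVAR) carrier process whose
  sparse off-diagonal coefficients live inside the four scalp groups -- this
  is the planted, directed "functional connectivity";
* band-limited oscillators (delta/theta/alpha/beta sinusoids with random
  per-channel frequency and phase) over 1/f background noise;
* EOG blink transients loaded onto the frontal electrodes, and occasional
  flat (disconnected) segments;
* per-subject metadata (age, sex, diagnosis, a noisy clinician "EEG result")
  with calibratable sensitivity/specificity.

Subjects of the positive ("epileptic-like") class have the within-group
directed coupling of one designated scalp group scaled by ``1 + effect_size``.
Everything is deterministic given the seeds in :class:`CohortSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .montage import CHANNELS_1020, GROUP_ELECTRODES, electrode_positions
from .preprocess import RawRecording

DIAGNOSES = ("focal_lesional", "generalized_idiopathic", "focal_nonlesional",
             "non_epileptic")
#: Mix of epilepsy types among positive-class subjects (hospital-cohort-like
#: proportions: focal lesional dominates).
EPILEPSY_TYPE_PROBS = {"focal_lesional": 219 / 291,
                       "focal_nonlesional": 48 / 291,
                       "generalized_idiopathic": 24 / 291}

_OSC_BANDS = {"delta": (1.5, 3.5), "theta": (4.5, 7.5),
              "alpha": (8.5, 12.5), "beta": (14.0, 25.0)}
#: Oscillator amplitudes in uV (resting-state-like, alpha dominant).
_OSC_AMP_UV = {"delta": 4.2, "theta": 3.5, "alpha": 5.6, "beta": 2.1}
_PINK_SIGMA_UV = 4.0
_MVAR_SIGMA_UV = 14.0
_FLAT_DURATION_S = 3.0
_MVAR_ORDER = 8
#: effect size the base coupling is guaranteed stable for
_STABILITY_HEADROOM = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int
    prevalence: float = 0.5
    effect_size: float = 2.0
    duration_s: float = 120.0
    fs: float = 256.0
    eog_per_min: float = 10.0
    flat_prob: float = 0.05
    clinician_sens: float = 0.660
    clinician_spec: float = 0.629
    planted_group: str = "AL"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.fs < 128:
            raise ValueError("fs must be >= 128 Hz")
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60 s")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for p in (self.clinician_sens, self.clinician_spec):
            if not 0.0 <= p <= 1.0:
                raise ValueError("clinician_sens/clinician_spec must be in [0, 1]")
        if self.planted_group not in GROUP_ELECTRODES:
            raise ValueError(f"unknown scalp group {self.planted_group!r}")


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    diagnosis: str
    clinician_eeg_result: str
    recording: RawRecording | None
    ground_truth_coupling: np.ndarray

    def __post_init__(self) -> None:
        if not 16 <= self.age <= 98:
            raise ValueError("age must be within [16, 98] years")
        if np.any(np.diag(self.ground_truth_coupling) != 0):
            raise ValueError("ground_truth_coupling must have zero diagonal")


@njit(cache=True)
def _simulate_mvar(A, innovations):  # pragma: no cover - numba kernel
    p, K, _ = A.shape
    n = innovations.shape[0]
    x = np.zeros((n, K))
    for t in range(n):
        for c in range(K):
            x[t, c] = innovations[t, c]
        for m in range(p):
            tm = t - m - 1
            if tm < 0:
                break
            Am = A[m]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += Am[i, j] * x[tm, j]
                x[t, i] += acc
    return x


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of MVAR coefficients A (p,K,K)."""
    p, K, _ = A.shape
    comp = np.zeros((K * p, K * p))
    comp[:K] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[K:, :-K] = np.eye(K * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _planted_mask(planted_group: str) -> np.ndarray:
    idx = {ch: i for i, ch in enumerate(CHANNELS_1020)}
    sel = [idx[ch] for ch in GROUP_ELECTRODES[planted_group]]
    mask = np.zeros((len(CHANNELS_1020),) * 2, dtype=bool)
    mask[np.ix_(sel, sel)] = True
    return mask


def base_coupling(seed: int,
                  planted_group: str = "AL") -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level MVAR coefficients and the ground-truth gain matrix.

    Returns ``(A, gains)`` where ``A`` is (order, 19, 19) and ``gains`` is a
    19 x 19 zero-diagonal matrix of the off-diagonal lag-1 coupling weights
    (the ground-truth directed gains).

    The diagonal carries a damped stochastic oscillator per channel (lags 1-2
    plus a weak lag-8 echo); off-diagonal coefficients are sparse, positive,
    of magnitude <= 0.15 and restricted to ordered electrode pairs within a
    scalp group.  Off-diagonal weights are rescaled until the base companion
    spectral radius is <= 0.95 *and* the positive-class matrix up to the
    reference effect size (delta = 2) stays clearly stable; larger effect
    sizes may be rejected as unstable at generation time.
    """
    effect_size = _STABILITY_HEADROOM
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    K = len(CHANNELS_1020)
    A = np.zeros((_MVAR_ORDER, K, K))
    r = rng.uniform(0.45, 0.65, size=K)
    f_c = rng.uniform(4.0, 12.0, size=K)
    theta = 2 * np.pi * f_c / 256.0
    A[0, np.arange(K), np.arange(K)] = 2 * r * np.cos(theta)
    A[1, np.arange(K), np.arange(K)] = -(r ** 2)
    A[7, np.arange(K), np.arange(K)] += 0.01

    gains = np.zeros((K, K))
    idx = {ch: i for i, ch in enumerate(CHANNELS_1020)}
    for group, electrodes in GROUP_ELECTRODES.items():
        # the planted group gets a denser, stronger base so the class gain
        # acts on a clearly recoverable substrate
        dens, lo, hi = ((0.6, 0.08, 0.15) if group == planted_group
                        else (0.25, 0.03, 0.07))
        for a in electrodes:
            for b in electrodes:
                if a == b:
                    continue
                if rng.random() < dens:
                    gains[idx[b], idx[a]] = rng.uniform(lo, hi)
    mask = _planted_mask(planted_group)
    A[0] += gains
    for _ in range(60):
        planted = np.where(mask, gains, 0.0)
        A_pos = A.copy()
        A_pos[0] += effect_size * planted
        if (companion_spectral_radius(A) <= 0.95
                and companion_spectral_radius(A_pos) <= 0.98):
            break
        A[0] -= gains
        gains *= 0.85
        A[0] += gains
    else:
        raise RuntimeError(
            "could not stabilise base coupling: diagonal dynamics alone "
            f"exceed the radius budget (radius {companion_spectral_radius(A):.4f})"
        )
    return A, gains


def _pink_noise(rng: np.random.Generator, n: int, fs: float, K: int) -> np.ndarray:
    """1/f power background, unit std per channel, shape (K, n)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    spec = (rng.standard_normal((K, freqs.size))
            + 1j * rng.standard_normal((K, freqs.size))) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def eog_spatial_loading() -> np.ndarray:
    """Fixed frontal spatial loading of the synthetic EOG source.

    Exponential decay with distance from a virtual peri-orbital source, so
    Fp1/Fp2 load strongest, then F7/F8/F3/F4.  Also used as the default ICA
    matching template.
    """
    pos = electrode_positions()
    eye = np.array([0.0, 0.105, -0.01])
    d = np.array([np.linalg.norm(pos[ch] - eye) for ch in CHANNELS_1020])
    loading = np.exp(-d / 0.045)
    return loading / loading.max()


def _eog_waveform(fs: float) -> np.ndarray:
    """Biphasic low-frequency (< 4 Hz) blink transient, peak 1."""
    t = np.arange(int(round(0.6 * fs))) / fs - 0.3
    w = np.exp(-0.5 * (t / 0.07) ** 2) - 0.55 * np.exp(-0.5 * ((t - 0.13) / 0.11) ** 2)
    return w / np.abs(w).max()


def subject_coefficients(spec: CohortSpec, positive: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-class MVAR coefficients; positive class gets (1+effect_size) gain."""
    A, gains = base_coupling(spec.seed, spec.planted_group)
    mask = _planted_mask(spec.planted_group)
    planted = np.where(mask, gains, 0.0)
    if positive:
        A = A.copy()
        A[0] += spec.effect_size * planted
    radius = companion_spectral_radius(A)
    if radius >= 1.0:
        raise ValueError(
            f"unstable MVAR coupling specification: companion spectral radius "
            f"{radius:.4f} >= 1; reduce effect_size or base coupling"
        )
    truth = gains + (spec.effect_size * planted if positive else 0.0)
    np.fill_diagonal(truth, 0.0)
    return A, truth


def generate_subject_eeg(
    spec: CohortSpec, class_label: str, seed: int
) -> SubjectRecord:
    """One 19-channel recording; deterministic given ``seed``.

    ``class_label`` is one of the four diagnosis categories; any epileptic
    category receives the planted coupling gain.
    """
    if class_label not in DIAGNOSES:
        raise ValueError(f"unknown diagnosis {class_label!r}")
    positive = class_label != "non_epileptic"
    A, truth = subject_coefficients(spec, positive)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    K = len(CHANNELS_1020)
    n = int(round(spec.duration_s * spec.fs))

    innovations = rng.standard_normal((n, K))
    carrier = _simulate_mvar(np.ascontiguousarray(A), innovations).T
    carrier /= carrier.std(axis=1, keepdims=True)
    signal = _MVAR_SIGMA_UV * carrier

    t = np.arange(n) / spec.fs
    for band, (lo, hi) in _OSC_BANDS.items():
        f = rng.uniform(lo, hi, size=K)
        phase = rng.uniform(0, 2 * np.pi, size=K)
        amp = _OSC_AMP_UV[band] * rng.uniform(0.7, 1.3, size=K)
        signal += amp[:, None] * np.sin(2 * np.pi * f[:, None] * t + phase[:, None])
    signal += _PINK_SIGMA_UV * _pink_noise(rng, n, spec.fs, K)

    # EOG blink transients through the fixed frontal loading
    loading = eog_spatial_loading()
    wave = _eog_waveform(spec.fs)
    n_events = rng.poisson(spec.eog_per_min * spec.duration_s / 60.0)
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - wave.size))
        amp = 150.0 * rng.uniform(0.7, 1.3)
        signal[:, start:start + wave.size] += amp * np.outer(loading, wave)

    if rng.random() < spec.flat_prob:
        flat_n = int(round(_FLAT_DURATION_S * spec.fs))
        start = int(rng.integers(0, max(1, n - flat_n)))
        signal[:, start:start + flat_n] = 0.0

    rec = RawRecording(signal=signal, fs=spec.fs,
                       channel_names=list(CHANNELS_1020))
    age = float(np.round(rng.uniform(16, 98), 1))
    sex = "M" if rng.random() < 0.5 else "F"
    clinician = _clinician_label(rng, positive, spec)
    return SubjectRecord(
        subject_id=f"sub-{seed:06d}", age=age, sex=sex, diagnosis=class_label,
        clinician_eeg_result=clinician, recording=rec,
        ground_truth_coupling=truth,
    )


def _clinician_label(rng: np.random.Generator, positive: bool,
                     spec: CohortSpec) -> str:
    if positive:
        return "abnormal" if rng.random() < spec.clinician_sens else "normal"
    return "normal" if rng.random() < spec.clinician_spec else "abnormal"


def _draw_diagnosis(rng: np.random.Generator, positive: bool) -> str:
    if not positive:
        return "non_epileptic"
    cats = list(EPILEPSY_TYPE_PROBS)
    probs = np.array([EPILEPSY_TYPE_PROBS[c] for c in cats])
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def generate_metadata(spec: CohortSpec) -> pd.DataFrame:
    """Cohort metadata table only (no signals); cheap at any n.

    Columns: subject_id, age, sex, diagnosis, clinician_eeg_result, seed.
    Ages uniform on [16, 98]; sexes exactly balanced (shuffled); diagnosis
    drawn at the stated prevalence; the clinician label is Bernoulli with
    ``clinician_sens`` given an epileptic diagnosis and ``clinician_spec``
    given a non-epileptic one.
    """
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0407]))
    n = spec.n_subjects
    positive = rng.random(n) < spec.prevalence
    sexes = np.array(["M", "F"])[rng.permutation(np.arange(n) % 2)]
    rows = []
    for i in range(n):
        diag = _draw_diagnosis(rng, bool(positive[i]))
        rows.append({
            "subject_id": f"sub-{i:04d}",
            "age": float(np.round(rng.uniform(16, 98), 1)),
            "sex": str(sexes[i]),
            "diagnosis": diag,
            "clinician_eeg_result": _clinician_label(rng, bool(positive[i]), spec),
            "seed": int(rng.integers(0, 2 ** 31 - 1)),
        })
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec, signals: bool = True
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Full cohort: subject records (with recordings) plus the metadata table."""
    meta = generate_metadata(spec)
    records: list[SubjectRecord] = []
    for _, row in meta.iterrows():
        if signals:
            rec = generate_subject_eeg(spec, row["diagnosis"], int(row["seed"]))
            rec = replace_fields(rec, row)
        else:
            _, truth = subject_coefficients(
                spec, row["diagnosis"] != "non_epileptic")
            rec = SubjectRecord(
                subject_id=row["subject_id"], age=row["age"], sex=row["sex"],
                diagnosis=row["diagnosis"],
                clinician_eeg_result=row["clinician_eeg_result"],
                recording=None, ground_truth_coupling=truth,
            )
        records.append(rec)
    return records, meta.drop(columns=["seed"])


def replace_fields(rec: SubjectRecord, row: pd.Series) -> SubjectRecord:
    """Align a generated record with its row of the cohort metadata table."""
    rec.subject_id = row["subject_id"]
    rec.age = float(row["age"])
    rec.sex = str(row["sex"])
    rec.clinician_eeg_result = str(row["clinician_eeg_result"])
    return rec


def write_cohort(records: list[SubjectRecord], meta: pd.DataFrame,
                 out_dir) -> None:
    """Write one EDF per subject plus ``metadata.csv``."""
    from pathlib import Path

    from .edf import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        if rec.recording is None:
            raise ValueError(f"{rec.subject_id} has no signal data")
        write_edf(out / f"{rec.subject_id}.edf", rec.recording)
    meta.to_csv(out / "metadata.csv", index=False)
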