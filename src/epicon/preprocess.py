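"""Raw-EEG preprocessing: filter, EOG removal, epoching, cleaning, montage.

The fixed stage order is: band-pass filter -> ICA EOG removal -> epoching
(two epoch sets) -> flat-epoch exclusion -> statistical epoch cleaning ->
bipolar derivation.  All amplitudes are in microvolts throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import (
    CHANNELS_1020,
    MontageLayout,
    nearest_channels,
    normalize_channel_name,
)

logger = logging.getLogger(__name__)


@dataclass
class RawRecording:
    """Continuous multichannel EEG in uV."""

    signal: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_1020(self) -> None:
        """Check all 19 standard labels are present exactly once."""
        normalized = [normalize_channel_name(c) for c in self.channel_names]
        if sorted(normalized) != sorted(CHANNELS_1020):
            raise ValueError(
                "recording must contain the 19 standard 10-20 channels "
                f"exactly once, got {normalized}"
            )


@dataclass
class EpochSet:
    """Fixed-length non-overlapping epochs with per-epoch quality flags."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    epoch_length_s: float
    channel_names: list[str]
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolation_log: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ValueError("epoch sample count must equal fs * epoch_length_s")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not self.interpolation_log:
            self.interpolation_log = [[] for _ in range(self.epochs.shape[0])]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self) -> np.ndarray:
        """View of the retained epochs only."""
        return self.epochs[self.kept_mask]

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept_mask)


@dataclass
class ICATemplate:
    """Spatial EOG archetypes matched against ICA component topographies."""

    components: np.ndarray  # (n_templates, n_channels)
    correlation_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.components.shape[0] < 1:
            raise ValueError("at least one template component is required")
        if not 0.0 < self.correlation_threshold < 1.0:
            raise ValueError("correlation_threshold must be in (0, 1)")


def default_eog_template(threshold: float = 0.8) -> ICATemplate:
    """EOG template from the generator's known frontal source loading.

    Two archetypes: the symmetric blink topography and its lateral
    (left-right antisymmetric) counterpart, covering blinks and horizontal
    eye movements.
    """
    from .synthetic import eog_spatial_loading

    blink = eog_spatial_loading()
    lateral = blink.copy()
    right = [i for i, ch in enumerate(CHANNELS_1020)
             if ch in ("Fp2", "F4", "F8", "C4", "T4", "P4", "T6", "O2")]
    lateral[right] *= -1.0
    return ICATemplate(components=np.vstack([blink, lateral]),
                       correlation_threshold=threshold)


def design_bandpass(fs: float, low_hz: float = 1.0, high_hz: float = 40.0,
                    window_s: float = 6.6) -> np.ndarray:
    """Symmetric linear-phase FIR band-pass, Hamming design, odd length."""
    numtaps = int(round(window_s * fs))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs)
    # null the residual DC leakage of the windowed design exactly
    # (perturbs the pass-band response by < 1e-6)
    taps -= taps.sum() / numtaps
    return taps


def bandpass_filter(rec: RawRecording, low_hz: float = 1.0,
                    high_hz: float = 40.0) -> RawRecording:
    """Zero-phase-equivalent 1-40 Hz band-pass (delay-compensated FIR)."""
    if rec.fs <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper edge")
    taps = design_bandpass(rec.fs, low_hz, high_hz)
    min_samples = 3 * taps.size
    if rec.n_samples < min_samples:
        raise ValueError(
            f"recording too short for filtering: need >= {min_samples} samples "
            f"({min_samples / rec.fs:.1f} s), got {rec.n_samples}"
        )
    # symmetric taps + centred 'same' convolution == delay-compensated output
    filtered = sps.fftconvolve(rec.signal, taps[None, :], mode="same", axes=1)
    return replace(rec, signal=filtered)


def template_correlations(mixing: np.ndarray,
                          template: ICATemplate) -> np.ndarray:
    """|Pearson r| between component topographies and template archetypes.

    ``mixing`` is (n_channels, n_components); rows of the result are
    components, columns templates.  Matching is strict: a component is
    flagged only when its correlation *exceeds* the template threshold, so a
    correlation of exactly the threshold keeps the component.
    """

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / denom) if denom > 0 else 0.0

    n_comp = mixing.shape[1]
    n_temp = template.components.shape[0]
    corrs = np.zeros((n_comp, n_temp))
    for k in range(n_comp):
        for t in range(n_temp):
            corrs[k, t] = abs(_corr(mixing[:, k], template.components[t]))
    return corrs


def matched_components(corrs: np.ndarray, threshold: float) -> list[int]:
    """Components whose best template correlation strictly exceeds threshold."""
    return [k for k in range(corrs.shape[0]) if corrs[k].max() > threshold]


@dataclass
class EOGRemovalReport:
    removed: list[int]
    correlations: np.ndarray  # (n_components, n_templates)
    converged: bool
    n_iter: int


def remove_eog(rec: RawRecording, template: ICATemplate,
               n_components: int = 15, seed: int = 0,
               ) -> tuple[RawRecording, EOGRemovalReport]:
    """ICA decomposition; components matching the EOG template are subtracted.

    A component is removed when the absolute Pearson correlation between its
    spatial loading (mixing-matrix column) and any template topography is
    strictly above the template threshold.  Only the removed components'
    contribution is subtracted, so an empty match returns the signal
    unchanged exactly.

    For speed the unmixing is estimated on a decimated copy (~64 Hz; EOG
    topographies are low-frequency and recording-length independent) and
    applied at full rate.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if rec.signal.shape[0] < n_components:
        raise ValueError("need at least as many channels as ICA components")
    step = max(1, int(rec.fs // 64))
    X_fit = rec.signal[:, ::step].T  # samples x channels
    ica = FastICA(n_components=n_components, random_state=seed,
                  max_iter=300, tol=1e-4, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X_fit)
    converged = not any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    mixing = ica.mixing_  # (n_channels, n_components)
    if not np.all(np.isfinite(mixing)):
        raise RuntimeError(
            f"ICA failed to produce a finite mixing matrix after "
            f"{ica.n_iter_} iterations"
        )

    corrs = template_correlations(mixing, template)
    removed = matched_components(corrs, template.correlation_threshold)

    report = EOGRemovalReport(removed=removed, correlations=corrs,
                              converged=converged, n_iter=int(ica.n_iter_))
    if not removed:
        return rec, report
    # sources at full rate from the fitted unmixing; subtract removed part
    X_full = rec.signal.T
    sources = (X_full - ica.mean_) @ ica.components_.T
    artifact = sources[:, removed] @ mixing[:, removed].T
    cleaned = (X_full - artifact).T
    logger.info("removed %d EOG component(s): %s", len(removed), removed)
    return replace(rec, signal=cleaned), report


def make_epochs(rec: RawRecording, epoch_length_s: float,
                target_fs: float) -> EpochSet:
    """Decimate to ``target_fs`` and cut into non-overlapping epochs.

    Plain integer-stride decimation is safe here because the signal has
    already been low-passed at 40 Hz (< target Nyquist).
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_fs must divide the recording sampling rate")
    factor = int(round(factor))
    n_per = epoch_length_s * target_fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_length_s * target_fs must be an integer")
    n_per = int(round(n_per))
    if rec.duration_s < epoch_length_s:
        raise ValueError("recording shorter than one epoch")
    decimated = rec.signal[:, ::factor]
    n_epochs = decimated.shape[1] // n_per
    cut = decimated[:, : n_epochs * n_per]
    epochs = cut.reshape(cut.shape[0], n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), fs=target_fs,
                    epoch_length_s=epoch_length_s,
                    channel_names=list(rec.channel_names))


def drop_flat_epochs(es: EpochSet, min_ptp_uV: float = 1.0) -> EpochSet:
    """Flag epochs whose max peak-to-peak over all channels is below threshold."""
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # (n_ep, n_ch)
    flat = ptp.max(axis=1) < min_ptp_uV
    mask = es.kept_mask & ~flat
    return replace(es, epochs=es.epochs, kept_mask=mask,
                   interpolation_log=[list(x) for x in es.interpolation_log])


def _sensor_thresholds(epochs: np.ndarray, grid: np.ndarray,
                       n_folds: int) -> np.ndarray:
    """Per-channel peak-to-peak rejection threshold chosen by k-fold CV.

    For each candidate threshold the mean over sub-threshold training epochs
    is compared (RMSE) with the median over validation epochs; the threshold
    minimising the summed error is chosen.  Among thresholds within 0.1%
    relative error of the minimum the largest is taken, so homogeneous clean
    data yields a threshold above every epoch's amplitude.
    """
    n_ep, n_ch, _ = epochs.shape
    ptp = epochs.max(axis=2) - epochs.min(axis=2)
    folds = np.array_split(np.arange(n_ep), n_folds)
    thresholds = np.empty(n_ch)
    for c in range(n_ch):
        E = epochs[:, c, :]
        err = np.zeros(grid.size)
        keep = ptp[None, :, c] <= grid[:, None]  # (grid, n_ep)
        for val_idx in folds:
            train = np.ones(n_ep, dtype=bool)
            train[val_idx] = False
            val_med = np.median(E[val_idx], axis=0)
            K = keep & train[None, :]
            counts = K.sum(axis=1)
            means = (K @ E) / np.maximum(counts, 1)[:, None]
            e = np.sqrt(np.mean((means - val_med[None, :]) ** 2, axis=1))
            e[counts == 0] = np.inf
            err += e
        best = err.min()
        ok = np.flatnonzero(err <= best * 1.001)
        thresholds[c] = grid[ok[-1]]
    return thresholds


def clean_epochs(es: EpochSet, n_folds: int = 10, max_interp: int = 3,
                 grid: np.ndarray | None = None) -> EpochSet:
    """Threshold-based epoch cleaning with channel interpolation.

    Per-channel peak-to-peak thresholds are selected by ``n_folds``-fold
    cross-validation over a log-spaced candidate grid (10-500 uV by default).
    In each epoch, channels exceeding their threshold are repaired by
    inverse-distance-weighted interpolation from the 3 nearest clean
    channels when at most ``max_interp`` channels are bad; epochs with more
    bad channels are dropped.  Epochs with no supra-threshold channel are
    never modified.
    """
    kept_idx = es.kept_indices()
    if kept_idx.size < n_folds:
        raise ValueError(f"need at least {n_folds} kept epochs for CV cleaning")
    if grid is None:
        grid = np.logspace(np.log10(10.0), np.log10(500.0), 40)
    epochs = es.epochs.copy()
    sub = epochs[kept_idx]
    thr = _sensor_thresholds(sub, np.asarray(grid, dtype=float), n_folds)

    ptp = sub.max(axis=2) - sub.min(axis=2)  # (n_kept, n_ch)
    bad = ptp > thr[None, :]
    mask = es.kept_mask.copy()
    log = [list(x) for x in es.interpolation_log]
    names = es.channel_names
    n_dropped = 0
    for row, ep_i in enumerate(kept_idx):
        bad_ch = np.flatnonzero(bad[row])
        if bad_ch.size == 0:
            continue
        if bad_ch.size > max_interp:
            mask[ep_i] = False
            n_dropped += 1
            continue
        clean_names = [names[c] for c in range(len(names)) if c not in bad_ch]
        for c in bad_ch:
            neighbours = nearest_channels(names[c], clean_names, n=3)
            w = np.array([1.0 / max(d, 1e-6) for _, d in neighbours])
            w /= w.sum()
            idxs = [names.index(nm) for nm, _ in neighbours]
            epochs[ep_i, c, :] = np.tensordot(w, epochs[ep_i, idxs, :], axes=1)
            log[ep_i].append(names[c])
    n_kept0 = kept_idx.size
    if n_dropped > 0.5 * n_kept0:
        logger.warning("epoch cleaning dropped %d of %d epochs (> 50%%)",
                       n_dropped, n_kept0)
    return replace(es, epochs=epochs, kept_mask=mask, interpolation_log=log)


def to_bipolar(es: EpochSet, layout: MontageLayout | None = None) -> EpochSet:
    """Derive the 18 longitudinal bipolar channels (anode minus cathode)."""
    layout = layout or MontageLayout()
    name_map = {normalize_channel_name(c): i
                for i, c in enumerate(es.channel_names)}
    anode_idx, cathode_idx = [], []
    for a, c in layout.bipolar_pairs:
        for label in (a, c):
            if label not in name_map:
                raise ValueError(f"channel {label!r} missing from epoch set")
        anode_idx.append(name_map[a])
        cathode_idx.append(name_map[c])
    bipolar = es.epochs[:, anode_idx, :] - es.epochs[:, cathode_idx, :]
    return EpochSet(epochs=bipolar, fs=es.fs, epoch_length_s=es.epoch_length_s,
                    channel_names=layout.bipolar_names,
                    kept_mask=es.kept_mask.copy(),
                    interpolation_log=[list(x) for x in es.interpolation_log])
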