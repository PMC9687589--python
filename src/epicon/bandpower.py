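"""Welch band powers with 1/f correction, GBP epoch ranking and features.

Band edges are half-open [lo, hi) so shared edges (4, 8, 13 Hz) are never
counted twice.  Two band contexts exist: band-power features use delta
1-4 Hz and global 1-30 Hz; spectral-connectivity selections use delta
2-4 Hz and global 2-30 Hz (2.5 s epochs cannot hold five cycles below 2 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .montage import GROUP_ORDER, MontageLayout
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

BANDS = ("delta", "theta", "alpha", "beta")
GBP_EPSILON = 1e-12

BAND_EDGES: dict[str, dict[str, tuple[float, float]]] = {
    "bandpower": {
        "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0), "global": (1.0, 30.0),
    },
    "connectivity": {
        "delta": (2.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0), "global": (2.0, 30.0),
    },
}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float
    context: str = "bandpower"

    @classmethod
    def get(cls, name: str, context: str = "bandpower") -> "BandDefinition":
        lo, hi = BAND_EDGES[context][name]
        return cls(name=name, lo_hz=lo, hi_hz=hi, context=context)


def welch_psd(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (uV^2/Hz): 2 s Hamming segments, 50% overlap."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(2 * fs))
    if epoch.shape[1] < nperseg:
        raise ValueError("epoch must be at least one 2 s Welch segment long")
    freqs, psd = sps.welch(epoch, fs=fs, window="hamming", nperseg=nperseg,
                           noverlap=nperseg // 2, axis=1)
    return freqs, psd


def one_over_f_correct(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Multiply each bin's power by its frequency (the 0 Hz bin becomes 0)."""
    return psd * freqs


def relative_band_power(
    freqs: np.ndarray, corrected_psd: np.ndarray, context: str = "bandpower"
) -> dict[str, np.ndarray]:
    """Per-channel band fractions of the 1/f-corrected total (half-open bins)."""
    edges = BAND_EDGES[context]
    lo_t, hi_t = edges["global"]
    total_mask = (freqs >= lo_t) & (freqs < hi_t)
    total = corrected_psd[..., total_mask].sum(axis=-1)
    out: dict[str, np.ndarray] = {}
    zero = total <= 0
    if np.any(zero):
        logger.warning("zero total power in %d channel(s); fractions set to 0",
                       int(np.sum(zero)))
    safe_total = np.where(zero, 1.0, total)
    for band in BANDS:
        lo, hi = edges[band]
        mask = (freqs >= lo) & (freqs < hi)
        frac = corrected_psd[..., mask].sum(axis=-1) / safe_total
        out[band] = np.where(zero, 0.0, frac)
    return out


@dataclass
class BandPowerSet:
    """Per-kept-epoch band powers of one (bipolar) epoch set.

    ``rel``: (n_kept, n_channels, 4) relative powers over (delta, theta,
    alpha, beta); ``tap``: (n_kept, n_channels) 1/f-corrected total absolute
    power over the global band (uV^2, rectangle-rule band mass); ``gbp``:
    per-epoch GBP score; ``epoch_indices``: absolute epoch indices.
    """

    rel: np.ndarray
    tap: np.ndarray
    gbp: np.ndarray
    epoch_indices: np.ndarray
    context: str


def gbp_score(rel_chan_avg: np.ndarray, tap_chan_avg: float) -> float:
    """GBP = total absolute power / population variance of the 4 relative powers."""
    var = float(np.var(rel_chan_avg))  # population variance
    return float(tap_chan_avg) / max(var, GBP_EPSILON)


def compute_bandpowers(es: EpochSet, context: str = "bandpower") -> BandPowerSet:
    """Band powers, total power and GBP for every kept epoch."""
    kept = es.kept()
    idx = es.kept_indices()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs")
    freqs, psd = welch_psd(kept.reshape(-1, kept.shape[2]), es.fs)
    psd = psd.reshape(kept.shape[0], kept.shape[1], -1)
    df = freqs[1] - freqs[0]
    corrected = one_over_f_correct(freqs, psd)
    fracs = relative_band_power(freqs, corrected, context)
    rel = np.stack([fracs[b] for b in BANDS], axis=-1)
    lo, hi = BAND_EDGES[context]["global"]
    mask = (freqs >= lo) & (freqs < hi)
    tap = corrected[..., mask].sum(axis=-1) * df
    gbp = np.array([
        gbp_score(rel[e].mean(axis=0), tap[e].mean()) for e in range(rel.shape[0])
    ])
    return BandPowerSet(rel=rel, tap=tap, gbp=gbp, epoch_indices=idx,
                        context=context)


def select_top_epochs(bps: BandPowerSet, criterion: str, k: int = 50) -> np.ndarray:
    """Top-k kept epochs by channel-averaged band power (or GBP for 'global').

    Returns absolute epoch indices, best first; ties break toward the earlier
    epoch.  If fewer than k epochs are available all are returned.
    """
    if criterion == "global":
        scores = bps.gbp
    elif criterion in BANDS:
        scores = bps.rel[:, :, BANDS.index(criterion)].mean(axis=1)
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    order = np.argsort(-scores, kind="stable")
    if order.size < k:
        logger.info("epoch selection shortfall: %d available < k=%d",
                    order.size, k)
    return bps.epoch_indices[order[:k]]


def band_selections(bps: BandPowerSet, k: int = 50) -> dict[str, np.ndarray]:
    """Selections for the four bands plus the GBP-ranked global set."""
    return {b: select_top_epochs(bps, b, k) for b in (*BANDS, "global")}


def bandpower_features(
    bps: BandPowerSet, layout: MontageLayout,
    selections: dict[str, np.ndarray],
) -> dict[str, float]:
    """The 40 band-power features.

    Per band: median and standard deviation over the band's selected epochs
    of the group-mean relative power, per scalp group (32).  Total absolute
    power over the global selection: median and std per group (8).
    """
    pos = {int(e): i for i, e in enumerate(bps.epoch_indices)}
    feats: dict[str, float] = {}
    for band_i, band in enumerate(BANDS):
        rows = [pos[int(e)] for e in selections[band]]
        for group in GROUP_ORDER:
            gi = layout.group_indices(group)
            per_epoch = bps.rel[rows][:, gi, band_i].mean(axis=1)
            feats[f"bp_{band}_{group}_median"] = float(np.median(per_epoch))
            feats[f"bp_{band}_{group}_std"] = float(np.std(per_epoch))
    rows = [pos[int(e)] for e in selections["global"]]
    for group in GROUP_ORDER:
        gi = layout.group_indices(group)
        per_epoch = bps.tap[rows][:, gi].mean(axis=1)
        feats[f"tap_{group}_median"] = float(np.median(per_epoch))
        feats[f"tap_{group}_std"] = float(np.std(per_epoch))
    return feats
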