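"""Functional-connectivity estimators: IMCOH, PLV, MI and PDC.

Spectral estimators (IMCOH, PLV) work on multitaper cross-spectra of the
2.5 s / 128 Hz epochs on a 0.4 Hz bin grid; PDC comes from a single order-8
MVAR model per subject evaluated on a 0.25 Hz grid; MI is a time-domain
Kraskov k-nearest-neighbour estimate, median-combined over epochs.  Band
values are means over the band's frequency bins (half-open [lo, hi)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from ._ksg import ksg_mutual_information
from .bandpower import BAND_EDGES
from .montage import GROUP_ORDER, MontageLayout

logger = logging.getLogger(__name__)

PDC_FREQS = np.arange(1, 121) * 0.25  # 0.25 .. 30 Hz inclusive
MULTITAPER_NW = 4.0


@dataclass
class SpectralEstimate:
    """Epoch-averaged multitaper cross-spectral accumulators.

    ``mean_Sxy``: complex (n_ch, n_ch, n_bins) epoch mean of the per-epoch
    cross-spectral density; ``mean_phase``: epoch mean of Sxy/|Sxy| (the
    unit-modulus cross-spectral phase); ``mean_Sxx``: real (n_ch, n_bins)
    epoch-mean auto-spectra; ``freqs``: the band's bin grid in Hz.
    """

    mean_Sxy: np.ndarray
    mean_phase: np.ndarray
    mean_Sxx: np.ndarray
    freqs: np.ndarray
    n_epochs: int


@dataclass
class ConnectivityMatrix:
    values: np.ndarray  # (n_ch, n_ch), zero diagonal
    estimator: str  # imcoh | plv | mi | pdc
    band: str
    directed: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class MVARModel:
    """Least-squares MVAR fit: x(n) = sum_m A(m) x(n-m) + e(n)."""

    A: np.ndarray  # (order, K, K)
    noise_cov: np.ndarray  # (K, K) innovation covariance
    fs: float

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]


def cross_spectra(epochs: np.ndarray, fs: float, band: str,
                  context: str = "connectivity") -> SpectralEstimate:
    """Multitaper (DPSS, NW=4) cross- and auto-spectra on the band's bins.

    ``epochs`` is (n_epochs, n_channels, n_samples); the native rFFT grid of
    a 2.5 s / 128 Hz epoch has exactly 0.4 Hz spacing.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
    n_ep, n_ch, n = epochs.shape
    lo, hi = BAND_EDGES[context][band]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= lo) & (freqs < hi)
    if not np.any(sel):
        raise ValueError(f"band {band!r} outside the spectral range")
    n_tapers = int(2 * MULTITAPER_NW - 1)
    tapers = dpss(n, MULTITAPER_NW, n_tapers)  # (n_tapers, n)

    acc_Sxy = np.zeros((n_ch, n_ch, int(sel.sum())), dtype=complex)
    acc_phase = np.zeros_like(acc_Sxy)
    acc_Sxx = np.zeros((n_ch, int(sel.sum())))
    for e in range(n_ep):
        X = np.fft.rfft(epochs[e][None, :, :] * tapers[:, None, :], axis=2)
        X = X[:, :, sel]
        Sxy = np.einsum("tcf,tdf->cdf", X, np.conj(X)) / n_tapers
        acc_Sxy += Sxy
        mag = np.abs(Sxy)
        zero = mag == 0
        if np.any(zero):
            logger.warning("zero |Sxy| in %d bins of one epoch", int(zero.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            ph = np.where(zero, 0.0, Sxy / np.where(zero, 1.0, mag))
        acc_phase += ph
        acc_Sxx += np.real(np.einsum("tcf,tcf->cf", X, np.conj(X))) / n_tapers
    return SpectralEstimate(
        mean_Sxy=acc_Sxy / n_ep, mean_phase=acc_phase / n_ep,
        mean_Sxx=acc_Sxx / n_ep, freqs=freqs[sel], n_epochs=n_ep,
    )


def imcoh(se: SpectralEstimate, band: str) -> ConnectivityMatrix:
    """|Im(coherency)| per bin, averaged over the band's bins.

    Coherency = E[Sxy] / sqrt(E[Sxx] E[Syy]); absolute values of its
    imaginary part are retained (sign deliberately discarded).
    """
    if se.n_epochs < 2:
        raise ValueError("imcoh needs at least 2 epochs")
    denom = np.sqrt(se.mean_Sxx[:, None, :] * se.mean_Sxx[None, :, :])
    zero = denom <= 0
    if np.any(zero):
        logger.warning("zero-power channel in imcoh; values set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(zero, 0.0, np.imag(se.mean_Sxy) / np.where(zero, 1.0, denom))
    values = np.abs(coh).mean(axis=2)
    return ConnectivityMatrix(values=values, estimator="imcoh", band=band,
                              directed=False)


def plv(se: SpectralEstimate, band: str) -> ConnectivityMatrix:
    """|epoch mean of Sxy/|Sxy|| per bin, averaged over the band's bins."""
    if se.n_epochs < 2:
        raise ValueError("plv needs at least 2 epochs")
    values = np.abs(se.mean_phase).mean(axis=2)
    return ConnectivityMatrix(values=values, estimator="plv", band=band,
                              directed=False)


def mutual_information(epochs: np.ndarray, k: int = 3) -> ConnectivityMatrix:
    """Kraskov kNN MI (nats) per channel pair; median over epochs, clipped >= 0.

    ``epochs`` should be the global-band-selected 2.5 s epochs.
    """
    epochs = np.asarray(epochs, dtype=float)
    n_ep, n_ch, _ = epochs.shape
    iu = np.triu_indices(n_ch, 1)
    pairs = np.column_stack(iu).astype(np.int64)
    per_epoch = np.empty((n_ep, pairs.shape[0]))
    for e in range(n_ep):
        data = epochs[e]
        constant = np.ptp(data, axis=1) == 0
        vals = ksg_mutual_information(data, pairs, k=k)
        if np.any(constant):
            dead = constant[pairs[:, 0]] | constant[pairs[:, 1]]
            vals = np.where(dead, 0.0, vals)
        per_epoch[e] = vals
    med = np.median(per_epoch, axis=0)
    med = np.clip(med, 0.0, None)
    values = np.zeros((n_ch, n_ch))
    values[iu] = med
    values += values.T
    return ConnectivityMatrix(values=values, estimator="mi", band="global",
                              directed=False)


def fit_mvar(epochs: np.ndarray, fs: float, order: int = 8) -> MVARModel:
    """One joint least-squares MVAR fit over all epochs.

    Normal equations are accumulated per epoch, so the regression never
    crosses epoch boundaries.  No ridge penalty.
    """
    epochs = np.asarray(epochs, dtype=float)
    n_ep, K, n = epochs.shape
    usable = n_ep * (n - order)
    if usable < 10 * K * order:
        raise ValueError(
            f"too few samples to fit MVAR: {usable} usable rows < "
            f"{10 * K * order}; supply more or longer epochs"
        )
    ZtZ = np.zeros((K * order, K * order))
    ZtY = np.zeros((K * order, K))
    for e in range(n_ep):
        x = epochs[e]
        Y = x[:, order:].T  # (n - order, K)
        Z = np.concatenate([x[:, order - m: n - m].T for m in range(1, order + 1)],
                           axis=1)  # (n - order, K * order)
        ZtZ += Z.T @ Z
        ZtY += Z.T @ Y
    try:
        coef = np.linalg.solve(ZtZ, ZtY)  # (K*order, K)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "rank-deficient MVAR normal equations; use more epochs"
        ) from exc
    A = coef.T.reshape(K, order, K).transpose(1, 0, 2)
    resid_sq = np.zeros((K, K))
    count = 0
    for e in range(n_ep):
        x = epochs[e]
        Y = x[:, order:].T
        Z = np.concatenate([x[:, order - m: n - m].T for m in range(1, order + 1)],
                           axis=1)
        R = Y - Z @ coef
        resid_sq += R.T @ R
        count += R.shape[0]
    return MVARModel(A=A, noise_cov=resid_sq / count, fs=fs)


def pdc_spectrum(model: MVARModel, freqs: np.ndarray = PDC_FREQS) -> np.ndarray:
    """PDC_ij(f) on the given grid; (n_bins, K, K), columns sum-of-squares 1.

    Abar(f) = I - sum_m A(m) exp(-i 2 pi f m / fs); PDC_ij =
    |Abar_ij| / sqrt(sum_k |Abar_kj|^2) -- normalized by the outgoing flow
    of source j.
    """
    p, K, _ = model.A.shape
    m = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, m) / model.fs)  # (F, p)
    Abar = np.eye(K)[None, :, :] - np.einsum("fm,mij->fij", phase, model.A)
    mag = np.abs(Abar)
    col_norm = np.sqrt((mag ** 2).sum(axis=1, keepdims=True))  # (F, 1, K)
    if np.any(col_norm == 0):
        raise ValueError("zero column norm in PDC normalization")
    return mag / col_norm


def pdc(model: MVARModel, band: str, context: str = "connectivity"
        ) -> ConnectivityMatrix:
    """Band-mean PDC matrix (diagonal zeroed for graph use)."""
    lo, hi = BAND_EDGES[context][band]
    sel = (PDC_FREQS >= lo) & (PDC_FREQS < hi)
    spec = pdc_spectrum(model, PDC_FREQS[sel])
    return ConnectivityMatrix(values=spec.mean(axis=0), estimator="pdc",
                              band=band, directed=True)


def summarize_groups(cm: ConnectivityMatrix, layout: MontageLayout
                     ) -> dict[str, tuple[float, float]]:
    """Within-group mean and population std of off-diagonal entries.

    Directed matrices use all 20 ordered off-diagonal entries of the 5x5
    group submatrix; undirected ones the 10 unique pairs.
    """
    out: dict[str, tuple[float, float]] = {}
    for group in GROUP_ORDER:
        gi = layout.group_indices(group)
        sub = cm.values[np.ix_(gi, gi)]
        if cm.directed:
            vals = sub[~np.eye(len(gi), dtype=bool)]
        else:
            vals = sub[np.triu_indices(len(gi), 1)]
        out[group] = (float(vals.mean()), float(vals.std()))
    return out
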