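"""End-to-end orchestration: EEG in, feature table and evaluation report out.

Stage order per subject: band-pass filter -> ICA EOG removal -> dual epoching
(5 s @ 256 Hz for band powers, 2.5 s @ 128 Hz for connectivity) -> flat-epoch
exclusion -> CV epoch cleaning -> bipolar derivation -> band-power /
connectivity / graph / asymmetry features (784 per subject).  Cohort level:
stratified split, grid-searched classifier, surrogate-ROC evaluation and
clinician-label fusion.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify
from .bandpower import band_selections, bandpower_features, compute_bandpowers
from .config import PipelineConfig
from .connectivity import (cross_spectra, fit_mvar, imcoh, mutual_information,
                           pdc, plv)
from .montage import CHANNELS_1020, MontageLayout, normalize_channel_name
from .netfeatures import (FIVE_BANDS, assemble_features, connectivity_features,
                          feature_names, graph_features)
from .preprocess import (ICATemplate, RawRecording, bandpass_filter,
                         clean_epochs, default_eog_template, drop_flat_epochs,
                         make_epochs, remove_eog, to_bipolar)

logger = logging.getLogger(__name__)

TASKS = ("all-epilepsy", "focal-lesional")


def _canonical_order(rec: RawRecording) -> RawRecording:
    rec.validate_1020()
    normalized = [normalize_channel_name(c) for c in rec.channel_names]
    order = [normalized.index(ch) for ch in CHANNELS_1020]
    return RawRecording(signal=rec.signal[order], fs=rec.fs,
                        channel_names=list(CHANNELS_1020))


def extract_subject_features(
    rec: RawRecording,
    config: PipelineConfig | None = None,
    layout: MontageLayout | None = None,
    template: ICATemplate | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """The canonical 784-entry feature vector for one recording."""
    cfg = config or PipelineConfig()
    layout = layout or MontageLayout()
    template = template or default_eog_template(cfg.ica_threshold)

    rec = _canonical_order(rec)
    filtered = bandpass_filter(rec, cfg.filter_low_hz, cfg.filter_high_hz)
    cleaned, _ = remove_eog(filtered, template, cfg.ica_components, seed=seed)

    bp_fs = min(cfg.bandpower_fs, rec.fs)
    es_bp = make_epochs(cleaned, cfg.bandpower_epoch_s, bp_fs)
    es_conn = make_epochs(cleaned, cfg.connectivity_epoch_s,
                          cfg.connectivity_fs)
    feats_blocks = []
    # band-power block on the 5 s epochs
    es_bp = drop_flat_epochs(es_bp, cfg.flat_ptp_uv)
    es_bp = clean_epochs(es_bp, cfg.clean_folds, cfg.clean_max_interp)
    bip_bp = to_bipolar(es_bp, layout)
    bps = compute_bandpowers(bip_bp, context="bandpower")
    sel_bp = band_selections(bps, cfg.top_k_epochs)
    feats_blocks.append(bandpower_features(bps, layout, sel_bp))

    # connectivity block on the 2.5 s epochs
    es_conn = drop_flat_epochs(es_conn, cfg.flat_ptp_uv)
    es_conn = clean_epochs(es_conn, cfg.clean_folds, cfg.clean_max_interp)
    bip_conn = to_bipolar(es_conn, layout)
    bps_conn = compute_bandpowers(bip_conn, context="connectivity")
    sel_conn = band_selections(bps_conn, cfg.top_k_epochs)

    def _epochs_for(indices: np.ndarray) -> np.ndarray:
        return bip_conn.epochs[np.asarray(indices, dtype=int)]

    matrices = {}
    for band in FIVE_BANDS:
        band_epochs = _epochs_for(sel_conn[band if band != "global" else "global"])
        se = cross_spectra(band_epochs, cfg.connectivity_fs, band)
        matrices[("imcoh", band)] = imcoh(se, band)
        matrices[("plv", band)] = plv(se, band)
    global_epochs = _epochs_for(sel_conn["global"])
    matrices[("mi", "global")] = mutual_information(global_epochs,
                                                    k=cfg.mi_neighbors)
    model = fit_mvar(global_epochs, cfg.connectivity_fs, order=cfg.mvar_order)
    for band in FIVE_BANDS:
        matrices[("pdc", band)] = pdc(model, band)

    feats_blocks.append(connectivity_features(matrices, layout))
    feats_blocks.append(graph_features(matrices, layout))
    return assemble_features(*feats_blocks)


def load_edf_cohort(edf_dir) -> tuple[list[RawRecording], pd.DataFrame]:
    """Read ``metadata.csv`` plus one EDF per subject from a directory."""
    from .edf import read_edf

    edf_dir = Path(edf_dir)
    meta = pd.read_csv(edf_dir / "metadata.csv")
    recs = [read_edf(edf_dir / f"{sid}.edf") for sid in meta["subject_id"]]
    return recs, meta


def extract_cohort_features(
    records, meta: pd.DataFrame, config: PipelineConfig | None = None,
    cache_dir=None, skip_bad: bool = False,
) -> pd.DataFrame:
    """Feature table (subject_id + 784 columns) for a cohort.

    ``records`` may be :class:`SubjectRecord` or :class:`RawRecording`
    instances aligned with ``meta`` rows.  Per-subject features are cached
    under ``cache_dir`` when given, keyed by subject id.
    """
    import joblib

    cfg = config or PipelineConfig()
    layout = MontageLayout()
    template = default_eog_template(cfg.ica_threshold)
    rows, kept_ids = [], []
    for i, rec in enumerate(records):
        sid = str(meta.iloc[i]["subject_id"])
        raw = getattr(rec, "recording", rec)
        cache_file = None
        if cache_dir is not None:
            cache_file = Path(cache_dir) / f"{sid}.features.joblib"
            if cache_file.exists():
                rows.append(joblib.load(cache_file))
                kept_ids.append(sid)
                continue
        try:
            feats = extract_subject_features(
                raw, cfg, layout, template, seed=cfg.seed + i)
        except Exception as exc:
            msg = f"feature extraction failed for subject {sid}: {exc}"
            if skip_bad:
                logger.warning("%s (skipped)", msg)
                continue
            raise RuntimeError(msg) from exc
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            joblib.dump(feats, cache_file)
        rows.append(feats)
        kept_ids.append(sid)
    table = pd.DataFrame(rows, columns=feature_names())
    table.insert(0, "subject_id", kept_ids)
    return table


def task_labels(meta: pd.DataFrame, task: str) -> tuple[np.ndarray, np.ndarray]:
    """(row mask, binary labels) for a classification task."""
    diag = meta["diagnosis"].to_numpy()
    if task == "all-epilepsy":
        mask = np.ones(len(meta), dtype=bool)
        y = (diag != "non_epileptic").astype(int)
    elif task == "focal-lesional":
        mask = np.isin(diag, ["focal_lesional", "non_epileptic"])
        y = (diag[mask] == "focal_lesional").astype(int)
    else:
        raise ValueError(f"unknown task {task!r}; choose from {TASKS}")
    return mask, y


def run_classification(
    features: pd.DataFrame, meta: pd.DataFrame, task: str = "all-epilepsy",
    config: PipelineConfig | None = None, grid: dict | None = None,
) -> dict:
    """Split, train, evaluate and fuse for one task; JSON-ready report."""
    cfg = config or PipelineConfig()
    mask, y = task_labels(meta, task)
    X = features[feature_names()].to_numpy(dtype=float)[mask]
    sub_meta = meta[mask].reset_index(drop=True)
    tr, te = classify.split_train_test(X, y, ratio=cfg.split_ratio,
                                       seed=cfg.seed)
    model, cv_report = classify.train_model(
        X[tr], y[tr], model_kind=cfg.model_kind, reduction=cfg.reduction,
        grid=grid, cv_folds=cfg.cv_folds, seed=cfg.seed)
    report = classify.evaluate(model, X[te], y[te], seed=cfg.seed,
                               n_surrogates=cfg.n_surrogates)
    clinician = (sub_meta["clinician_eeg_result"].to_numpy() == "abnormal"
                 ).astype(int)
    model_pred = (classify._scores(model, X[te])
                  >= report.optimal_threshold).astype(int)
    fusion = {
        op: classify.fuse_with_clinician(model_pred, clinician[te], y[te], op)
        for op in ("AND", "OR")
    }
    report.fusion = fusion
    return {
        "task": task,
        "n_train": int(tr.size),
        "n_test": int(te.size),
        "cv": asdict(cv_report),
        "test": {k: v for k, v in asdict(report).items()
                 if k not in ("roc_fpr", "roc_tpr", "surrogate_aucs")},
        "roc": {"fpr": report.roc_fpr, "tpr": report.roc_tpr},
        "seed": cfg.seed,
    }


def run_pipeline(
    cohort, config: PipelineConfig | None = None, task: str = "all-epilepsy",
    cache_dir=None, skip_bad: bool = False, grid: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline on an EDF directory or an in-memory cohort.

    ``cohort`` is either a path to a directory holding ``metadata.csv`` and
    per-subject EDFs, or a ``(records, metadata)`` tuple.  Returns the
    feature table and the evaluation report.
    """
    if isinstance(cohort, (str, Path)):
        records, meta = load_edf_cohort(cohort)
    else:
        records, meta = cohort
    features = extract_cohort_features(records, meta, config,
                                       cache_dir=cache_dir, skip_bad=skip_bad)
    meta = meta[meta["subject_id"].isin(features["subject_id"])].reset_index(
        drop=True)
    report = run_classification(features, meta, task, config, grid=grid)
    return features, report
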