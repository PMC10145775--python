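"""End-to-end orchestration: fit the three models on annotated recordings and
run the full segment -> classify -> score chain on a new recording."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, preprocess, regimes, scoring, segmentation

logger = logging.getLogger(__name__)


@dataclass
class PipelineModels:
    """Everything learned from the training cohort."""

    beta: float
    classifier: regimes.RegimeClassifier
    healthy_model: scoring.HealthyModel | None = None
    min_size: int = segmentation.DEFAULT_MIN_SIZE


@dataclass
class AnalysisResult:
    """Output of the full pipeline on one recording."""

    breakpoints_s: np.ndarray
    regime_records: list          # RegimeRecord with predicted labels
    labels: list
    scores: list                  # RegimeScore or None, parallel to regimes
    criteria: list                # GaitCriteria or None, parallel to regimes


def prepare(rec: preprocess.ImuRecording):
    """Band-pass filter a raw recording and build its spectral series."""
    filtered = preprocess.bandpass(rec)
    return filtered, preprocess.spectral_series(filtered)


def annotate_frames(ann, spec: preprocess.SpectralSeries) -> tuple:
    """Ground-truth breakpoints of an AnnotatedRecording as frame indices."""
    return segmentation.seconds_to_frames(ann.true_changepoints_s, spec)


def true_regime_records(ann, filtered: preprocess.ImuRecording) -> list:
    """Labeled RegimeRecords cut at the annotated change points."""
    recs = regimes.slice_regimes(filtered, ann.true_changepoints_s)
    for r, lab, rid in zip(recs, ann.regime_labels, ann.regime_ids or [""] * len(recs)):
        r.label = lab
        r.regime_id = rid
    return recs


def fit_models(
    train_subjects,
    calibration_subjects=None,
    min_size: int = segmentation.DEFAULT_MIN_SIZE,
    with_healthy_model: bool = True,
) -> PipelineModels:
    """Learn penalty, classifier and healthy model from annotated subjects.

    ``train_subjects`` is a list of synthetic ``Subject`` objects (or
    anything holding an AnnotatedRecording under ``.recording``).  The
    penalty is calibrated on ``calibration_subjects`` when given (a subset
    keeps the search affordable on large cohorts), otherwise on the full
    training set.
    """
    train_subjects = list(train_subjects)
    calib = list(calibration_subjects) if calibration_subjects is not None else train_subjects
    annotated = []
    for s in calib:
        filtered, spec = prepare(s.recording.recording)
        annotated.append((spec, segmentation.seconds_to_frames(s.recording.true_changepoints_s, spec)))
    cal = segmentation.calibrate_penalty(annotated, min_size=min_size)
    feats, labs = [], []
    healthy_criteria = []
    for s in train_subjects:
        ann = s.recording
        filtered, _ = prepare(ann.recording)
        for r in true_regime_records(ann, filtered):
            feats.append(regimes.extract_features(r))
            labs.append(r.label)
            if r.label == "walking" and getattr(s, "healthy", ann.healthy):
                healthy_criteria.append(scoring.compute_criteria(r.samples))
    clf = regimes.fit_classifiers(feats, labs)
    healthy = None
    if with_healthy_model:
        healthy = scoring.fit_healthy_model(healthy_criteria)
    return PipelineModels(beta=cal.beta_opt, classifier=clf,
                          healthy_model=healthy, min_size=min_size)


def analyze(rec: preprocess.ImuRecording, models: PipelineModels) -> AnalysisResult:
    """Segment, classify and (where walking) score one raw recording."""
    filtered, spec = prepare(rec)
    seg = segmentation.pelt_segment(spec, models.beta, min_size=models.min_size)
    bks_s = segmentation.frames_to_seconds(seg, spec)
    recs = regimes.slice_regimes(filtered, bks_s)
    feats = [regimes.extract_features(r) for r in recs]
    labels = regimes.predict_labels(models.classifier, feats)
    scores, criteria = [], []
    for r, lab in zip(recs, labels):
        r.label = lab
        crit = None
        if lab == "walking" and r.duration_s >= scoring.MIN_SCORED_DURATION_S:
            try:
                crit = scoring.compute_criteria(r.samples)
            except ValueError:
                logger.warning(
                    "walking regime [%.1f, %.1f) s not scoreable; left unscored",
                    *r.span,
                )
        elif lab == "walking":
            logger.info(
                "walking regime [%.1f, %.1f) s shorter than %.0f s; left unscored",
                *r.span, scoring.MIN_SCORED_DURATION_S,
            )
        criteria.append(crit)
        scores.append(
            scoring.score_regime(crit, models.healthy_model)
            if crit is not None and models.healthy_model is not None
            else None
        )
    return AnalysisResult(
        breakpoints_s=bks_s, regime_records=recs, labels=labels,
        scores=scores, criteria=criteria,
    )


def sample_label_arrays(ann, result: AnalysisResult) -> tuple:
    """True and predicted per-sample label arrays on the 100 Hz grid."""
    rec = ann.recording
    fs = rec.sampling_rate_hz
    dur = rec.duration_s
    t = evaluation.labels_to_samples(ann.true_changepoints_s, ann.regime_labels, dur, fs)
    p = evaluation.labels_to_samples(result.breakpoints_s, result.labels, dur, fs)
    return t, p


__all__ = [
    "PipelineModels",
    "AnalysisResult",
    "prepare",
    "annotate_frames",
    "true_regime_records",
    "fit_models",
    "analyze",
    "sample_label_arrays",
]
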