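"""Performance metrics: window profile correlation and within-transcript
crosslink-site discrimination.

Window-level accuracy is the Pearson correlation between a predicted
probability vector and the observed count vector (PCC is affine-invariant,
so probabilities versus raw counts is immaterial), averaged over windows.
Site-level accuracy treats called crosslink positions within one transcript
as positives and all other positions of the same transcript as negatives,
computing auROC and average precision per transcript and averaging across
qualifying transcripts — scores are never pooled across transcripts because
position-wise probabilities are only comparable within one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricReport", "profile_pcc", "mean_profile_pcc",
           "transcript_auroc_ap", "evaluate_transcripts",
           "replicate_pcc_baseline"]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Per-item metric values, their mean, and items excluded with reasons."""

    values: dict
    excluded: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        if not self.values:
            return float("nan")
        return float(np.mean(list(self.values.values())))


def profile_pcc(predicted, observed) -> float:
    """Pearson correlation between a predicted profile and observed counts."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if len(predicted) < 2:
        raise ValueError("need at least 2 positions")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise ValueError("PCC undefined for a constant vector")
    return float(stats.pearsonr(predicted, observed)[0])


def mean_profile_pcc(predictions, observations, ids=None) -> MetricReport:
    """Window PCCs with constant-count windows excluded (and logged)."""
    ids = ids if ids is not None else range(len(predictions))
    values, excluded = {}, {}
    for key, pred, obs in zip(ids, predictions, observations):
        try:
            values[key] = profile_pcc(pred, obs)
        except ValueError as err:
            excluded[key] = str(err)
            logger.warning("window %s excluded from PCC: %s", key, err)
    return MetricReport(values, excluded)


def transcript_auroc_ap(scores, positive_positions) -> tuple[float, float]:
    """(auROC, AP) of per-position scores against crosslink positions.

    Positives are the given positions; negatives are all other positions of
    the same transcript.  Requires at least one of each.  auROC uses the
    rank/Wilcoxon convention (ties get half credit); AP is the step-wise
    interpolation-free sum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.zeros(len(scores), dtype=int)
    positive_positions = np.asarray(sorted(positive_positions), dtype=int)
    if len(positive_positions) and (
        positive_positions[0] < 0 or positive_positions[-1] >= len(scores)
    ):
        raise ValueError("positive position outside transcript")
    labels[positive_positions] = 1
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one positive and one negative position")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def evaluate_transcripts(score_vectors, positive_sets, ids=None,
                         min_positives: int = 1) -> tuple[MetricReport, MetricReport]:
    """Per-transcript auROC and AP reports.

    Transcripts with fewer than ``min_positives`` crosslink sites (or without
    any negative position) are excluded and reported, mirroring the
    requirement that a transcript be expressed in the experiment.
    """
    ids = ids if ids is not None else range(len(score_vectors))
    auroc, ap = {}, {}
    excluded = {}
    for key, scores, positives in zip(ids, score_vectors, positive_sets):
        if len(positives) < min_positives:
            excluded[key] = f"fewer than {min_positives} crosslink sites"
            continue
        try:
            auroc[key], ap[key] = transcript_auroc_ap(scores, positives)
        except ValueError as err:
            excluded[key] = str(err)
    return MetricReport(auroc, dict(excluded)), MetricReport(ap, dict(excluded))


def replicate_pcc_baseline(p, n_counts: int, reps: int = 500,
                           seed: int | None = None) -> tuple[float, float]:
    """Compare model-vs-sample PCC with replicate-vs-replicate PCC.

    Repeatedly draws pairs of multinomial count samples of size ``n_counts``
    from the true distribution ``p`` and returns (mean PCC between ``p`` and a
    sample, mean PCC between the two samples of a pair).  Because each sample
    carries independent multinomial noise while ``p`` carries none, the first
    mean exceeds the second — the population profile is a better predictor of
    a replicate than a second replicate is.
    """
    p = np.asarray(p, dtype=float)
    if reps < 2:
        raise ValueError("need at least 2 replicate pairs")
    if (p > 0).sum() < 2:
        raise ValueError("degenerate (point-mass) truth: PCC undefined")
    rng = np.random.default_rng(seed)
    model_vs_sample, sample_vs_sample = [], []
    for _ in range(reps):
        a = rng.multinomial(n_counts, p)
        b = rng.multinomial(n_counts, p)
        if np.ptp(a) and np.ptp(p):
            model_vs_sample.append(stats.pearsonr(p, a)[0])
        if np.ptp(b) and np.ptp(p):
            model_vs_sample.append(stats.pearsonr(p, b)[0])
        if np.ptp(a) and np.ptp(b):
            sample_vs_sample.append(stats.pearsonr(a, b)[0])
    mvs = float(np.mean(model_vs_sample)) if model_vs_sample else float("nan")
    svs = float(np.mean(sample_vs_sample)) if sample_vs_sample else float("nan")
    return mvs, svs
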