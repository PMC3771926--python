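"""Clustering and region-recovery evaluation metrics.

Clustering quality is the size-weighted combined F-score: each reference
family is matched with the cluster maximizing the harmonic mean of precision
and recall, and family scores are averaged weighted by family size.  Region
recovery is measured both per hit (a predicted region paired with the right
reference label on the right sequence) and per residue (positional overlap
between predicted and reference intervals).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .seqdata import RegionAnnotation


def precision_recall(cluster: set[str], family: set[str]) -> tuple[float, float]:
    """Set precision/recall of a cluster against a reference family."""
    if not family:
        raise ValueError("family must be non-empty")
    tp = len(cluster & family)
    fp = len(cluster - family)
    fn = len(family - cluster)
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn)
    return p, r


def combined_fscore(
    clusters: list[set[str]], families: list[set[str]]
) -> float:
    """Size-weighted best-match F-score of a clustering vs reference families.

    ``F = sum_i (n_i / n) * max_j 2 P_ij R_ij / (P_ij + R_ij)``, with the
    harmonic term defined 0 when ``P_ij + R_ij = 0``.
    """
    families = [set(f) for f in families if f]
    clusters = [set(c) for c in clusters]
    n = sum(len(f) for f in families)
    if n == 0:
        raise ValueError("families must cover at least one sequence")
    total = 0.0
    for fam in families:
        best = 0.0
        for clu in clusters:
            p, r = precision_recall(clu, fam)
            if p + r > 0:
                best = max(best, 2 * p * r / (p + r))
        total += len(fam) / n * best
    return total


def pair_regions_to_labels(
    predicted: list[RegionAnnotation], reference: list[RegionAnnotation]
) -> dict[str, str]:
    """Assign each predicted region label its best-matching reference label.

    The analog of pairing discovered regions with reference database entries
    by the most significant hit: here the pairing maximizes total residue
    overlap across all sequences.  Regions with zero overlap stay unpaired.
    """
    overlap: dict[tuple[str, str], int] = defaultdict(int)
    ref_by_seq: dict[str, list[RegionAnnotation]] = defaultdict(list)
    for r in reference:
        ref_by_seq[r.seq_id].append(r)
    for p in predicted:
        for r in ref_by_seq.get(p.seq_id, []):
            ov = min(p.end, r.end) - max(p.start, r.start) + 1
            if ov > 0:
                overlap[(p.label, r.label)] += ov
    pairing: dict[str, str] = {}
    by_pred: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for (pl, rl), ov in overlap.items():
        by_pred[pl].append((ov, rl))
    for pl, cands in by_pred.items():
        cands.sort(key=lambda t: (-t[0], t[1]))
        pairing[pl] = cands[0][1]
    return pairing


def hit_metrics(
    predicted: set[tuple[str, str]], reference: set[tuple[str, str]]
) -> tuple[float, float]:
    """Hit-count sensitivity and precision of (sequence, label) associations.

    Precision is computed only over sequences carrying at least one
    reference hit.
    """
    tp = len(predicted & reference)
    fn = len(reference - predicted)
    ref_seqs = {s for s, _ in reference}
    fp = len({(s, l) for s, l in predicted - reference if s in ref_seqs})
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    return sens, prec


def residue_metrics(
    predicted: list[RegionAnnotation], reference: list[RegionAnnotation]
) -> tuple[float, float]:
    """Residue-level sensitivity/precision of predicted vs reference intervals.

    Per sequence and position: TP if covered by both, FN if reference-only,
    FP if predicted-only; counts aggregate over all sequences.
    """
    pred_pos: dict[str, set[int]] = defaultdict(set)
    ref_pos: dict[str, set[int]] = defaultdict(set)
    for a in predicted:
        pred_pos[a.seq_id] |= a.positions()
    for a in reference:
        ref_pos[a.seq_id] |= a.positions()
    tp = fn = fp = 0
    for sid in set(pred_pos) | set(ref_pos):
        p, r = pred_pos.get(sid, set()), ref_pos.get(sid, set())
        tp += len(p & r)
        fn += len(r - p)
        fp += len(p - r)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    return sens, prec


def roc_knee(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold at the knee of the ROC curve.

    Sweeps every observed score value as a candidate threshold (predict
    positive when score > t), and returns the threshold minimizing the
    Euclidean distance to the ideal corner (FPR=0, TPR=1); ties take the
    lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_t, best_d = None, np.inf
    for t in np.unique(scores):
        pred = scores > t
        tpr = (pred & labels).sum() / n_pos
        fpr = (pred & ~labels).sum() / n_neg
        d = float(np.hypot(fpr, 1.0 - tpr))
        if d < best_d - 1e-12:
            best_d, best_t = d, float(t)
    return best_t


@dataclass
class EvaluationReport:
    """Summary of clustering and region-recovery performance."""

    combined_f: float
    hit_sensitivity: float
    hit_precision: float
    residue_sensitivity: float
    residue_precision: float
    n_clusters: int
    n_families: int

    def to_dict(self) -> dict:
        return {
            "combined_f": self.combined_f,
            "hit_sensitivity": self.hit_sensitivity,
            "hit_precision": self.hit_precision,
            "residue_sensitivity": self.residue_sensitivity,
            "residue_precision": self.residue_precision,
            "n_clusters": self.n_clusters,
            "n_families": self.n_families,
        }

    def summary(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = [f"{k.ljust(width)}  {v:.4f}" if isinstance(v, float) else f"{k.ljust(width)}  {v}" for k, v in d.items()]
        return "\n".join(lines)


def evaluate(
    clusters: list[set[str]],
    families: list[set[str]],
    predicted: list[RegionAnnotation],
    reference: list[RegionAnnotation],
) -> EvaluationReport:
    """Full evaluation of a pipeline run against reference annotations."""
    f = combined_fscore(clusters, families)
    pairing = pair_regions_to_labels(predicted, reference)
    pred_hits = {
        (a.seq_id, pairing[a.label]) for a in predicted if a.label in pairing
    }
    ref_hits = {(a.seq_id, a.label) for a in reference}
    hs, hp = hit_metrics(pred_hits, ref_hits)
    rs, rp = residue_metrics(predicted, reference)
    return EvaluationReport(f, hs, hp, rs, rp, len(clusters), len(families))
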