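"""Conserved-region identification on clique alignments.

Each maximal clique is multiply aligned, every alignment column receives a
conservation score in [0, 1] (weighted sum-of-pairs over a normalized
substitution matrix, in the spirit of the valdar01 scorecons measure), the
score track is smoothed with a 1-D median filter, and maximal runs of
above-threshold positions at least ``min_len`` columns long become conserved
regions, from which per-column amino-acid+gap count profiles are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._kernels import profile_align
from .seqdata import (
    ALPHABET,
    AMINO_ACIDS,
    GAP_INDEX,
    X_INDEX,
    Alignment,
    Sequence,
    SubstitutionMatrix,
    read_alignment,  # re-exported: external alignments slot in for progressive_msa
)

N_SYMBOLS = 22  # 20 residues + X + gap


@dataclass
class RegionProfile:
    """Per-column residue+gap counts for one conserved region.

    ``span`` is the 0-based half-open column interval on the source
    alignment; ``member_spans`` maps each contributing sequence id to its
    1-based inclusive residue interval.
    """

    region_id: str
    clique_id: str
    span: tuple[int, int]
    counts: np.ndarray  # (span length, 22)
    member_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_rows(self) -> int:
        return int(self.counts[0].sum()) if self.n_columns else 0


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _identity_distance(a: str, b: str) -> float:
    """Guide-tree distance: normalized edit distance (1 - identity proxy)."""
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


def _profile_counts(rows: list[str]) -> np.ndarray:
    al = Alignment([str(i) for i in range(len(rows))], rows)
    enc = al.encoded()
    counts = np.zeros((al.n_columns, N_SYMBOLS), dtype=np.float64)
    for r in range(enc.shape[0]):
        counts[np.arange(al.n_columns), enc[r]] += 1.0
    return counts


def _apply_ops(rows: list[str], ops: np.ndarray, consume_code: int) -> list[str]:
    """Insert gap columns into ``rows`` according to a merge op path."""
    out = []
    for row in rows:
        buf = []
        pos = 0
        for op in ops:
            if op == 0 or op == consume_code:
                buf.append(row[pos])
                pos += 1
            else:
                buf.append("-")
        out.append("".join(buf))
    return out


def progressive_msa(
    seqs: list[Sequence],
    matrix: SubstitutionMatrix,
    gap_open: float = 10,
    gap_extend: float = 2,
) -> Alignment:
    """Progressive multiple alignment.

    A UPGMA guide tree is built from pairwise identity distances, then
    profiles are merged bottom-up with sum-of-pairs column scoring under
    affine gaps (free terminal gaps).  Deterministic for a fixed input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    n = len(seqs)
    sub = matrix.to_numpy()  # 21x21
    score_block = np.zeros((N_SYMBOLS, N_SYMBOLS))
    score_block[:21, :21] = sub  # gap rows/cols score 0

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _identity_distance(
                seqs[i].residues, seqs[j].residues
            )
    z = linkage(squareform(dist, checks=False), method="average")

    # cluster id -> (row indices into seqs, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        fa = _profile_counts(rows_a) / len(rows_a)
        fb = _profile_counts(rows_b) / len(rows_b)
        S = fa @ score_block @ fb.T
        _, ops = profile_align(S, float(gap_open), float(gap_extend))
        new_a = _apply_ops(rows_a, ops, consume_code=1)
        new_b = _apply_ops(rows_b, ops, consume_code=2)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)

    (indices, rows) = next(iter(clusters.values()))
    order = np.argsort(indices)
    return Alignment([ids[indices[k]] for k in order], [rows[k] for k in order])


# ---------------------------------------------------------------------------
# Conservation scoring


def sequence_weights(al: Alignment) -> np.ndarray:
    """Per-row weights proportional to mean pairwise distance, summing to 1.

    Distance between two rows is 1 minus their fractional identity over
    mutually non-gap columns; identical-row alignments fall back to uniform
    weights.
    """
    if al.n_rows < 2:
        raise ValueError("need at least 2 rows")
    enc = al.encoded()
    nongap = enc != GAP_INDEX
    n = al.n_rows
    dist = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap
        shared = both.sum(axis=1)
        matches = ((enc[i] == enc) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(shared > 0, matches / np.maximum(shared, 1), 0.0)
        dist[i] = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    mean_d = dist.sum(axis=1) / (n - 1)
    total = mean_d.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return mean_d / total


def normalized_mut(matrix: SubstitutionMatrix) -> np.ndarray:
    """The pair-score table used by conservation scoring, over 22 symbols.

    Residue-residue scores are mapped to [0, 1] so that every identical pair
    scores exactly 1 and dissimilar pairs score 0: raw scores are scaled
    Karlin-style by ``M(a,b)/sqrt(M(a,a)M(b,b))`` (diagonal -> 1) and
    negative values are clamped to 0.  A column of unrelated residues thus
    scores near 0 while conserved columns score near 1, which is what the
    downstream conservation threshold discriminates on.  Pairs involving a
    gap or an unknown residue score 0.
    """
    sub = matrix.to_numpy()[:20, :20]
    diag = np.diag(sub)
    if (diag <= 0).any():
        raise ValueError("substitution matrix diagonal must be positive")
    karlin = sub / np.sqrt(np.outer(diag, diag))
    norm = np.clip(karlin, 0.0, 1.0)
    table = np.zeros((N_SYMBOLS, N_SYMBOLS))
    table[:20, :20] = norm
    return table


def conservation_scores(
    al: Alignment, matrix: SubstitutionMatrix, weights: np.ndarray | None = None
) -> np.ndarray:
    """Per-column conservation scores in [0, 1].

    Column score is the weighted sum over row pairs of the normalized
    substitution score of their residues; gap (and unknown-residue) pairs
    contribute 0; an all-gap column scores 0.
    """
    if al.n_rows < 2:
        raise ValueError("need at least 2 rows")
    w = sequence_weights(al) if weights is None else np.asarray(weights, dtype=float)
    mut = normalized_mut(matrix)
    enc = al.encoded()
    n, ncol = enc.shape
    ww = np.outer(w, w)
    pair_mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    denom = ww[pair_mask].sum()
    scores = np.empty(ncol)
    for c in range(ncol):
        m = mut[np.ix_(enc[:, c], enc[:, c])]
        scores[c] = (ww * m)[pair_mask].sum() / denom
    return scores


# ---------------------------------------------------------------------------
# Median smoothing and region extraction


def median_filter(track: np.ndarray, frame: int = 50) -> np.ndarray:
    """1-D median smoothing with a ``frame + 1``-value window, zero padding.

    The window at position p holds the value at p plus ``frame/2`` neighbours
    per side (51 values at the default frame of 50); the output is the upper
    median, i.e. the (floor(w/2)+1)-th order statistic of the window.
    """
    if frame < 2:
        raise ValueError("frame must be >= 2")
    track = np.asarray(track, dtype=float)
    w = frame + 1
    left = frame // 2
    right = frame - left
    padded = np.concatenate([np.zeros(left), track, np.zeros(right)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    return np.partition(windows, w // 2, axis=1)[:, w // 2]


def extract_regions(
    track: np.ndarray, threshold: float = 0.2, min_len: int = 20
) -> list[tuple[int, int]]:
    """Maximal runs of positions scoring strictly above ``threshold``.

    Runs shorter than ``min_len`` are discarded; intervals are 0-based
    half-open, sorted and non-overlapping.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    above = np.asarray(track) > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(int)
    diffs = np.diff(padded)
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def build_profile(
    al: Alignment, span: tuple[int, int], clique_id: str, region_id: str = ""
) -> RegionProfile:
    """Count profile of alignment columns ``span`` (0-based half-open).

    Member residue spans map the span boundaries to each row's ungapped
    1-based coordinates; rows whose span maps to fewer than one residue are
    excluded from the associations.
    """
    start, end = span
    if not (0 <= start < end <= al.n_columns):
        raise ValueError(f"span {span} outside alignment of {al.n_columns} columns")
    enc = al.encoded()
    block = enc[:, start:end]
    ncol = end - start
    counts = np.zeros((ncol, N_SYMBOLS), dtype=np.float64)
    for r in range(al.n_rows):
        counts[np.arange(ncol), block[r]] += 1.0

    member_spans: dict[str, tuple[int, int]] = {}
    nongap = enc != GAP_INDEX
    for r, sid in enumerate(al.ids):
        inside = int(nongap[r, start:end].sum())
        if inside < 1:
            continue
        before = int(nongap[r, :start].sum())
        member_spans[sid] = (before + 1, before + inside)
    return RegionProfile(
        region_id=region_id or f"{clique_id}_r{start}",
        clique_id=clique_id,
        span=(start, end),
        counts=counts,
        member_spans=member_spans,
    )
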