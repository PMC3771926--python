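"""All-against-all Smith-Waterman local alignment and e-value statistics.

Local alignments use affine gap costs: a gap of length k costs
``gap_open + k * gap_extend``.  E-values follow the extreme-value law for
local alignment scores, ``E = K * m * N * exp(-lambda * S)`` with the Gumbel
parameters either taken from published gapped estimates or calibrated
empirically from shuffled decoys (maximum-likelihood fit).
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio import Align
from scipy import stats

from .seqdata import Sequence, SimilarityMap, SubstitutionMatrix

#: Published gapped Karlin-Altschul constants, keyed by (matrix, open, extend).
#: Used as fallbacks when no empirical calibration is available.
PUBLISHED_GUMBEL = {
    ("BLOSUM50", 10, 2): (0.232, 0.11),
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", 10, 2): (0.255, 0.035),
}


@dataclass(frozen=True)
class GumbelParams:
    """Extreme-value parameters for local alignment score statistics."""

    lam: float
    k: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Gumbel parameters must be positive")


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Best local alignment of a sequence pair.

    Spans are 1-based inclusive; ``None`` when the optimal score is 0
    (empty alignment).
    """

    score: float
    span_a: tuple[int, int] | None
    span_b: tuple[int, int] | None
    evalue: float | None = None


def make_aligner(
    matrix: SubstitutionMatrix, gap_open: float = 10, gap_extend: float = 2
) -> Align.PairwiseAligner:
    """A local PairwiseAligner charging ``open + k*extend`` for a gap of length k."""
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix.biopython
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix,
    gap_open: float = 10,
    gap_extend: float = 2,
) -> LocalAlignmentResult:
    """Optimal Smith-Waterman local alignment of two sequences."""
    if not a.residues or not b.residues:
        raise ValueError("sequences must be non-empty")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(a.residues, b.residues))
    if score <= 0:
        return LocalAlignmentResult(0.0, None, None)
    best = aligner.align(a.residues, b.residues)[0]
    (a0, a1) = best.aligned[0][0][0], best.aligned[0][-1][1]
    (b0, b1) = best.aligned[1][0][0], best.aligned[1][-1][1]
    return LocalAlignmentResult(score, (a0 + 1, a1), (b0 + 1, b1))


def estimate_evalue(
    score: float, len_a: int, db_residues: int, params: GumbelParams
) -> float:
    """``E = K * len_a * db_residues * exp(-lambda * score)``."""
    return params.k * len_a * db_residues * math.exp(-params.lam * score)


def fit_gumbel(scores: TSequence[float], m: int, n: int) -> GumbelParams:
    """Maximum-likelihood Gumbel fit of decoy scores -> (lambda, K).

    ``m`` and ``n`` are the decoy query/subject lengths used to express the
    location parameter as ``mu = ln(K*m*n)/lambda``.
    """
    loc, scale = stats.gumbel_r.fit(np.asarray(scores, dtype=float))
    lam = 1.0 / scale
    k = math.exp(loc / scale) / (m * n)
    return GumbelParams(lam, k)


def shuffled_decoys(
    seqs: list[Sequence], n_pairs: int, length: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Decoy pairs drawn from the residue composition of ``seqs``."""
    pool = "".join(s.residues for s in seqs)
    if not pool:
        raise ValueError("cannot build decoys from empty sequences")
    arr = np.frombuffer(pool.encode("ascii"), dtype=np.uint8)
    out = []
    for _ in range(n_pairs):
        q = arr[rng.integers(0, len(arr), size=length)].tobytes().decode("ascii")
        s = arr[rng.integers(0, len(arr), size=length)].tobytes().decode("ascii")
        out.append((q, s))
    return out


def calibrate(
    seqs: list[Sequence],
    matrix: SubstitutionMatrix,
    gap_open: float = 10,
    gap_extend: float = 2,
    n_pairs: int = 100,
    length: int = 200,
    rng: np.random.Generator | None = None,
) -> GumbelParams:
    """Estimate (lambda, K) by aligning shuffled decoys from the input composition."""
    rng = rng or np.random.default_rng(0)
    aligner = make_aligner(matrix, gap_open, gap_extend)
    scores = [
        float(aligner.score(q, s)) for q, s in shuffled_decoys(seqs, n_pairs, length, rng)
    ]
    return fit_gumbel(scores, length, length)


def default_params(
    matrix: SubstitutionMatrix, gap_open: float, gap_extend: float
) -> GumbelParams:
    """Published fallback Gumbel constants for a scoring combination."""
    key = (matrix.name, int(gap_open), int(gap_extend))
    if key not in PUBLISHED_GUMBEL:
        raise ValueError(
            f"no calibration for {key}; run calibrate() or supply GumbelParams"
        )
    lam, k = PUBLISHED_GUMBEL[key]
    return GumbelParams(lam, k)


def all_against_all(
    seqs: list[Sequence],
    matrix: SubstitutionMatrix,
    gap_open: float = 10,
    gap_extend: float = 2,
    params: GumbelParams | None = None,
    evalue_cap: float = 10.0,
    threads: int = 1,
) -> SimilarityMap:
    """All-against-all local alignment, thresholded at ``evalue_cap`` for storage.

    Results are independent of ``threads``.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if params is None:
        params = default_params(matrix, gap_open, gap_extend)
    db_residues = sum(len(s) for s in seqs)
    pairs = [(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))]

    def _score_chunk(chunk):
        aligner = make_aligner(matrix, gap_open, gap_extend)
        return [float(aligner.score(seqs[i].residues, seqs[j].residues)) for i, j in chunk]

    if threads > 1 and len(pairs) > 1:
        chunks = [pairs[k::threads] for k in range(threads)]
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_score_chunk, chunks))
        scores: dict[tuple[int, int], float] = {}
        for chunk, vals in zip(chunks, results):
            scores.update(zip(chunk, vals))
        ordered = [scores[p] for p in pairs]
    else:
        ordered = _score_chunk(pairs)

    sim = SimilarityMap()
    for (i, j), score in zip(pairs, ordered):
        ev = estimate_evalue(score, len(seqs[i]), db_residues, params)
        if ev <= evalue_cap:
            sim.add(seqs[i].id, seqs[j].id, ev)
    return sim


def threshold_connectivity(
    sim: SimilarityMap, seq_ids: Iterable[str], threshold: float = 0.01
):
    """Binary connectivity graph: an edge per pair with e-value <= threshold.

    Every id in ``seq_ids`` appears as a node even when isolated.
    """
    import networkx as nx

    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(seq_ids)
    for (a, b), ev in sim.items():
        if ev <= threshold and a in g and b in g:
            g.add_edge(a, b)
    return g
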