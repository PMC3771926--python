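"""Profile search, region merging and association-table assembly.

Conserved-region profiles are turned into log-odds PSSMs and locally aligned
against every input sequence (one pass, no profile re-estimation); hits at or
below the e-value threshold associate regions with sequences.  Redundant
regions — duplicates produced by redundant cliques or by random group
splitting — are detected by all-against-all local alignment of their
non-gapped consensus sequences and merged; the final product is the binary
sequence x region association table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import pssm_local_align
from .conservation import RegionProfile
from .pairwise import GumbelParams, estimate_evalue, fit_gumbel, make_aligner
from .seqdata import AMINO_ACIDS, X_INDEX, Sequence, SubstitutionMatrix


@dataclass(frozen=True)
class Hit:
    """One region-to-sequence association with its location (1-based incl)."""

    region_id: str
    seq_id: str
    evalue: float
    start: int
    end: int


@dataclass(frozen=True)
class PSSM:
    """Position-specific log-odds scores over consensus-retained columns."""

    region_id: str
    matrix: np.ndarray  # (n retained columns, 21); X column scores 0
    consensus: str


_ENC_LUT = np.full(128, X_INDEX, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _ENC_LUT[ord(_aa)] = _i


def encode_sequence(residues: str) -> np.ndarray:
    """Residue string -> int8 indices (0..19, X -> 20)."""
    return _ENC_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def background_frequencies(seqs: list[Sequence]) -> np.ndarray:
    """Amino-acid composition of a dataset (20-vector summing to 1).

    Unknown residues are ignored; every frequency is kept strictly positive
    with a one-count floor.
    """
    counts = np.ones(20, dtype=float)  # floor avoids zero background
    for s in seqs:
        enc = encode_sequence(s.residues)
        counts += np.bincount(enc[enc < 20], minlength=20)
    return counts / counts.sum()


def _retained_columns(profile: RegionProfile) -> np.ndarray:
    """Profile columns kept in the consensus: gap count < 50% of rows."""
    n_rows = profile.n_rows
    gap_counts = profile.counts[:, 21]
    return np.flatnonzero(gap_counts < 0.5 * n_rows)


def consensus(profile: RegionProfile) -> Sequence:
    """Non-gapped consensus: per retained column the most frequent residue.

    Ties break alphabetically; majority-gap columns are dropped entirely.
    Raises ``ValueError`` when every column is majority-gap.
    """
    cols = _retained_columns(profile)
    if cols.size == 0:
        raise ValueError(f"degenerate profile {profile.region_id}: all columns majority-gap")
    letters = []
    for c in cols:
        aa_counts = profile.counts[c, :20]
        if aa_counts.sum() > 0:
            letters.append(AMINO_ACIDS[int(np.argmax(aa_counts))])
        else:
            letters.append("X")
    return Sequence(profile.region_id or "consensus", "".join(letters))


def build_pssm(
    profile: RegionProfile,
    background: np.ndarray,
    pseudocount: float = 1.0,
) -> PSSM:
    """Log2-odds PSSM over consensus-retained columns.

    ``score(c, a) = log2((count(c,a) + pc*bg(a)) / ((N_c + pc) * bg(a)))``
    with ``N_c`` the non-gap standard-residue count in column c.  Unknown
    residues score 0.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or (background <= 0).any():
        raise ValueError("background must be a strictly positive 20-vector")
    if not math.isclose(background.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must sum to 1")
    cols = _retained_columns(profile)
    if cols.size == 0:
        raise ValueError(f"degenerate profile {profile.region_id}")
    counts = profile.counts[cols, :20]
    n_col = counts.sum(axis=1)
    scores = np.log2(
        (counts + pseudocount * background) / ((n_col + pseudocount)[:, None] * background)
    )
    matrix = np.zeros((cols.size, 21))
    matrix[:, :20] = scores
    cons = consensus(profile)
    return PSSM(profile.region_id, matrix, cons.residues)


def calibrate_pssm(
    pssm: PSSM,
    seqs: list[Sequence],
    gap_open: float,
    gap_extend: float,
    n_decoys: int = 60,
    rng: np.random.Generator | None = None,
) -> GumbelParams:
    """Gumbel (lambda, K) for a PSSM from residue-shuffled decoy scores."""
    rng = rng or np.random.default_rng(0)
    idx = rng.integers(0, len(seqs), size=n_decoys)
    scores = []
    lengths = []
    for i in idx:
        enc = encode_sequence(seqs[int(i)].residues).copy()
        rng.shuffle(enc)
        s, *_ = pssm_local_align(pssm.matrix, enc, float(gap_open), float(gap_extend))
        scores.append(s)
        lengths.append(len(enc))
    mean_len = max(1, int(np.mean(lengths)))
    return fit_gumbel(scores, pssm.matrix.shape[0], mean_len)


def pssm_search(
    pssm: PSSM,
    seqs: list[Sequence],
    params: GumbelParams,
    evalue_threshold: float = 1e-5,
    gap_open: float = 10,
    gap_extend: float = 2,
) -> list[Hit]:
    """One-pass local search of a PSSM against every sequence.

    The single best local alignment per sequence is reported when its
    e-value is at or below the threshold.
    """
    db_residues = sum(len(s) for s in seqs)
    qlen = pssm.matrix.shape[0]
    hits: list[Hit] = []
    for seq in seqs:
        enc = encode_sequence(seq.residues)
        score, _, _, s_start, s_end = pssm_local_align(
            pssm.matrix, enc, float(gap_open), float(gap_extend)
        )
        if score <= 0:
            continue
        ev = estimate_evalue(score, qlen, db_residues, params)
        if ev <= evalue_threshold:
            hits.append(Hit(pssm.region_id, seq.id, ev, s_start + 1, s_end + 1))
    return hits


# ---------------------------------------------------------------------------
# Region merging


def _aligned_pairs(aligner, a: str, b: str):
    """Best local alignment of two strings -> (score, list of (i, j) pairs)."""
    score = float(aligner.score(a, b))
    if score <= 0:
        return 0.0, []
    best = aligner.align(a, b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return score, pairs


def merge_regions(
    profiles: list[RegionProfile],
    matrix: SubstitutionMatrix,
    params: GumbelParams,
    gap_open: float = 10,
    gap_extend: float = 2,
    align_threshold: float = 0.01,
    overlap_fraction: float = 0.9,
) -> tuple[list[RegionProfile], dict[str, str]]:
    """Iteratively merge regions representing the same family.

    Consensus sequences are locally aligned all-against-all; a significantly
    aligned pair (e-value < ``align_threshold``) merges when the aligned
    columns cover the shorter consensus entirely (containment) or more than
    ``overlap_fraction`` of it.  Pairs are processed in ascending e-value
    order and merging repeats until no pair qualifies.

    Returns the merged profiles and a mapping from every input region id to
    its final region id (identity for unmerged regions).
    """
    aligner = make_aligner(matrix, gap_open, gap_extend)
    current = list(profiles)
    id_map = {p.region_id: p.region_id for p in profiles}
    counter = 0

    while True:
        consensi: dict[str, str] = {}
        for p in current:
            try:
                consensi[p.region_id] = consensus(p).residues
            except ValueError:
                continue  # degenerate profiles never merge
        candidates = []
        items = sorted(consensi.items())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ra, ca = items[i]
                rb, cb = items[j]
                score, pairs = _aligned_pairs(aligner, ca, cb)
                if not pairs:
                    continue
                short_len = min(len(ca), len(cb))
                ev = estimate_evalue(score, short_len, max(len(ca), len(cb)), params)
                if ev >= align_threshold:
                    continue
                # coverage of the shorter consensus by the aligned span
                if len(ca) <= len(cb):
                    lo, hi = pairs[0][0], pairs[-1][0]
                else:
                    lo, hi = pairs[0][1], pairs[-1][1]
                covered = (hi - lo + 1) / short_len
                contained = lo == 0 and hi == short_len - 1
                if contained or covered > overlap_fraction:
                    candidates.append((ev, ra, rb))
        if not candidates:
            break
        candidates.sort()
        _, ra, rb = candidates[0]
        pa = next(p for p in current if p.region_id == ra)
        pb = next(p for p in current if p.region_id == rb)
        merged = _merge_pair(pa, pb, aligner, counter)
        counter += 1
        current = [p for p in current if p.region_id not in (ra, rb)] + [merged]
        for old, new in list(id_map.items()):
            if new in (ra, rb):
                id_map[old] = merged.region_id
        id_map[merged.region_id] = merged.region_id

    current.sort(key=lambda p: p.region_id)
    return current, {k: v for k, v in id_map.items() if k in {p.region_id for p in profiles}}


def _merge_pair(pa: RegionProfile, pb: RegionProfile, aligner, counter: int) -> RegionProfile:
    """Sum the aligned per-column counts of two profiles.

    The profile with the longer consensus is the base; the other's counts are
    added over aligned columns, its unaligned flanks dropped, and the base's
    unaligned flanks carried through unchanged.
    """
    ca, cb = consensus(pa).residues, consensus(pb).residues
    if (len(ca), pb.region_id) > (len(cb), pa.region_id):
        base, other, cons_base, cons_other = pa, pb, ca, cb
    else:
        base, other, cons_base, cons_other = pb, pa, cb, ca
    _, pairs = _aligned_pairs(aligner, cons_base, cons_other)
    cols_base = _retained_columns(base)
    cols_other = _retained_columns(other)
    counts = base.counts.copy()
    for i, j in pairs:
        counts[cols_base[i]] += other.counts[cols_other[j]]
    member_spans = dict(other.member_spans)
    member_spans.update(base.member_spans)
    return RegionProfile(
        region_id=f"m{counter:04d}",
        clique_id=f"{base.clique_id}+{other.clique_id}",
        span=base.span,
        counts=counts,
        member_spans=member_spans,
    )


# ---------------------------------------------------------------------------
# Association table and final clustering


def association_table(
    hits: list[Hit], seq_ids: list[str], region_ids: list[str]
) -> pd.DataFrame:
    """Binary sequences x regions table: 1 iff >= 1 hit links the pair."""
    table = pd.DataFrame(
        np.zeros((len(seq_ids), len(region_ids)), dtype=np.int8),
        index=list(seq_ids),
        columns=list(region_ids),
    )
    for h in hits:
        if h.seq_id in table.index and h.region_id in table.columns:
            table.loc[h.seq_id, h.region_id] = 1
    return table


def cluster_from_associations(table: pd.DataFrame) -> list[list[str]]:
    """Connected components of the sequence-region bipartite projection.

    Two sequences are linked iff they share at least one region; all-zero
    rows become singletons.  Clusters are sorted (size desc, then members).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(table.index)
    for col in table.columns:
        members = list(table.index[table[col] == 1])
        for other in members[1:]:
            g.add_edge(members[0], other)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    return sorted(clusters, key=lambda c: (-len(c), c))
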