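import numpy as np
import pandas as pd
import pytest

from conregid import conservation as cons
from conregid import pairwise as pw
from conregid import search_merge as sm
from conregid import synthetic as syn
from conregid.seqdata import AMINO_ACIDS, Alignment, Sequence

from conftest import random_protein


def profile_from_rows(rows, clique_id="c0", region_id="r0"):
    al = Alignment([f"s{i}" for i in range(len(rows))], rows)
    return cons.build_profile(al, (0, al.n_columns), clique_id, region_id)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_identical_rows():
    prof = profile_from_rows(["MKTAYIAKQR"] * 4)
    assert sm.consensus(prof).residues == "MKTAYIAKQR"


def test_consensus_tie_breaks_alphabetically():
    prof = profile_from_rows(["AKT", "AKT", "VKT", "VKT"])
    assert sm.consensus(prof).residues[0] == "A"


def test_consensus_drops_majority_gap_columns():
    rows = ["MK---TAYIA", "MK---TAYIA", "MKWWWTAYIA", "MK---TAYIA"]
    prof = profile_from_rows(rows)
    # 3 of 10 columns have 3/4 gaps -> dropped
    assert sm.consensus(prof).residues == "MKTAYIA"
    all_gap = profile_from_rows(["---", "---"])
    with pytest.raises(ValueError, match="degenerate"):
        sm.consensus(all_gap)


# ---------------------------------------------------------------------------
# PSSM construction


def test_pssm_sign_pattern():
    prof = profile_from_rows(["W" * 5] * 6)
    bg = syn.BACKGROUND
    pssm = sm.build_pssm(prof, bg)
    w_idx = AMINO_ACIDS.index("W")
    a_idx = AMINO_ACIDS.index("A")
    assert (pssm.matrix[:, w_idx] > 0).all()
    assert (pssm.matrix[:, a_idx] < 0).all()


def test_pssm_background_counts_score_near_zero():
    bg = np.full(20, 0.05)
    counts = np.zeros((4, 22))
    counts[:, :20] = 50.0  # 1000 rows, uniform counts = background proportion
    prof = cons.RegionProfile("r", "c", (0, 4), counts, {})
    pssm = sm.build_pssm(prof, bg)
    assert np.abs(pssm.matrix[:, :20]).max() < 0.01


def test_pssm_matches_direct_formula():
    rows = ["AAAG", "AAAG", "AAGG", "GAAG"]
    prof = profile_from_rows(rows)
    bg = np.full(20, 0.05)
    pssm = sm.build_pssm(prof, bg, pseudocount=1.0)
    # column 0: counts A=3, G=1, N=4
    expect_a = np.log2((3 + 0.05) / (5 * 0.05))
    expect_g = np.log2((1 + 0.05) / (5 * 0.05))
    expect_w = np.log2(0.05 / (5 * 0.05))
    assert pssm.matrix[0, AMINO_ACIDS.index("A")] == pytest.approx(expect_a)
    assert pssm.matrix[0, AMINO_ACIDS.index("G")] == pytest.approx(expect_g)
    assert pssm.matrix[0, AMINO_ACIDS.index("W")] == pytest.approx(expect_w)


# ---------------------------------------------------------------------------
# PSSM search


@pytest.fixture(scope="module")
def family_profile_and_seqs():
    rng = np.random.default_rng(77)
    model = syn.make_domain(80, rng, "D")
    seqs = []
    spans = {}
    for i in range(8):
        left = syn._draw(rng, int(rng.integers(40, 100)), syn.BACKGROUND)
        right = syn._draw(rng, int(rng.integers(40, 100)), syn.BACKGROUND)
        seg, _ = syn.emit_member(model, 0.08, 0.0, rng)
        seqs.append(Sequence(f"s{i}", left + seg + right))
        spans[f"s{i}"] = (len(left) + 1, len(left) + len(seg))
    from conregid.seqdata import load_matrix

    al = cons.progressive_msa(seqs, load_matrix("BLOSUM62"))
    track = cons.median_filter(
        cons.conservation_scores(al, load_matrix("BLOSUM62")), 50
    )
    region = cons.extract_regions(track, 0.2, 20)[0]
    prof = cons.build_profile(al, region, "c0", "c0_r0")
    return prof, seqs, spans


def test_pssm_self_recovery(family_profile_and_seqs):
    prof, seqs, _ = family_profile_and_seqs
    pssm = sm.build_pssm(prof, sm.background_frequencies(seqs))
    params = sm.calibrate_pssm(pssm, seqs, 10, 2, rng=np.random.default_rng(5))
    hits = {h.seq_id: h for h in sm.pssm_search(pssm, seqs, params)}
    for sid, (ms, me) in prof.member_spans.items():
        assert sid in hits
        h = hits[sid]
        seq_len = len(next(s for s in seqs if s.id == sid))
        assert 1 <= h.start <= h.end <= seq_len
        overlap = max(0, min(h.end, me) - max(h.start, ms) + 1)
        assert overlap / (me - ms + 1) >= 0.9


def test_pssm_search_rejects_shuffled_decoys(family_profile_and_seqs):
    prof, seqs, _ = family_profile_and_seqs
    pssm = sm.build_pssm(prof, sm.background_frequencies(seqs))
    params = sm.calibrate_pssm(pssm, seqs, 10, 2, rng=np.random.default_rng(6))
    rng = np.random.default_rng(8)
    decoys = []
    for i in range(100):
        residues = list(seqs[i % len(seqs)].residues)
        rng.shuffle(residues)
        decoys.append(Sequence(f"d{i}", "".join(residues)))
    hits = sm.pssm_search(pssm, decoys, params, 1e-5)
    assert len(hits) <= 5  # >= 95% of decoys rejected


def test_pssm_hit_count_monotone_in_threshold(family_profile_and_seqs):
    prof, seqs, _ = family_profile_and_seqs
    pssm = sm.build_pssm(prof, sm.background_frequencies(seqs))
    params = sm.calibrate_pssm(pssm, seqs, 10, 2, rng=np.random.default_rng(7))
    counts = [
        len(sm.pssm_search(pssm, seqs, params, thr)) for thr in (1e-10, 1e-5, 1e-2)
    ]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# merging


def _simple_profile(segment, members, region_id, n_rows=4):
    rows = [segment] * n_rows
    prof = profile_from_rows(rows, region_id=region_id)
    prof.member_spans = {m: (1, len(segment)) for m in members}
    return prof


@pytest.fixture(scope="module")
def merge_env():
    from conregid.seqdata import load_matrix

    return load_matrix("BLOSUM50"), pw.GumbelParams(0.232, 0.11)


def test_merge_duplicates(merge_env, rng):
    matrix, params = merge_env
    seg = random_protein(rng, 60)
    pa = _simple_profile(seg, ["s1", "s2"], "ra")
    pb = _simple_profile(seg, ["s2", "s3"], "rb")
    merged, id_map = sm.merge_regions([pa, pb], matrix, params)
    assert len(merged) == 1
    assert set(merged[0].member_spans) == {"s1", "s2", "s3"}
    assert id_map["ra"] == id_map["rb"] == merged[0].region_id


def test_merge_containment_unions_associations(merge_env, rng):
    matrix, params = merge_env
    long_seg = random_protein(rng, 100)
    short_seg = long_seg[20:80]  # contained in the longer region
    px = _simple_profile(long_seg, ["s1", "s2", "s3", "s4", "s5"], "rx")
    py = _simple_profile(short_seg, ["s4", "s5", "s6", "s7"], "ry")
    merged, id_map = sm.merge_regions([px, py], matrix, params)
    assert len(merged) == 1
    assert set(merged[0].member_spans) == {f"s{i}" for i in range(1, 8)}
    # counts over the aligned block doubled, flanks carried through
    assert merged[0].counts.shape[0] == 100
    assert merged[0].counts[:20].sum(axis=1).max() == 4
    assert merged[0].counts[20:80].sum(axis=1).min() == 8


def test_slight_overlap_not_merged(merge_env, rng):
    matrix, params = merge_env
    a = random_protein(rng, 60)
    b = a[36:] + random_protein(rng, 36)  # 40% of the shorter overlaps
    pa = _simple_profile(a, ["s1"], "ra")
    pb = _simple_profile(b, ["s2"], "rb")
    merged, id_map = sm.merge_regions([pa, pb], matrix, params)
    assert len(merged) == 2
    assert id_map == {"ra": "ra", "rb": "rb"}


def test_merge_is_fixpoint(merge_env, rng):
    matrix, params = merge_env
    seg = random_protein(rng, 70)
    profiles = [
        _simple_profile(seg, [f"s{i}"], f"r{i}") for i in range(3)
    ] + [_simple_profile(random_protein(rng, 70), ["t1"], "r_other")]
    merged, _ = sm.merge_regions(profiles, matrix, params)
    again, id_map = sm.merge_regions(merged, matrix, params)
    assert [p.region_id for p in again] == [p.region_id for p in merged]
    assert all(k == v for k, v in id_map.items())
    # association sets never shrink
    before = {m for p in profiles for m in p.member_spans}
    after = {m for p in merged for m in p.member_spans}
    assert before == after


# ---------------------------------------------------------------------------
# association table and clustering


def test_association_table_basics():
    hits = [
        sm.Hit("r1", "sqx", 1e-9, 1, 50),
        sm.Hit("r2", "sqx", 1e-8, 60, 110),
        sm.Hit("r3", "sqx", 1e-7, 120, 170),
        sm.Hit("r1", "sqx", 1e-6, 1, 40),  # duplicate collapses
        sm.Hit("r1", "a", 1e-9, 1, 50),
    ]
    table = sm.association_table(hits, ["a", "b", "sqx"], ["r1", "r2", "r3"])
    assert table.loc["sqx"].tolist() == [1, 1, 1]
    assert table.loc["a"].tolist() == [1, 0, 0]
    assert table.loc["b"].tolist() == [0, 0, 0]
    assert set(np.unique(table.values)) <= {0, 1}


def test_association_table_empty():
    table = sm.association_table([], ["a", "b"], ["r1"])
    assert (table.values == 0).all()


def test_cluster_from_associations_blocks_and_chaining():
    idx = [f"s{i}" for i in range(6)]
    block = pd.DataFrame(
        [[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], index=idx, columns=["r1", "r2"]
    )
    assert sm.cluster_from_associations(block) == [
        ["s0", "s1", "s2"], ["s3", "s4", "s5"]
    ]
    # one sequence sharing regions with both groups chains them
    chained = block.copy()
    chained.loc["s2", "r2"] = 1
    assert sm.cluster_from_associations(chained) == [sorted(idx)]
    zeros = pd.DataFrame(np.zeros((3, 1), dtype=int), index=["a", "b", "c"], columns=["r"])
    assert sm.cluster_from_associations(zeros) == [["a"], ["b"], ["c"]]
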