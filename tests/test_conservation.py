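import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conregid import conservation as cons
from conregid import synthetic as syn
from conregid.seqdata import Alignment, Sequence

from conftest import random_protein


# ---------------------------------------------------------------------------
# progressive MSA


def nw_free_end_score_oracle(a: str, b: str, matrix, go: float, ge: float) -> float:
    """Quadratic free-end-gap global alignment score oracle."""
    la, lb = len(a), len(b)
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0
    Y[0, 1:] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + matrix.score(
                a[i - 1], b[j - 1]
            )
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge)
    edge = [M[la, j] for j in range(lb + 1)] + [X[la, j] for j in range(lb + 1)]
    edge += [Y[la, j] for j in range(lb + 1)]
    edge += [M[i, lb] for i in range(la + 1)] + [X[i, lb] for i in range(la + 1)]
    edge += [Y[i, lb] for i in range(la + 1)]
    return max(edge)


def score_pair_alignment(al: Alignment, matrix, go: float, ge: float) -> float:
    """Score a produced 2-row alignment under the merge objective
    (substitution scores on residue columns, affine interior gaps, free ends)."""
    r1, r2 = al.rows
    cols = [(x, y) for x, y in zip(r1, r2)]
    first = next(i for i, (x, y) in enumerate(cols) if x != "-" and y != "-")
    last = len(cols) - 1 - next(
        i for i, (x, y) in enumerate(reversed(cols)) if x != "-" and y != "-"
    )
    total, gap_state = 0.0, None
    for x, y in cols[first : last + 1]:
        if x != "-" and y != "-":
            total += matrix.score(x, y)
            gap_state = None
        else:
            state = "x" if y == "-" else "y"
            total -= ge if gap_state == state else go + ge
            gap_state = state
    return total


def test_msa_identical_sequences_gap_free(b62):
    seqs = [Sequence(f"s{i}", "MKTAYIAKQRQISFVKSHFSRQ") for i in range(4)]
    al = cons.progressive_msa(seqs, b62)
    assert al.n_columns == len(seqs[0])
    assert all("-" not in row for row in al.rows)
    track = cons.conservation_scores(al, b62)
    assert np.allclose(track, 1.0)


@pytest.mark.parametrize("trial", range(5))
def test_msa_pairwise_matches_global_dp_oracle(b62, trial):
    rng = np.random.default_rng(300 + trial)
    a = Sequence("a", random_protein(rng, 40))
    b = Sequence("b", random_protein(rng, 45))
    al = cons.progressive_msa([a, b], b62)
    produced = score_pair_alignment(al, b62, 10, 2)
    assert produced == pytest.approx(nw_free_end_score_oracle(a.residues, b.residues, b62, 10, 2))


def test_msa_degap_recovers_inputs(b62, rng):
    seqs = [Sequence(f"s{i}", random_protein(rng, 50 + 5 * i)) for i in range(5)]
    al = cons.progressive_msa(seqs, b62)
    recovered = {s.id: s.residues for s in al.degapped()}
    assert recovered == {s.id: s.residues for s in seqs}
    with pytest.raises(ValueError):
        cons.progressive_msa(seqs[:1], b62)


# ---------------------------------------------------------------------------
# sequence weights and conservation scores


def test_weights_identical_rows_uniform():
    al = Alignment(["a", "b", "c"], ["MKTA"] * 3)
    assert np.allclose(cons.sequence_weights(al), 1 / 3)


def test_weights_two_rows_symmetric():
    al = Alignment(["a", "b"], ["MKTA", "MQTA"])
    assert np.allclose(cons.sequence_weights(al), 0.5)


def test_weights_diverged_row_weighs_most():
    rows = ["MKTAYIAKQR", "MKTAYIAKQR", "WWPCGHNDEF"]
    al = Alignment(["a", "b", "c"], rows)
    w = cons.sequence_weights(al)
    # hand computation: d(a,b)=0, d(a,c)=d(b,c)=1 -> mean dists (0.5, 0.5, 1)
    assert np.allclose(w, [0.25, 0.25, 0.5])
    assert w[2] == max(w)


def conservation_oracle(al: Alignment, matrix, weights) -> np.ndarray:
    """Direct double-sum implementation, independent of vectorization."""
    mut = cons.normalized_mut(matrix)
    enc = al.encoded()
    n, ncol = enc.shape
    denom = sum(
        weights[i] * weights[j] for i in range(n) for j in range(i + 1, n)
    )
    out = np.zeros(ncol)
    for c in range(ncol):
        s = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                s += weights[i] * weights[j] * mut[enc[i, c], enc[j, c]]
        out[c] = s / denom
    return out


def test_conservation_extreme_columns(b62):
    al = Alignment(["a", "b", "c"], ["W-A", "W-V", "W-A"])
    track = cons.conservation_scores(al, b62)
    assert track[0] == pytest.approx(1.0)  # identical column
    assert track[1] == 0.0  # all-gap column
    assert 0 < track[2] < 1


def test_conservation_matches_double_sum_oracle(b62, rng):
    rows = ["".join(rng.choice(list("ACDEF-"), size=12)) for _ in range(5)]
    al = Alignment([f"s{i}" for i in range(5)], rows)
    w = cons.sequence_weights(al)
    assert np.allclose(
        cons.conservation_scores(al, b62), conservation_oracle(al, b62, w)
    )


def test_conservation_invariant_under_row_permutation(b62, rng):
    rows = ["MKTAYIAKQR", "MKTAYIGKQR", "MQTAYIAKQR", "MKTAWIAKQR"]
    al = Alignment(list("abcd"), rows)
    perm = Alignment(list("dcba"), rows[::-1])
    assert np.allclose(
        cons.conservation_scores(al, b62), cons.conservation_scores(perm, b62)
    )


# ---------------------------------------------------------------------------
# median filter


def median_filter_oracle(track, frame):
    """Sort each zero-padded window and take the upper median."""
    w = frame + 1
    left = frame // 2
    out = np.empty(len(track))
    padded = [0.0] * left + list(track) + [0.0] * (frame - left)
    for p in range(len(track)):
        window = sorted(padded[p : p + w])
        out[p] = window[w // 2]
    return out


def test_median_filter_constant_tracks():
    ones = np.ones(200)
    assert np.allclose(cons.median_filter(ones, 50), 1.0)
    zeros = np.zeros(120)
    assert np.allclose(cons.median_filter(zeros, 50), 0.0)
    # idempotent on constants
    assert np.allclose(cons.median_filter(cons.median_filter(ones, 50), 50), 1.0)


@pytest.mark.parametrize("frame", [4, 10, 50])
def test_median_filter_matches_sorting_oracle(frame, rng):
    track = rng.random(137)
    assert np.allclose(
        cons.median_filter(track, frame), median_filter_oracle(track, frame)
    )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=5, max_size=60), st.integers(2, 20))
def test_median_filter_output_from_window_multiset(values, frame):
    track = np.asarray(values)
    out = cons.median_filter(track, frame)
    left = frame // 2
    for p, v in enumerate(out):
        window = list(track[max(0, p - left) : p + (frame - left) + 1]) + [0.0]
        assert any(np.isclose(v, x) for x in window)


def test_median_filter_monotone(rng):
    track = rng.random(90)
    raised = np.minimum(track + 0.2, 1.0)
    assert (cons.median_filter(raised, 10) >= cons.median_filter(track, 10) - 1e-12).all()


# ---------------------------------------------------------------------------
# region extraction


def planted_track(run_len, n=500):
    track = np.zeros(n)
    start = (n - run_len) // 2
    track[start : start + run_len] = 1.0
    return track, start


def test_short_run_removed_entirely():
    track, _ = planted_track(24)
    smooth = cons.median_filter(track, 50)
    assert not (smooth > 0.2).any()
    assert cons.extract_regions(smooth) == []


def test_planted_run_of_30_survives_intact():
    track, start = planted_track(30)
    smooth = cons.median_filter(track, 50)
    assert cons.extract_regions(smooth) == [(start, start + 30)]


def test_run_below_min_length_discarded():
    track = np.zeros(100)
    track[10:29] = 0.9  # 19 above-threshold positions, no smoothing applied
    assert cons.extract_regions(track, 0.2, 20) == []
    track[10:40] = 0.9
    assert cons.extract_regions(track, 0.2, 20) == [(10, 40)]


def test_threshold_is_strict():
    track = np.full(50, 0.2)
    assert cons.extract_regions(track, 0.2, 20) == []


def test_ideal_boundaries_within_three_columns():
    for run in (26, 40, 60, 120):
        track, start = planted_track(run)
        smooth = cons.median_filter(track, 50)
        regions = cons.extract_regions(smooth, 0.2, 20)
        assert len(regions) == 1
        s, e = regions[0]
        assert abs(s - start) <= 3 and abs(e - (start + run)) <= 3


# ---------------------------------------------------------------------------
# profiles and the planted-domain shape test


def test_build_profile_identical_rows(b62):
    al = Alignment([f"s{i}" for i in range(4)], ["MKTAYIAKQRQISFVKSHFSRQLEERLGL"] * 4)
    prof = cons.build_profile(al, (0, 25), "c0")
    assert prof.counts.shape == (25, 22)
    assert (prof.counts.sum(axis=1) == 4).all()
    assert (prof.counts.max(axis=1) == 4).all()
    assert prof.member_spans == {f"s{i}": (1, 25) for i in range(4)}


def test_build_profile_gap_rows_shorten_member_spans():
    al = Alignment(["a", "b"], ["MKTAYIAKQW", "MKT--IAKQW"])
    prof = cons.build_profile(al, (2, 8), "c0")
    assert prof.member_spans["a"] == (3, 8)
    assert prof.member_spans["b"] == (3, 6)  # two gap columns inside the span


def test_planted_domain_recovered_with_high_jaccard(b62):
    """Ten sequences sharing one 60-residue domain (10% point mutations) in
    random flanks yield exactly one region overlapping the planted domain
    with Jaccard >= 0.8 for every member."""
    rng = np.random.default_rng(42)
    model = syn.make_domain(60, rng, "D")
    seqs, truth = [], {}
    for i in range(10):
        left = syn._draw(rng, int(rng.integers(40, 120)), syn.BACKGROUND)
        right = syn._draw(rng, int(rng.integers(40, 120)), syn.BACKGROUND)
        segment, _ = syn.emit_member(model, 0.10, 0.0, rng)
        seqs.append(Sequence(f"s{i}", left + segment + right))
        truth[f"s{i}"] = (len(left) + 1, len(left) + len(segment))
    al = cons.progressive_msa(seqs, b62)
    smooth = cons.median_filter(cons.conservation_scores(al, b62), 50)
    regions = cons.extract_regions(smooth, 0.2, 20)
    assert len(regions) == 1
    prof = cons.build_profile(al, regions[0], "c0")
    for sid, (ts, te) in truth.items():
        ps, pe = prof.member_spans[sid]
        inter = max(0, min(pe, te) - max(ps, ts) + 1)
        union = (te - ts + 1) + (pe - ps + 1) - inter
        assert inter / union >= 0.8, sid
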