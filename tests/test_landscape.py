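import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pipesites.io_formats import InteractionDB, Protein
from pipesites.landscape import (
    MatchParams,
    compute_landscape,
    match_profile,
    window_match,
    windows,
)

from conftest import brute_force_landscape, random_proteome

EXACT2 = MatchParams(w=2)


class TestWindows:
    @pytest.mark.parametrize(
        "seq,w,expected",
        [
            ("MKLV", 2, [(1, "MK"), (2, "KL"), (3, "LV")]),
            ("MKLV", 4, [(1, "MKLV")]),
            ("MK", 3, []),
        ],
    )
    def test_enumeration(self, seq, w, expected):
        assert windows(Protein("P", seq), w) == expected


class TestWindowMatch:
    def test_substring_hit(self):
        assert window_match("KL", Protein("X", "QMKL"), EXACT2)

    def test_substring_miss(self):
        assert not window_match("LV", Protein("X", "QMKL"), EXACT2)

    def test_similarity_self_match_at_self_score(self):
        # threshold equal to the window's self-score: the window matches itself
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        self_score = blosum["M", "M"] + blosum["K", "K"]
        params = MatchParams(w=2, mode="similarity", score_threshold=self_score)
        assert window_match("MK", Protein("X", "MK"), params)
        assert not window_match("MK", Protein("X", "WW"), params)

    def test_x_never_matches_in_similarity_mode(self):
        params = MatchParams(w=2, mode="similarity", score_threshold=-100.0)
        assert not window_match("XK", Protein("X1", "XKXK"), params)

    def test_x_matches_itself_in_exact_mode(self):
        assert window_match("XK", Protein("X1", "AXKA"), EXACT2)

    def test_similarity_requires_threshold(self):
        with pytest.raises(ValueError):
            MatchParams(w=2, mode="similarity")


class TestMatchProfile:
    def test_two_hits(self, toy_proteome):
        assert match_profile(toy_proteome["A"], toy_proteome["X"], EXACT2) == {1, 2}

    def test_no_hits(self, toy_proteome):
        assert match_profile(toy_proteome["A"], Protein("W", "WWWW"), EXACT2) == frozenset()

    def test_self_profile_full(self, toy_proteome):
        a = toy_proteome["A"]
        assert match_profile(a, a, EXACT2) == {1, 2, 3}


class TestComputeLandscape:
    def test_worked_example(self, toy_proteome, toy_db):
        ls = compute_landscape(
            toy_proteome["A"], toy_proteome["B"], toy_db, EXACT2,
            exclude_query_pair=False,
        )
        assert ls.H.tolist() == [[1, 1, 0], [1, 1, 0], [0, 0, 0]]

    def test_empty_db_gives_zero_matrix(self, toy_proteome):
        db = InteractionDB(proteome=toy_proteome)
        ls = compute_landscape(toy_proteome["A"], toy_proteome["B"], db, EXACT2)
        assert ls.H.shape == (3, 3) and not ls.H.any()

    def test_self_interaction_everywhere_positive(self):
        p = Protein("S", "MKLVAG")
        db = InteractionDB(proteome={"S": p}, pairs={("S", "S")})
        ls = compute_landscape(p, p, db, MatchParams(w=2), exclude_query_pair=False)
        assert (ls.H >= 1).all()

    def test_short_query_yields_empty_landscape(self, toy_proteome, toy_db):
        short = Protein("SH", "M")
        ls = compute_landscape(short, toy_proteome["B"], toy_db, EXACT2)
        assert ls.is_empty and ls.H.shape[0] == 0

    def test_exclude_query_pair_removes_self_hit(self, toy_proteome):
        db = InteractionDB(proteome=toy_proteome, pairs={("A", "B")})
        with_hit = compute_landscape(
            toy_proteome["A"], toy_proteome["B"], db, EXACT2, exclude_query_pair=False
        )
        without = compute_landscape(
            toy_proteome["A"], toy_proteome["B"], db, EXACT2, exclude_query_pair=True
        )
        assert with_hit.H.max() > 0 and not without.H.any()

    def test_orientation_bound(self, toy_proteome, toy_db):
        ls = compute_landscape(
            toy_proteome["A"], toy_proteome["B"], toy_db, EXACT2,
            exclude_query_pair=False,
        )
        assert ls.H.max() <= 2 * len(toy_db)


def _random_instance(seed: int):
    rng = np.random.default_rng(seed)
    proteome = random_proteome(rng, int(rng.integers(2, 9)))
    ids = list(proteome)
    n_pairs = int(rng.integers(1, 8))
    pairs = {
        tuple(sorted(rng.choice(ids, size=2, replace=True)))
        for _ in range(n_pairs)
    }
    db = InteractionDB(proteome=proteome, pairs=pairs)
    a, b = proteome[ids[0]], proteome[ids[1]]
    w = int(rng.integers(1, 5))
    return a, b, db, w


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        a, b, db, w = _random_instance(seed)
        params = MatchParams(w=w)
        ls = compute_landscape(a, b, db, params, exclude_query_pair=False)
        expected = brute_force_landscape(a, b, db, w)
        np.testing.assert_array_equal(ls.H, expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry(self, seed):
        a, b, db, w = _random_instance(seed)
        params = MatchParams(w=w)
        ab = compute_landscape(a, b, db, params, exclude_query_pair=False)
        ba = compute_landscape(b, a, db, params, exclude_query_pair=False)
        np.testing.assert_array_equal(ab.H, ba.H.T)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_db(self, seed):
        a, b, db, w = _random_instance(seed)
        params = MatchParams(w=w)
        base = compute_landscape(a, b, db, params, exclude_query_pair=False).H
        ids = sorted(db.proteome)
        grown = InteractionDB(
            proteome=db.proteome, pairs=db.pairs | {(ids[0], ids[-1])}
        )
        bigger = compute_landscape(a, b, grown, params, exclude_query_pair=False).H
        assert (bigger >= base).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seq_a=st.text(alphabet="ACDG", min_size=2, max_size=12),
    seq_x=st.text(alphabet="ACDG", min_size=2, max_size=12),
)
def test_w1_reduces_to_residue_occurrence(seq_a, seq_x):
    """Exact matching at w=1 is single-residue occurrence counting."""
    a, x = Protein("A", seq_a), Protein("X", seq_x)
    profile = match_profile(a, x, MatchParams(w=1))
    expected = {i + 1 for i, c in enumerate(seq_a) if c in set(seq_x)}
    assert profile == expected
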