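import math

import numpy as np
import pytest

from pipesites.evaluation import (
    bin_dms,
    evaluate,
    per_protein_contributions,
    random_site_pair,
)
from pipesites.io_formats import LabSitePair, Protein
from pipesites.metrics import DMBreakdown
from pipesites.sites import Peak, SitePrediction


def _pred(rank, ra, rb, height=15):
    return SitePrediction(
        rank=rank,
        peak=Peak(i=ra[0], j=rb[0], height=height),
        rect=(ra[0], ra[1], rb[0], rb[1]),
        range_a=ra,
        range_b=rb,
    )


@pytest.fixture
def proteome100():
    seq = "ACDEFGHIKL" * 10
    return {pid: Protein(pid, seq) for pid in ("A", "B", "C", "D")}


class TestRandomSitePair:
    def test_degenerate_length_one(self):
        rng = np.random.default_rng(0)
        assert random_site_pair(1, 1, rng) == ((1, 1), (1, 1))

    def test_reproducible_under_seed(self):
        a = random_site_pair(50, 80, np.random.default_rng(42))
        b = random_site_pair(50, 80, np.random.default_rng(42))
        assert a == b

    def test_start_is_uniform(self):
        """P(start = 1) at len 100 should be ~1/100 (binomial 3-sigma band)."""
        rng = np.random.default_rng(123)
        n = 10_000
        hits = sum(random_site_pair(100, 100, rng)[0][0] == 1 for _ in range(n))
        p = 1 / 100
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) <= 3 * sigma

    def test_intervals_valid(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            (sa, ea), (sb, eb) = random_site_pair(37, 211, rng)
            assert 1 <= sa <= ea <= 37
            assert 1 <= sb <= eb <= 211


class TestEvaluate:
    def test_perfect_predictions_score_zero(self, proteome100):
        labs = [
            LabSitePair("A", "B", (10, 30), (40, 60)),
            LabSitePair("C", "D", (5, 25), (50, 70)),
        ]
        predictions = {
            ("A", "B"): [_pred(1, (10, 30), (40, 60))],
            ("C", "D"): [_pred(1, (5, 25), (50, 70))],
        }
        report = evaluate(predictions, labs, proteome100, k=1, n_random=1,
                          rng=np.random.default_rng(0))
        assert report.averages[1] == 0.0
        assert report.enrichment[1].counts_predicted[0] == 2

    def test_gated_pairs_counted_and_excluded(self, proteome100):
        labs = [
            LabSitePair("A", "B", (10, 30), (40, 60)),
            LabSitePair("C", "D", (5, 25), (50, 70)),
        ]
        predictions = {("A", "B"): [_pred(1, (10, 30), (40, 60))]}
        report = evaluate(predictions, labs, proteome100, k=2, n_random=2,
                          rng=np.random.default_rng(0))
        assert report.n_gated == 1 and report.n_evaluated == 1

    def test_best_of_k_averages_non_increasing(self, proteome100):
        rng = np.random.default_rng(11)
        # many pairs, each carrying 3 randomly placed predictions
        labs, predictions = [], {}
        ids = list(proteome100)
        extra = {f"Q{i}": Protein(f"Q{i}", proteome100[ids[0]].sequence)
                 for i in range(40)}
        proteome = {**proteome100, **extra}
        for idx in range(40):
            id_a, id_b = f"Q{idx}", ids[idx % len(ids)]
            labs.append(LabSitePair(id_a, id_b, (10, 30), (40, 60)))
            predictions[(id_a, id_b)] = [
                _pred(r + 1, random_site_pair(100, 100, rng)[0],
                      random_site_pair(100, 100, rng)[1])
                for r in range(3)
            ]
        proteome100 = proteome
        report = evaluate(predictions, labs, proteome100, k=3, n_random=3,
                          rng=np.random.default_rng(1))
        values = [report.averages[m] for m in (1, 2, 3)]
        assert values == sorted(values, reverse=True)

    def test_flipped_pair_key_swaps_protein_roles(self, proteome100):
        labs = [LabSitePair("A", "B", (10, 30), (40, 60))]
        direct = {("A", "B"): [_pred(1, (10, 30), (40, 60))]}
        flipped = {("B", "A"): [_pred(1, (40, 60), (10, 30))]}
        r1 = evaluate(direct, labs, proteome100, k=1, n_random=1,
                      rng=np.random.default_rng(0))
        r2 = evaluate(flipped, labs, proteome100, k=1, n_random=1,
                      rng=np.random.default_rng(0))
        assert r1.averages[1] == r2.averages[1] == 0.0

    def test_missing_protein_raises(self, proteome100):
        labs = [LabSitePair("A", "ZZ", (1, 5), (1, 5))]
        with pytest.raises(KeyError, match="ZZ"):
            evaluate({}, labs, proteome100, rng=np.random.default_rng(0))

    def test_seed_is_mandatory(self, proteome100):
        with pytest.raises(ValueError):
            evaluate({}, [], proteome100, rng=None)


class TestEnrichment:
    def test_condition_against_itself_is_one(self):
        dms = [0.05, 0.15, 0.55, 0.30, 0.02]
        table = bin_dms(dms, dms)
        for pred, rand, enr in zip(
            table.counts_predicted, table.counts_random, table.enrichment
        ):
            if rand:
                assert enr == 1.0
            else:
                assert math.isnan(enr)

    def test_counts_sum_to_sample_size(self):
        rng = np.random.default_rng(3)
        dms = rng.uniform(0, 1, size=97)
        table = bin_dms(dms, dms)
        assert sum(table.counts_predicted) == 97


class TestPerProteinContributions:
    def test_average_and_frequency(self):
        sqrt2 = math.sqrt(2)
        bds = [
            ("P1", "P2", DMBreakdown(0, 0, 0.0, 0.0, 0.0)),
            ("P1", "P3", DMBreakdown(5, 0, 0.2 * sqrt2, 0.0, 0.2)),
        ]
        table = per_protein_contributions(bds)
        row = table[table.protein == "P1"].iloc[0]
        assert row.frequency == 2
        assert row.avg_contribution == pytest.approx(0.1)

    def test_contained_prediction_contributes_zero(self):
        bds = [("P1", "P2", DMBreakdown(0, 9, 0.0, 0.5, 0.35))]
        table = per_protein_contributions(bds)
        assert table[table.protein == "P1"].iloc[0].avg_contribution == 0.0

    def test_sorted_by_descending_frequency(self):
        bd = DMBreakdown(0, 0, 0.0, 0.0, 0.0)
        bds = [("P1", "P2", bd), ("P1", "P3", bd), ("P3", "P1", bd)]
        table = per_protein_contributions(bds)
        assert list(table.protein[:1]) == ["P1"]
        assert list(table.frequency) == sorted(table.frequency, reverse=True)
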