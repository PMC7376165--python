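"""Fisher enrichment, difference scores and 1D rank enrichment, each checked
against independent combinatorial oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from npcorona import (
    AnnotationCatalog,
    difference_scores,
    fisher_enrichment,
    fisher_p,
    one_d_enrichment,
    one_d_score,
)
from conftest import make_tensor


def hypergeom_two_sided_p(a, b, c, d):
    """Oracle: enumerate the hypergeometric support and sum probabilities
    not exceeding that of the observed table."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    return float(pmf[pmf <= pmf[support == a][0] * (1 + 1e-7)].sum())


def brute_force_one_d(member, other):
    """Oracle: count member-over-non-member wins pairwise, ties as 1/2."""
    u = 0.0
    for m in member:
        for o in other:
            u += 1.0 if m > o else (0.5 if m == o else 0.0)
    return 2.0 * u / (len(member) * len(other)) - 1.0


def bh_step_up(pvals):
    """Oracle: textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestFisher:
    def test_worked_odds_ratio(self):
        reference = {f"P{i}" for i in range(100)}
        panel = {f"P{i}" for i in range(50)}
        term = {f"P{i}" for i in range(35, 55)}  # 20 members, 15 in panel
        catalog = AnnotationCatalog("GOCC", {"T": frozenset(term)}, {})
        (rec,) = fisher_enrichment(panel, reference, catalog)
        assert rec.table == ((15, 35), (5, 45))
        assert 2 ** rec.log2_odds == pytest.approx(3.857, abs=5e-4)
        assert rec.log2_odds == pytest.approx(1.948, abs=5e-4)
        assert rec.p_value == pytest.approx(hypergeom_two_sided_p(15, 35, 5, 45))
        assert rec.enriched

    def test_proportional_membership_gives_zero_log_odds(self):
        reference = {f"P{i}" for i in range(100)}
        panel = {f"P{i}" for i in range(50)}
        term = {f"P{i}" for i in range(40, 60)}  # 10 in, 10 out of panel
        catalog = AnnotationCatalog("GOCC", {"T": frozenset(term)}, {})
        (rec,) = fisher_enrichment(panel, reference, catalog)
        assert rec.log2_odds == pytest.approx(0.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_degenerate_table_clamped_to_extreme_finite(self):
        reference = {f"P{i}" for i in range(40)}
        panel = {f"P{i}" for i in range(20)}
        catalog = AnnotationCatalog("GOCC", {
            "all_in": frozenset({"P0", "P1", "P2"}),          # infinite OR
            "tilted": frozenset({"P0", "P1", "P2", "P30"}),   # finite OR
        }, {})
        records = {r.term_id: r for r in fisher_enrichment(panel, reference, catalog)}
        assert np.isfinite(records["all_in"].log2_odds)
        assert records["all_in"].log2_odds == records["tilted"].log2_odds
        assert records["all_in"].enriched

    def test_panel_outside_reference_dropped_with_warning(self):
        catalog = AnnotationCatalog("GOCC", {"T": frozenset({"P1"})}, {})
        with pytest.warns(UserWarning, match="dropped"):
            fisher_enrichment({"P1", "GHOST"}, {"P1", "P2", "P3"}, catalog)

    def test_p_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_p(a, b, c, d) == pytest.approx(
                hypergeom_two_sided_p(a, b, c, d), rel=1e-9)


class TestDifferenceScores:
    def _tensor(self, medians_by_np, missing=()):
        # one protein per row; three replicates at exactly the median value
        values = {}
        for protein, per_np in medians_by_np.items():
            values[protein] = {
                (np_id, "standard", "pool", r): (np.nan if (protein, np_id, r) in missing
                                                 else m)
                for np_id, m in per_np.items() for r in (1, 2, 3)
            }
        return make_tensor(values, scale="log10")

    def test_identical_medians_score_zero(self):
        t = self._tensor({"P1": {"A": 1.5, "B": 1.5, "C": 1.5}})
        assert (difference_scores(t).loc["P1"] == 0.0).all()

    def test_hand_computed_scores(self):
        t = self._tensor({"P1": {"A": 4.0, "B": 1.0, "C": 1.0}})
        scores = difference_scores(t)
        assert scores.loc["P1", "A"] == pytest.approx(3.0)
        assert scores.loc["P1", "B"] == pytest.approx(-1.5)
        assert scores.loc["P1", "C"] == pytest.approx(-1.5)

    def test_scores_sum_to_zero_when_fully_quantified(self):
        rng = np.random.default_rng(2)
        t = self._tensor({f"P{i}": {n: float(rng.normal()) for n in "ABCD"}
                          for i in range(20)})
        sums = difference_scores(t).sum(axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)

    def test_partial_quantification_everywhere_excluded(self):
        missing = {("P1", np_id, 3) for np_id in "ABC"}  # 2/3 on every particle
        t = self._tensor({"P1": {"A": 1.0, "B": 2.0, "C": 3.0},
                          "P2": {"A": 1.0, "B": 2.0, "C": 3.0}}, missing=missing)
        scores = difference_scores(t)
        assert "P1" not in scores.index and "P2" in scores.index

    def test_single_particle_rejected(self):
        t = self._tensor({"P1": {"A": 1.0}})
        with pytest.raises(ValueError):
            difference_scores(t)


class TestOneDScore:
    def test_members_at_top_score_plus_one(self):
        assert one_d_score(np.array([10.0, 9.0]), np.array([1.0, 2.0, 3.0])) == 1.0

    def test_symmetric_extremes_score_zero(self):
        # members at ranks 1 and 6 of six values
        member = np.array([6.0, 1.0])
        other = np.array([2.0, 3.0, 4.0, 5.0])
        assert one_d_score(member, other) == 0.0
        assert brute_force_one_d(member, other) == 0.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(400):
            n = int(rng.integers(3, 13))
            n1 = int(rng.integers(1, n))
            values = rng.integers(0, 5, size=n).astype(float)  # many ties
            member, other = values[:n1], values[n1:]
            assert one_d_score(member, other) == pytest.approx(
                brute_force_one_d(member, other))

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10),
           st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, values, data):
        n1 = data.draw(st.integers(1, len(values) - 1))
        member = np.array(values[:n1])
        other = np.array(values[n1:])
        s_pos = one_d_score(member, other)
        s_neg = one_d_score(-member, -other)
        assert s_pos == pytest.approx(-s_neg)

    def test_random_membership_centers_on_zero(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=60)
        means = []
        for _ in range(1000):
            pick = rng.choice(60, size=15, replace=False)
            mask = np.zeros(60, dtype=bool)
            mask[pick] = True
            means.append(one_d_score(values[mask], values[~mask]))
        assert abs(np.mean(means)) < 0.05


class TestOneDEnrichment:
    def _scores(self, n=120, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"P{i:03d}" for i in range(n)],
            columns=["NP-A", "NP-B", "NP-C"],
        )

    def test_small_terms_filtered_not_errored(self):
        scores = self._scores()
        catalog = AnnotationCatalog("GOCC", {
            "small": frozenset(scores.index[:5]),
            "large": frozenset(scores.index[:30]),
        }, {})
        records = one_d_enrichment(scores, catalog, min_size=11)
        assert {r.term_id for r in records} == {"large"}

    def test_planted_shift_detected_with_fdr_control(self):
        scores = self._scores()
        members = list(scores.index[:25])
        scores.loc[members, "NP-A"] += 2.0  # strong planted enrichment
        catalog = AnnotationCatalog("GOCC", {
            "planted": frozenset(members),
            **{f"null{i}": frozenset(
                np.random.default_rng(i).choice(scores.index, 20, replace=False))
               for i in range(10)},
        }, {})
        records = one_d_enrichment(scores, catalog, min_size=11, fdr_level=0.02)
        planted = [r for r in records if r.term_id == "planted" and r.np_id == "NP-A"]
        assert planted[0].score > 0
        assert planted[0].fdr < 0.02
        assert planted[0].term_significant

    def test_bh_adjustment_matches_step_up_oracle(self):
        scores = self._scores(n=200, seed=5)
        rng = np.random.default_rng(6)
        catalog = AnnotationCatalog("KEGG", {
            f"T{i}": frozenset(rng.choice(scores.index, rng.integers(12, 40),
                                          replace=False))
            for i in range(15)
        }, {})
        records = one_d_enrichment(scores, catalog)
        expected = bh_step_up([r.p_value for r in records])
        np.testing.assert_allclose([r.fdr for r in records], expected)

    def test_bh_oracle_on_random_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(adj, bh_step_up(p))
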