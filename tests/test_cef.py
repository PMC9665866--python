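"""Multinomial exact test, FSN classification and the CEF workflow."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import poms
from poms.cef import _direction_summary, FsnClassCounts
from poms.node_tests import BsnResult, FsnResult


def multinomial_oracle(counts, probs):
    """Independent full enumeration with LLR ordering (math module only)."""
    n = sum(counts)
    if n == 0:
        return 1.0

    def llr(ks):
        return 2.0 * sum(k * math.log(k / (n * p)) for k, p in zip(ks, probs) if k > 0)

    def pmf(ks):
        lp = math.lgamma(n + 1) - sum(math.lgamma(k + 1) for k in ks)
        for k, p in zip(ks, probs):
            if k > 0:
                lp += k * math.log(p)
        return math.exp(lp)

    gobs = llr(counts)
    total = 0.0
    for k1 in range(n + 1):
        for k2 in range(n - k1 + 1):
            ks = (k1, k2, n - k1 - k2)
            if any(k > 0 and p == 0 for k, p in zip(ks, probs)):
                continue
            if llr(ks) >= gobs - 1e-9 * max(1.0, abs(gobs)):
                total += pmf(ks)
    return min(1.0, total)


class TestNullProbabilities:
    def test_mass_action_split(self):
        assert np.allclose(poms.null_probabilities(100, 10), [0.90, 0.05, 0.05])

    def test_no_bsns(self):
        assert np.allclose(poms.null_probabilities(50, 0), [1.0, 0.0, 0.0])

    def test_all_bsns(self):
        assert np.allclose(poms.null_probabilities(8, 8), [0.0, 0.5, 0.5])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            poms.null_probabilities(5, 6)


class TestMultinomialExact:
    def test_empty_observation(self):
        assert poms.multinomial_exact_test((0, 0, 0), (0.9, 0.05, 0.05)) == 1.0

    def test_single_possible_outcome(self):
        assert poms.multinomial_exact_test((2, 0, 0), (1.0, 0.0, 0.0)) == 1.0

    def test_impossible_observation_rejected(self):
        with pytest.raises(ValueError):
            poms.multinomial_exact_test((0, 1, 0), (1.0, 0.0, 0.0))

    def test_frozen_hand_case(self):
        # all five FSNs in a 5%-probability class
        p = poms.multinomial_exact_test((0, 5, 0), (0.9, 0.05, 0.05))
        assert p == pytest.approx(6.25e-07, rel=1e-9)

    def test_category_swap_symmetry(self):
        p1 = poms.multinomial_exact_test((3, 1, 4), (0.6, 0.3, 0.1))
        p2 = poms.multinomial_exact_test((3, 4, 1), (0.6, 0.1, 0.3))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_least_extreme_outcome_has_p_one(self):
        """Summing every outcome's probability must give exactly 1."""
        probs = (0.55, 0.3, 0.15)
        n = 9
        best, best_g = None, None
        for k1 in range(n + 1):
            for k2 in range(n - k1 + 1):
                ks = (k1, k2, n - k1 - k2)
                g = 2.0 * sum(
                    k * math.log(k / (n * p)) for k, p in zip(ks, probs) if k > 0
                )
                if best_g is None or g < best_g:
                    best, best_g = ks, g
        assert poms.multinomial_exact_test(best, probs) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(0, 13))
            probs = rng.dirichlet([1.0, 1.0, 1.0])
            counts = rng.multinomial(n, probs)
            mine = poms.multinomial_exact_test(tuple(counts), tuple(probs))
            orc = multinomial_oracle(tuple(counts), tuple(probs))
            assert mine == pytest.approx(orc, abs=1e-12)


class TestClassifyFsns:
    def _fsn(self, node, fn, sig=True, side="lhs"):
        return FsnResult(node, fn, 0.01 if sig else 0.5, sig, side if sig else None, ((0, 0), (0, 0)))

    def _bsn(self, node, sig=True, direction="lhs"):
        return BsnResult(node, 0.01 if sig else 0.5, sig, direction if sig else None, "user")

    def test_non_bsn_node_counts_nonintersecting(self):
        counts = poms.classify_fsns([self._fsn("n1", "f")], [self._bsn("n1", sig=False)])
        assert counts["f"].as_array().tolist() == [1, 0, 0]

    def test_matching_side_counts_group1(self):
        counts = poms.classify_fsns([self._fsn("n1", "f", side="lhs")], [self._bsn("n1")])
        assert counts["f"].as_array().tolist() == [0, 1, 0]

    def test_opposite_side_counts_group2(self):
        counts = poms.classify_fsns([self._fsn("n1", "f", side="rhs")], [self._bsn("n1")])
        assert counts["f"].as_array().tolist() == [0, 0, 1]

    def test_nondirectional_bsn_counts_as_non_bsn(self):
        bsn = BsnResult("n1", 0.01, True, None, "wilcoxon")
        counts = poms.classify_fsns([self._fsn("n1", "f")], [bsn])
        assert counts["f"].as_array().tolist() == [1, 0, 0]

    def test_no_significant_fsns(self):
        counts = poms.classify_fsns([self._fsn("n1", "f", sig=False)], [self._bsn("n1")])
        assert counts["f"].as_array().tolist() == [0, 0, 0]

    def test_mixed_signal_is_representable(self):
        """Intersections toward both groups, few non-intersecting: significant, mixed."""
        nodes = [f"n{i}" for i in range(30)]
        bsns = [self._bsn(n, sig=(i < 6), direction="lhs" if i < 3 else "rhs")
                for i, n in enumerate(nodes)]
        fsns = [self._fsn(nodes[i], "f", side="lhs") for i in range(6)]
        counts = poms.classify_fsns(fsns, bsns)["f"]
        assert counts.as_array().tolist() == [0, 3, 3]
        probs = poms.null_probabilities(30, 6)
        p = poms.multinomial_exact_test(counts.as_array(), probs)
        assert p < 0.05
        assert _direction_summary(counts, "g1", "g2") == "mixed"


class TestDirectionSummary:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 4, 0), "g1-consistent"),
            ((2, 0, 4), "g2-consistent"),
            ((2, 3, 1), "mixed"),
            ((5, 0, 0), "mixed"),
        ],
    )
    def test_rule(self, counts, expected):
        c = FsnClassCounts("f", *counts)
        assert _direction_summary(c, "g1", "g2") == expected


def bh_oracle(ps):
    """Reference Benjamini–Hochberg step-up."""
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, ps[i] * m / rank)
        adj[i] = prev
    return adj


class TestRunPoms:
    def test_demo_consistent_function_tops_table(self, demo):
        res = poms.run_poms(
            demo.phylogeny, demo.taxa_table, demo.function_table, demo.design, min_tips=4
        )
        assert res.cefs[0].function_id == "consistent"
        assert res.cefs[0].bh_p < 0.05
        assert res.cefs[0].direction_summary == "group1-consistent"
        incons = next(r for r in res.cefs if r.function_id == "inconsistent")
        assert incons.bh_p >= 0.05

    def test_bh_matches_stepup_oracle_and_is_monotone(self, demo):
        res = poms.run_poms(
            demo.phylogeny, demo.taxa_table, demo.function_table, demo.design, min_tips=4
        )
        raw = np.array([r.p_value for r in res.cefs])
        adj = np.array([r.bh_p for r in res.cefs])
        assert np.allclose(adj, bh_oracle(raw))
        assert (adj >= raw - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_ubiquitous_function_never_cef(self, demo):
        ft = demo.function_table.copy()
        ft["everywhere"] = 1.0
        res = poms.run_poms(demo.phylogeny, demo.taxa_table, ft, demo.design, min_tips=4)
        rec = next(r for r in res.cefs if r.function_id == "everywhere")
        assert rec.counts.total == 0
        assert rec.p_value == 1.0

    def test_zero_bsns_degenerates_with_warning(self, demo, caplog):
        user = poms.bsn_user(
            [p.node_id for p in demo.phylogeny.testable_nodes(4)], {}, {}
        )
        with caplog.at_level("WARNING", logger="poms"):
            res = poms.run_poms(
                demo.phylogeny, demo.taxa_table, demo.function_table, demo.design,
                min_tips=4, user_bsns=user,
            )
        assert "zero directional BSNs" in caplog.text
        assert all(r.p_value == 1.0 for r in res.cefs)

    def test_zero_fsn_functions_kept_in_bh_family(self, demo):
        res = poms.run_poms(
            demo.phylogeny, demo.taxa_table, demo.function_table, demo.design, min_tips=4
        )
        assert len(res.cefs) == demo.function_table.shape[1]

    def test_cef_table_columns(self, demo):
        res = poms.run_poms(
            demo.phylogeny, demo.taxa_table, demo.function_table, demo.design, min_tips=4
        )
        table = res.cef_table()
        assert "total_fsns" in table.columns and "corrected_p" in table.columns
        assert table.shape[0] == len(res.cefs)
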