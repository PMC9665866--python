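"""Synthetic communities, perturbation schemes and focal-gene ranking."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import poms


class TestGenerateCommunity:
    def test_same_seed_identical(self):
        a = poms.generate_community(n_taxa=40, n_samples_per_group=5, n_functions=20, seed=3)
        b = poms.generate_community(n_taxa=40, n_samples_per_group=5, n_functions=20, seed=3)
        assert a.phylogeny.to_newick() == b.phylogeny.to_newick()
        pd.testing.assert_frame_equal(a.taxa_table, b.taxa_table)
        pd.testing.assert_frame_equal(a.function_table, b.function_table)

    def test_different_seed_differs(self):
        a = poms.generate_community(n_taxa=40, n_samples_per_group=5, n_functions=20, seed=3)
        b = poms.generate_community(n_taxa=40, n_samples_per_group=5, n_functions=20, seed=4)
        assert not a.taxa_table.equals(b.taxa_table)

    def test_sparsity_near_target(self):
        com = poms.generate_community(n_taxa=200, n_samples_per_group=20, n_functions=5,
                                      sparsity=0.7, seed=0)
        realized = (com.taxa_table.to_numpy() == 0).mean()
        assert 0.6 <= realized <= 0.8

    def test_function_rarity_spectrum(self, small_community):
        frac = (small_community.function_table > 0).mean(axis=0)
        assert frac.min() <= 0.1
        assert frac.max() >= 0.5
        assert ((frac > 0) & (frac < 1)).all()

    def test_no_functions(self):
        com = poms.generate_community(n_taxa=40, n_samples_per_group=5, n_functions=0, seed=1)
        assert com.function_table.shape[1] == 0

    def test_clustering_lowers_encoder_pd(self):
        """Clustered gene content spans less branch length than random sets."""
        rng = np.random.default_rng(5)
        clustered = poms.generate_community(
            n_taxa=150, n_samples_per_group=4, n_functions=30, clustering=0.75, seed=5
        )
        scattered = poms.generate_community(
            n_taxa=150, n_samples_per_group=4, n_functions=30, clustering=0.0, seed=5
        )

        def pd_ratio(com):
            phy = com.phylogeny
            tips = list(phy.tips)
            ratios = []
            for fid in com.function_table.columns:
                enc = com.encoding_taxa(fid)
                if not 10 <= len(enc) <= 120:
                    continue
                rand = np.mean(
                    [phy.faith_pd(rng.choice(tips, size=len(enc), replace=False))
                     for _ in range(30)]
                )
                ratios.append(phy.faith_pd(enc) / rand)
            return np.mean(ratios)

        # scattered limit: encoder sets look like uniform random subsets
        assert 0.9 <= pd_ratio(scattered) <= 1.1
        assert pd_ratio(clustered) < 0.9


@pytest.fixture(scope="module")
def com():
    return poms.generate_community(n_taxa=60, n_samples_per_group=6, n_functions=30, seed=11)


class TestPerturbations:
    def test_focal_gene_rule_and_locality(self, com):
        enc = (com.function_table > 0).sum(axis=0)
        focal = enc.index[(enc >= 5)][0]
        table, rec = poms.perturb_focal_gene(com, focal, "group2")
        assert rec.scheme == "focal_gene"
        assert rec.perturbed_taxa == frozenset(com.encoding_taxa(focal))
        g2 = set(com.design.samples_in("group2"))
        before, after = com.taxa_table, table
        for t in before.index:
            for s in before.columns:
                b, a = before.loc[t, s], after.loc[t, s]
                if t in rec.perturbed_taxa and s in g2:
                    assert a == pytest.approx((b + 1.0) * 1.5, rel=1e-12)
                else:
                    assert a == b

    def test_identity_perturbation(self, com):
        enc = (com.function_table > 0).sum(axis=0)
        focal = enc.index[(enc >= 5)][0]
        table, _ = poms.perturb_focal_gene(com, focal, "group1", pseudocount=0.0, multiplier=1.0)
        pd.testing.assert_frame_equal(table, com.taxa_table)

    def test_unknown_function_rejected(self, com):
        with pytest.raises(KeyError):
            poms.perturb_focal_gene(com, "nope", "group1")

    def test_random_taxa_matched_size_and_seeded(self, com):
        t1, r1 = poms.perturb_random_taxa(com, 12, "group1", seed=5)
        t2, r2 = poms.perturb_random_taxa(com, 12, "group1", seed=5)
        t3, r3 = poms.perturb_random_taxa(com, 12, "group1", seed=6)
        assert len(r1.perturbed_taxa) == 12
        assert r1.perturbed_taxa == r2.perturbed_taxa
        assert r1.perturbed_taxa != r3.perturbed_taxa
        pd.testing.assert_frame_equal(t1, t2)

    def test_random_taxa_extremes(self, com):
        t0, r0 = poms.perturb_random_taxa(com, 0, "group1", seed=1)
        pd.testing.assert_frame_equal(t0, com.taxa_table)
        tn, rn = poms.perturb_random_taxa(com, 60, "group1", seed=1)
        assert len(rn.perturbed_taxa) == 60
        with pytest.raises(ValueError):
            poms.perturb_random_taxa(com, 61, "group1", seed=1)

    def test_clade_perturbation(self, com):
        phy = com.phylogeny
        nodes = phy.clade_nodes(min_total_tips=5, exclude_root=True)
        node = min(nodes, key=lambda n: len(phy.clade_tips(n)))
        table, rec = poms.perturb_clade(com, node, "group2")
        assert rec.perturbed_taxa == phy.clade_tips(node)

    def test_clade_root_rejected(self, com):
        with pytest.raises(ValueError):
            poms.perturb_clade(com, com.phylogeny.root_id, "group2")

    def test_disjoint_clades_disjoint_sets(self, com):
        phy = com.phylogeny
        nodes = phy.clade_nodes(min_total_tips=5, exclude_root=True)
        for n1 in nodes:
            for n2 in nodes:
                a, b = phy.clade_tips(n1), phy.clade_tips(n2)
                if not (a <= b or b <= a):
                    _, r1 = poms.perturb_clade(com, n1, "group1")
                    _, r2 = poms.perturb_clade(com, n2, "group1")
                    assert not (r1.perturbed_taxa & r2.perturbed_taxa)
                    return
        pytest.skip("no disjoint clade pair in this topology")

    def test_perturbed_clade_side_becomes_bsn(self):
        """Inflating one side of a testable node must flag that node as a BSN."""
        com = poms.generate_community(
            n_taxa=100, n_samples_per_group=15, n_functions=10, seed=21
        )
        phy = com.phylogeny
        parts = phy.testable_nodes(5)
        target = None
        for p in parts:
            for nid in phy.clade_nodes(min_total_tips=5, exclude_root=True):
                if phy.clade_tips(nid) == p.lhs_tips:
                    target, node = p, nid
                    break
            if target:
                break
        assert target is not None
        table, _ = poms.perturb_clade(com, node, "group2", multiplier=3.0)
        bal = poms.balance_matrix(table, parts)
        bsns = poms.bsn_two_group(bal, com.design)
        hit = next(b for b in bsns if b.node_id == target.node_id)
        assert hit.is_significant
        assert hit.direction == "rhs"  # lhs inflated in group2 => rhs higher in group1


class TestFocalGeneRanking:
    def _rec(self, fid, p, bh):
        return SimpleNamespace(function_id=fid, p_value=p, bh_p=bh)

    def test_clear_winner(self):
        recs = [self._rec("a", 1e-6, 1e-4), self._rec("b", 0.01, 0.04), self._rec("c", 0.5, 0.9)]
        assert poms.focal_gene_ranking(recs, "a") == 1.0

    def test_not_significant_is_missing(self):
        recs = [self._rec("a", 0.5, 0.9)]
        assert poms.focal_gene_ranking(recs, "a") is None

    def test_tied_minimum_shares_mean_rank(self):
        recs = [self._rec("a", 1e-4, 0.01), self._rec("b", 1e-4, 0.01), self._rec("c", 0.9, 0.9)]
        assert poms.focal_gene_ranking(recs, "a") == 1.5
        assert poms.focal_gene_ranking(recs, "b") == 1.5

    def test_unknown_focal_rejected(self):
        with pytest.raises(KeyError):
            poms.focal_gene_ranking([self._rec("a", 0.1, 0.2)], "zzz")

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            poms.focal_gene_ranking([], "a")


class TestWeaklyEncodedFocal:
    def test_rare_focal_runs_without_crash(self):
        """A focal gene with very few encoders may be missed but must not break."""
        com = poms.generate_community(
            n_taxa=80, n_samples_per_group=10, n_functions=30, seed=13
        )
        enc = (com.function_table > 0).sum(axis=0)
        rare = enc.index[(enc >= 5) & (enc <= 6)]
        if rare.empty:
            rare = enc.index[enc == enc[enc >= 5].min()]
        focal = rare[0]
        table, _ = poms.perturb_focal_gene(com, focal, "group2")
        res = poms.run_poms(com.phylogeny, table, com.function_table, com.design, min_tips=5)
        assert len(res.cefs) >= 1
        assert all(0.0 <= r.p_value <= 1.0 for r in res.cefs)


class TestContrastDemo:
    def test_deterministic(self):
        a = poms.simulate.contrast_demo(seed=0)
        b = poms.simulate.contrast_demo(seed=0)
        pd.testing.assert_frame_equal(a.taxa_table, b.taxa_table)

    def test_structure(self, demo):
        assert demo.phylogeny.n_tips == 60
        assert set(demo.function_table.columns) == {"consistent", "inconsistent", "mixed"}
        assert int((demo.function_table["consistent"] > 0).sum()) == 24
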