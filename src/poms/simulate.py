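"""Synthetic communities and the three perturbation schemes used for benchmarking.

The generator emulates, at desk scale, the kind of data the balance-tree
workflow is designed for: a set of genomes (taxa) on a shared random
bifurcating phylogeny, sparse heavy-tailed abundance profiles across two
sample groups, and a gene-presence matrix whose genes span the rarity
spectrum (from ~1% to ~95% of taxa) and are phylogenetically clustered to a
configurable degree.

Perturbation schemes (all applied to target-group samples only, with the
rule ``abundance <- (abundance + pseudocount) * multiplier``):

* focal gene — every taxon encoding a randomly chosen "focal" function is
  inflated, simulating selection on the function itself;
* random taxa — a uniformly drawn taxon set of matched size is inflated,
  the negative control where no consistent functional signal is expected;
* clade — all descendants of one internal node are inflated, probing
  robustness to the bloom of a single lineage.

``focal_gene_ranking`` evaluates recovery: the 1-based rank (mean rank under
ties) of the focal function among the significant functions of a result
list, ordered by ascending p-value; ``None`` when the focal function is not
significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .phylo_core import Phylogeny
from .tables import SampleDesign

logger = logging.getLogger("poms")

__all__ = [
    "SyntheticCommunity",
    "PerturbationRecord",
    "generate_community",
    "perturb_focal_gene",
    "perturb_random_taxa",
    "perturb_clade",
    "focal_gene_ranking",
]


@dataclass
class SyntheticCommunity:
    phylogeny: Phylogeny
    taxa_table: pd.DataFrame        # taxa x samples
    function_table: pd.DataFrame    # taxa x functions
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def design(self) -> SampleDesign:
        """Two-group design implied by the sample naming (g1/g2 prefixes)."""
        groups = pd.Series(
            ["group1" if s.startswith("g1") else "group2" for s in self.taxa_table.columns],
            index=self.taxa_table.columns,
        )
        return SampleDesign.two_group(groups, group1="group1", group2="group2")

    def encoding_taxa(self, function_id: str) -> list:
        col = self.function_table[function_id]
        return list(col.index[col > 0])


@dataclass(frozen=True)
class PerturbationRecord:
    scheme: str                      # focal_gene | random_taxa | clade
    perturbed_taxa: frozenset
    target_group: str
    pseudocount_used: float
    multiplier_used: float
    focal_function_id: Optional[str] = None
    node_id: Optional[str] = None
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------


def _random_bifurcating_newick(n_taxa: int, rng: np.random.Generator) -> str:
    """Random topology by sequential pair-joining; exponential branch lengths."""
    nodes = [f"T{i:04d}:{rng.exponential(0.1):.6f}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.1):.6f}"
        nodes[i] = merged
        del nodes[j]
    return f"({nodes[0]},{nodes[1]});"


def _normalize_depth(phy: Phylogeny) -> Phylogeny:
    """Rescale branch lengths so the maximum root-to-tip depth is 1."""
    depths = phy._depths()
    dmax = max(depths[id(t)] for t in phy.tree.tips())
    for node in phy.tree.traverse(include_self=False):
        node.length = node.length / dmax
    return Phylogeny(phy.tree)


def _simulate_presence(
    phy: Phylogeny, prevalences: np.ndarray, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state (absent/present) Markov switching along the tree.

    Per function f with stationary presence frequency pi_f, the state flips
    along a branch of length t with the standard two-state transition
    probabilities at total rate ``switch_rate``; low rates give
    phylogenetically clustered presence, high rates approach independent
    tips.  Returns tips x functions 0/1.
    """
    m = len(prevalences)
    tip_index = {t: i for i, t in enumerate(phy.tips)}
    states = {id(phy.tree): (rng.random(m) < prevalences).astype(np.int8)}
    out = np.zeros((phy.n_tips, m), dtype=np.int8)
    for node in phy.tree.preorder(include_self=False):
        parent = states[id(node.parent)]
        decay = math.exp(-switch_rate * node.length)
        p_present = np.where(
            parent == 1,
            prevalences + (1 - prevalences) * decay,
            prevalences * (1 - decay),
        )
        st = (rng.random(m) < p_present).astype(np.int8)
        if node.is_tip():
            out[tip_index[node.name]] = st
        else:
            states[id(node)] = st
    return out


def generate_community(
    n_taxa: int = 300,
    n_samples_per_group: int = 40,
    n_functions: int = 400,
    sparsity: float = 0.7,
    clustering: float = 0.75,
    seed: int = 0,
    meanlog: float = 1.0,
    sdlog: float = 1.0,
    taxon_sdlog: float = 1.0,
    min_prevalence: float = 0.01,
    max_prevalence: float = 0.95,
) -> SyntheticCommunity:
    """Generate a reproducible synthetic community.

    Abundances are zero-inflated log-normal: each taxon draws an occupancy
    probability around ``1 - sparsity`` (Beta-distributed, so some taxa are
    near-core and some near-absent) and a taxon-level mean depth (log-normal
    across taxa, giving the heavy tail).  Function presence follows the
    two-state switching process of :func:`_simulate_presence` with switch
    rate ``0.5 * 100**(1 - clustering)`` per unit tree depth: ``clustering=1``
    gives strongly conserved gene content, ``clustering=0`` nearly independent
    tips.  Function prevalence targets are log-uniform on
    [min_prevalence, max_prevalence].  Copy numbers are 1 plus occasional
    extra copies.
    """
    if not 4 <= n_taxa:
        raise ValueError("n_taxa too small")
    if n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    if not 0 <= clustering <= 1:
        raise ValueError("clustering must be in [0, 1]")
    rng = np.random.default_rng(seed)

    phy = _normalize_depth(Phylogeny.from_newick(_random_bifurcating_newick(n_taxa, rng)))
    taxa = list(phy.tips)
    samples = [f"g1s{i:03d}" for i in range(n_samples_per_group)] + [
        f"g2s{i:03d}" for i in range(n_samples_per_group)
    ]
    n_samples = len(samples)

    occupancy = (
        rng.beta(6 * (1 - sparsity), 6 * sparsity, size=n_taxa)
        if sparsity > 0
        else np.ones(n_taxa)
    )
    taxon_mu = rng.normal(meanlog, taxon_sdlog, size=n_taxa)
    present = rng.random((n_taxa, n_samples)) < occupancy[:, None]
    depths = np.exp(rng.normal(taxon_mu[:, None], sdlog, size=(n_taxa, n_samples)))
    abund = np.where(present, depths, 0.0)
    taxa_table = pd.DataFrame(np.round(abund, 4), index=taxa, columns=samples)

    if n_functions > 0:
        prevalences = np.exp(
            rng.uniform(math.log(min_prevalence), math.log(max_prevalence), size=n_functions)
        )
        switch_rate = 0.5 * 100 ** (1 - clustering)
        presence = _simulate_presence(phy, prevalences, switch_rate, rng)
        # avoid degenerate all-absent / all-present functions: re-draw a few
        # times, then force one flipped tip for any stubborn column
        for _ in range(10):
            counts = presence.sum(axis=0)
            bad = (counts == 0) | (counts == n_taxa)
            if not bad.any():
                break
            presence[:, bad] = _simulate_presence(
                phy, prevalences[bad], switch_rate, rng
            )
        counts = presence.sum(axis=0)
        for j in np.where(counts == 0)[0]:
            presence[rng.integers(n_taxa), j] = 1
        for j in np.where(counts == n_taxa)[0]:
            presence[rng.integers(n_taxa), j] = 0
        copies = presence * (1 + rng.poisson(0.15, size=presence.shape))
        function_table = pd.DataFrame(
            copies.astype(float),
            index=taxa,
            columns=[f"F{j:04d}" for j in range(n_functions)],
        )
    else:
        function_table = pd.DataFrame(index=pd.Index(taxa), columns=pd.Index([], dtype=object))

    params = dict(
        n_taxa=n_taxa,
        n_samples_per_group=n_samples_per_group,
        n_functions=n_functions,
        sparsity=sparsity,
        clustering=clustering,
        meanlog=meanlog,
        sdlog=sdlog,
        taxon_sdlog=taxon_sdlog,
    )
    return SyntheticCommunity(phy, taxa_table, function_table, seed, params)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def _apply_perturbation(
    taxa_table: pd.DataFrame, taxa, group_samples, pseudocount: float, multiplier: float
) -> pd.DataFrame:
    out = taxa_table.copy()
    if taxa:
        rows = out.index.get_indexer(list(taxa))
        cols = out.columns.get_indexer(list(group_samples))
        block = out.to_numpy()
        sub = block[np.ix_(rows, cols)]
        block[np.ix_(rows, cols)] = (sub + pseudocount) * multiplier
        out = pd.DataFrame(block, index=out.index, columns=out.columns)
    return out


def _group_samples(community: SyntheticCommunity, target_group: str) -> list:
    design = community.design
    if target_group not in (design.group1, design.group2):
        raise ValueError(f"unknown target group {target_group!r}")
    return design.samples_in(target_group)


def perturb_focal_gene(
    community: SyntheticCommunity,
    focal_function: str,
    target_group: str,
    pseudocount: float = 1.0,
    multiplier: float = 1.5,
):
    """Inflate every taxon encoding the focal function in one group's samples."""
    if focal_function not in community.function_table.columns:
        raise KeyError(f"unknown function {focal_function!r}")
    taxa = community.encoding_taxa(focal_function)
    if not taxa:
        raise ValueError(f"function {focal_function!r} is encoded by no taxa")
    table = _apply_perturbation(
        community.taxa_table, taxa, _group_samples(community, target_group),
        pseudocount, multiplier,
    )
    rec = PerturbationRecord(
        "focal_gene", frozenset(taxa), target_group, pseudocount, multiplier,
        focal_function_id=focal_function,
    )
    return table, rec


def perturb_random_taxa(
    community: SyntheticCommunity,
    n_taxa_to_perturb: int,
    target_group: str,
    pseudocount: float = 1.0,
    multiplier: float = 1.5,
    seed: int = 0,
):
    """Inflate a uniformly drawn taxon set of the given size (matched control)."""
    all_taxa = list(community.taxa_table.index)
    if n_taxa_to_perturb > len(all_taxa):
        raise ValueError("cannot perturb more taxa than exist")
    rng = np.random.default_rng(seed)
    taxa = list(rng.choice(all_taxa, size=n_taxa_to_perturb, replace=False)) if n_taxa_to_perturb else []
    table = _apply_perturbation(
        community.taxa_table, taxa, _group_samples(community, target_group),
        pseudocount, multiplier,
    )
    rec = PerturbationRecord(
        "random_taxa", frozenset(taxa), target_group, pseudocount, multiplier, seed=seed
    )
    return table, rec


def perturb_clade(
    community: SyntheticCommunity,
    node_id: str,
    target_group: str,
    pseudocount: float = 1.0,
    multiplier: float = 1.5,
    min_clade_tips: int = 5,
):
    """Inflate all descendants of one internal (non-root) node."""
    phy = community.phylogeny
    eligible = set(phy.clade_nodes(min_total_tips=min_clade_tips, exclude_root=True))
    if node_id not in eligible:
        raise ValueError(
            f"node {node_id!r} is not an eligible clade (non-root, >= {min_clade_tips} tips)"
        )
    taxa = sorted(phy.clade_tips(node_id))
    table = _apply_perturbation(
        community.taxa_table, taxa, _group_samples(community, target_group),
        pseudocount, multiplier,
    )
    rec = PerturbationRecord(
        "clade", frozenset(taxa), target_group, pseudocount, multiplier, node_id=node_id
    )
    return table, rec


# ---------------------------------------------------------------------------
# Deterministic contrast demo
# ---------------------------------------------------------------------------


def contrast_demo(
    seed: int = 0, n_samples_per_group: int = 12, fold: float = 4.0,
    include_mixed: bool = False,
) -> SyntheticCommunity:
    """A 60-tip worked example contrasting consistent and inconsistent enrichment.

    Fifteen 4-tip clades are arranged as seven clade pairs plus one extra
    clade hanging off a caterpillar spine.  In pairs 0-5 the left clade's
    taxa are ``fold`` times more abundant in group 1; pair 6 and the extra
    clade are unperturbed.  Two functions are annotated:

    * ``consistent`` — encoded by exactly the six elevated clades, so its
      enriched side coincides with the group-1-higher side at six independent
      nodes (the consistently-enriched pattern);
    * ``inconsistent`` — encoded by the left clade of the *unperturbed* pair
      plus two tips of every other clade, so its single clean
      function-significant node does not fall on a balance-significant node.

    With ``include_mixed`` a third function encoded by the elevated side of
    pairs 0-2 and the non-elevated side of pairs 3-5 is added: its
    intersections point to both groups (the mixed-signal pattern).

    Analyse with ``min_tips=4``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    clade_tips = [[f"C{k:02d}{x}" for x in "abcd"] for k in range(15)]

    def clade(k):
        a, b, c, d = clade_tips[k]
        return f"(({a}:0.1,{b}:0.1):0.2,({c}:0.1,{d}:0.1):0.2):0.3"

    pairs = [f"({clade(2 * k)},{clade(2 * k + 1)}):0.3" for k in range(7)]
    spine = f"({pairs[6]},{clade(14)}):0.3"
    for k in range(5, -1, -1):
        spine = f"({pairs[k]},{spine}):0.3"
    phy = Phylogeny.from_newick(spine[: spine.rfind(":")] + ";")

    taxa = list(phy.tips)
    samples = [f"g1s{i:03d}" for i in range(n_samples_per_group)] + [
        f"g2s{i:03d}" for i in range(n_samples_per_group)
    ]
    abund = np.exp(rng.normal(2.0, 0.5, size=(len(taxa), len(samples))))
    elevated = [t for k in range(6) for t in clade_tips[2 * k]]
    rows = [taxa.index(t) for t in elevated]
    abund[np.ix_(rows, range(n_samples_per_group))] *= fold
    taxa_table = pd.DataFrame(np.round(abund, 4), index=taxa, columns=samples)

    consistent = set(elevated)
    # full left clade of the unperturbed pair, plus a balanced 2-of-4 spread
    # everywhere else (so no other node shows a side-wise imbalance)
    inconsistent = set(clade_tips[12]) | {
        clade_tips[k][x] for k in range(15) if k not in (12, 13) for x in (0, 1)
    }
    funcs = {
        "consistent": [1.0 if t in consistent else 0.0 for t in taxa],
        "inconsistent": [1.0 if t in inconsistent else 0.0 for t in taxa],
    }
    if include_mixed:
        mixed = {t for k in range(3) for t in clade_tips[2 * k]} | {
            t for k in range(3, 6) for t in clade_tips[2 * k + 1]
        }
        funcs["mixed"] = [1.0 if t in mixed else 0.0 for t in taxa]
    function_table = pd.DataFrame(funcs, index=taxa)
    params = dict(kind="contrast_demo", fold=fold, n_samples_per_group=n_samples_per_group)
    return SyntheticCommunity(phy, taxa_table, function_table, seed, params)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def null_calibration_study(
    n_replicates: int = 50,
    n_bsn_replicates: int = 70,
    seed: int = 0,
    min_tips: int = 5,
    node_alpha: float = 0.05,
    bh_alpha: float = 0.05,
    **community_kwargs,
) -> dict:
    """False-positive behaviour on unperturbed communities with random labels.

    Runs the full CEF workflow on ``n_replicates`` unperturbed communities
    (the two groups are arbitrary labels over exchangeable samples) and
    additionally measures the per-node BSN rate over ``n_bsn_replicates``
    balance-only replicates, pooling all node tests.  A calibrated workflow
    should flag CEFs in at most ~bh_alpha of replicates and BSNs at ~node_alpha
    of nodes.
    """
    from . import cef as _cef

    rng = np.random.default_rng(seed)
    child = rng.integers(2**31 - 1, size=max(n_replicates, n_bsn_replicates))
    any_cef = 0
    bsn_hits = 0
    node_tests_total = 0
    for i in range(n_bsn_replicates):
        com = generate_community(seed=int(child[i]), **community_kwargs)
        parts = com.phylogeny.testable_nodes(min_tips)
        from . import balances as _bal
        from . import node_tests as _nt

        bal = _bal.balance_matrix(com.taxa_table, parts)
        bsns = _nt.bsn_two_group(bal, com.design, node_alpha)
        bsn_hits += sum(1 for b in bsns if b.is_significant)
        node_tests_total += len(bsns)
        if i < n_replicates:
            res = _cef.run_poms(
                com.phylogeny, com.taxa_table, com.function_table, com.design,
                min_tips=min_tips, node_alpha=node_alpha, bh_alpha=bh_alpha,
            )
            any_cef += any(r.bh_p < bh_alpha for r in res.cefs)
    return {
        "n_replicates": n_replicates,
        "any_cef_fraction": any_cef / n_replicates,
        "bsn_rate": bsn_hits / node_tests_total,
        "n_node_tests": node_tests_total,
    }


def focal_gene_study(
    n_replicates: int = 50,
    seed: int = 0,
    min_tips: int = 5,
    min_encoder_fraction: float = 0.25,
    target_group: str = "group2",
    pseudocount: float = 1.0,
    multiplier: float = 1.5,
    bh_alpha: float = 0.05,
    **community_kwargs,
) -> dict:
    """Focal-gene recovery versus the matched random-taxa control.

    Per replicate: pick a focal function encoded by at least
    ``min_encoder_fraction`` of taxa, inflate its encoders in the target
    group, run the CEF workflow and record the focal function's rank among
    significant functions; then perturb an equally sized uniform taxon set
    and record the proportion of significant functions under that control.
    The focal median rank is computed over replicates where the focal
    function was detected (mirroring the convention of dropping undetected
    cases from rank plots).
    """
    from . import cef as _cef

    rng = np.random.default_rng(seed)
    child = rng.integers(2**31 - 1, size=n_replicates)
    ranks, props_focal, props_random = [], [], []
    detected = 0
    for i in range(n_replicates):
        rep_seed = int(child[i])
        com = generate_community(seed=rep_seed, **community_kwargs)
        n_taxa = com.taxa_table.shape[0]
        enc = (com.function_table > 0).sum(axis=0)
        eligible = list(enc.index[enc >= min_encoder_fraction * n_taxa])
        rep_rng = np.random.default_rng(rep_seed + 1)
        focal = eligible[rep_rng.integers(len(eligible))]

        table, rec = perturb_focal_gene(
            com, focal, target_group, pseudocount, multiplier
        )
        res = _cef.run_poms(
            com.phylogeny, table, com.function_table, com.design,
            min_tips=min_tips, bh_alpha=bh_alpha,
        )
        rank = focal_gene_ranking(res.cefs, focal, bh_alpha)
        if rank is not None:
            ranks.append(rank)
            detected += 1
        props_focal.append(np.mean([r.bh_p < bh_alpha for r in res.cefs]))

        rtable, _ = perturb_random_taxa(
            com, len(rec.perturbed_taxa), target_group, pseudocount, multiplier,
            seed=rep_seed + 2,
        )
        rres = _cef.run_poms(
            com.phylogeny, rtable, com.function_table, com.design,
            min_tips=min_tips, bh_alpha=bh_alpha,
        )
        props_random.append(np.mean([r.bh_p < bh_alpha for r in rres.cefs]))
    mean_focal = float(np.mean(props_focal))
    mean_random = float(np.mean(props_random))
    return {
        "n_replicates": n_replicates,
        "median_focal_rank": float(np.median(ranks)) if ranks else None,
        "detection_fraction": detected / n_replicates,
        "mean_prop_significant_focal": mean_focal,
        "mean_prop_significant_random": mean_random,
        "focal_to_random_ratio": (
            math.inf if mean_random == 0 else mean_focal / mean_random
        ),
    }


def _sig_and_p(record, alpha):
    # duck-typed over CefRecord / RegressionResult
    bh = getattr(record, "bh_p")
    p = getattr(record, "p_value")
    sig = (not math.isnan(bh)) and bh < alpha
    return sig, p


def focal_gene_ranking(results, focal_function: str, alpha: float = 0.05):
    """1-based rank of the focal function among significant results, by raw p.

    Ties share the mean rank.  Returns ``None`` if the focal function is not
    significant at BH < alpha; raises ``KeyError`` if it is absent entirely.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    ids = [r.function_id for r in results]
    if focal_function not in ids:
        raise KeyError(f"focal function {focal_function!r} not among results")
    sig = [(r.function_id, p) for r in results for s, p in [_sig_and_p(r, alpha)] if s]
    sig_ids = [fid for fid, _ in sig]
    if focal_function not in sig_ids:
        return None
    ranks = rankdata([p for _, p in sig], method="average")
    return float(ranks[sig_ids.index(focal_function)])
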