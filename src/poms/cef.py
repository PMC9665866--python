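"""Consistently enriched functions (CEFs): the headline balance-tree output.

For each function, its significant FSNs are partitioned into three classes:

1. FSNs at nodes that are not (directional) BSNs;
2. FSNs at BSNs where the function-enriched side is the side whose taxa are
   relatively higher in sample group 1;
3. the analogous class for group 2.

Under the mass-action null — FSNs landing on nodes independently of BSNs —
the expected class proportions are ((T - B)/T, B/2T, B/2T) where T is the
number of tested nodes and B the number of directional BSNs (intersections
split evenly between the two directions).  An exact multinomial
goodness-of-fit test (log-likelihood-ratio ordering over the full outcome
enumeration) per function, followed by Benjamini–Hochberg correction across
functions, yields the CEF table.  A significant function whose intersecting
FSNs all point to one group is consistently enriched toward that group; a
significant function with intersections toward both groups is flagged
"mixed" and needs post-hoc inspection of the class counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import balances as _balances
from . import node_tests as _node_tests
from .phylo_core import Phylogeny
from .tables import SampleDesign, filter_tables

logger = logging.getLogger("poms")

__all__ = [
    "FsnClassCounts",
    "CefRecord",
    "PomsResult",
    "null_probabilities",
    "classify_fsns",
    "multinomial_exact_test",
    "run_poms",
]


@dataclass(frozen=True)
class FsnClassCounts:
    """Three-class FSN counts for one function."""

    function_id: str
    n_nonintersecting: int
    n_group1: int
    n_group2: int

    @property
    def total(self) -> int:
        return self.n_nonintersecting + self.n_group1 + self.n_group2

    def as_array(self) -> np.ndarray:
        return np.array([self.n_nonintersecting, self.n_group1, self.n_group2])


@dataclass(frozen=True)
class CefRecord:
    """Per-function multinomial-test outcome."""

    function_id: str
    counts: FsnClassCounts
    null_probs: tuple
    p_value: float
    bh_p: float
    direction_summary: str


@dataclass
class PomsResult:
    """Full output of one balance-tree run (CEF records plus provenance)."""

    cefs: list
    bsns: list
    fsns: list
    balances: pd.DataFrame
    partitions: list
    group1_label: str
    group2_label: str

    @property
    def n_tested_nodes(self) -> int:
        return len(self.partitions)

    @property
    def n_bsns(self) -> int:
        return sum(1 for b in self.bsns if b.is_significant and b.direction)

    def cef_table(self) -> pd.DataFrame:
        """CEF summary mirroring the published table layout."""
        rows = []
        for r in self.cefs:
            rows.append(
                {
                    "function": r.function_id,
                    "total_fsns": r.counts.total,
                    f"fsns_x_bsns_{self.group1_label}": r.counts.n_group1,
                    f"fsns_x_bsns_{self.group2_label}": r.counts.n_group2,
                    "fsns_not_x_bsns": r.counts.n_nonintersecting,
                    "raw_p": r.p_value,
                    "corrected_p": r.bh_p,
                    "direction": r.direction_summary,
                }
            )
        return pd.DataFrame(rows).set_index("function")


def null_probabilities(n_tested_nodes: int, n_bsn: int) -> np.ndarray:
    """Mass-action null class probabilities (non-intersecting, group1, group2)."""
    if n_tested_nodes < 1:
        raise ValueError("n_tested_nodes must be >= 1")
    if not 0 <= n_bsn <= n_tested_nodes:
        raise ValueError("need 0 <= n_bsn <= n_tested_nodes")
    q = n_bsn / n_tested_nodes
    return np.array([1.0 - q, q / 2.0, q / 2.0])


def classify_fsns(fsns, bsns, group1_side_of=None) -> dict:
    """Partition each function's significant FSNs into the three classes.

    ``bsns`` supplies, per node, whether it is a directional BSN and which
    side is the group1-higher side.  Non-directional significant BSNs (tied
    medians) count as non-BSN nodes.  Returns function_id -> FsnClassCounts.
    """
    direction_of = {}
    for b in bsns:
        if b.is_significant and b.direction in ("lhs", "rhs"):
            direction_of[b.node_id] = b.direction
    if group1_side_of:
        direction_of.update(group1_side_of)

    tallies = {}
    for f in fsns:
        if f.function_id not in tallies:
            tallies[f.function_id] = [0, 0, 0]
        if not f.is_significant:
            continue
        side = direction_of.get(f.node_id)
        if side is None:
            tallies[f.function_id][0] += 1
        elif f.enriched_side == side:
            tallies[f.function_id][1] += 1
        else:
            tallies[f.function_id][2] += 1
    return {
        fid: FsnClassCounts(fid, *counts) for fid, counts in tallies.items()
    }


def _llr(counts: np.ndarray, probs: np.ndarray) -> float:
    """G = 2 * sum k_i * ln(k_i / (n p_i)), with 0 * ln(0) = 0."""
    n = counts.sum()
    mask = counts > 0
    return float(2.0 * (counts[mask] * np.log(counts[mask] / (n * probs[mask]))).sum())


def multinomial_exact_test(counts, probs) -> float:
    """Exact multinomial goodness-of-fit p-value, LLR-ordered.

    Enumerates all outcomes (k1, k2, k3) with k1+k2+k3 = n and sums the
    multinomial probabilities of outcomes whose log-likelihood-ratio
    statistic is at least the observed one (ties included, relative
    tolerance 1e-9).
    """
    counts = np.asarray(counts, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != (3,) or probs.shape != (3,):
        raise ValueError("counts and probs must be length-3 vectors")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be non-negative and sum to 1")
    if ((probs == 0) & (counts > 0)).any():
        raise ValueError("observed count in a zero-probability category")
    n = int(counts.sum())
    if n == 0:
        return 1.0

    # Full outcome enumeration: C(n+2, 2) triples.
    k1, k2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = (k1 + k2) <= n
    k1, k2 = k1[keep], k2[keep]
    k3 = n - k1 - k2
    ks = np.stack([k1, k2, k3], axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(probs > 0, np.log(probs), -np.inf)
        log_pmf = (
            gammaln(n + 1)
            - gammaln(ks + 1).sum(axis=1)
            + np.where(ks > 0, ks * logp, 0.0).sum(axis=1)
        )
        g = 2.0 * np.where(
            ks > 0, ks * (np.log(np.where(ks > 0, ks, 1)) - math.log(n) - logp), 0.0
        ).sum(axis=1)

    g_obs = _llr(counts, probs)
    include = g >= g_obs - 1e-9 * max(1.0, abs(g_obs))
    return float(min(1.0, np.exp(log_pmf[include]).sum()))


def _direction_summary(c: FsnClassCounts, g1: str, g2: str) -> str:
    if c.n_group1 > 0 and c.n_group2 == 0:
        return f"{g1}-consistent"
    if c.n_group2 > 0 and c.n_group1 == 0:
        return f"{g2}-consistent"
    return "mixed"


def run_poms(
    tree: Phylogeny,
    taxa_table: pd.DataFrame,
    function_table: pd.DataFrame,
    design: SampleDesign,
    min_tips: int = 10,
    pseudocount: float = 1.0,
    node_alpha: float = 0.05,
    bh_alpha: float = 0.05,
    filter_inputs: bool = True,
    min_encoding_taxa: int = 5,
    min_encoding_fraction: float = 0.001,
    user_bsns=None,
) -> PomsResult:
    """The full balance-tree workflow.

    Stages: pre-filter tables -> shear tree to surviving taxa -> select
    testable nodes -> per-sample balances -> BSNs (Wilcoxon / Spearman /
    user-supplied) -> FSNs at all testable nodes -> three-class counts ->
    exact multinomial p per function -> BH across functions.

    Every tested function receives a record (functions with no significant
    FSNs get p = 1), so the BH family size equals the number of tested
    functions.  Records are sorted by corrected, then raw, p-value.
    """
    design.validate_against(taxa_table.columns)
    if filter_inputs:
        taxa_table, function_table = filter_tables(
            taxa_table, function_table, min_encoding_taxa, min_encoding_fraction
        )
    shared = [t for t in taxa_table.index if t in set(tree.tips)]
    if len(shared) < taxa_table.shape[0]:
        raise ValueError("taxa table contains taxa absent from the tree")
    if len(shared) < tree.n_tips:
        tree = tree.shear(shared)
    taxa_table = taxa_table.loc[list(tree.tips)]
    function_table = function_table.loc[taxa_table.index]

    partitions = tree.testable_nodes(min_tips)
    if not partitions:
        raise ValueError(f"no testable nodes with min_tips={min_tips}")
    logger.info("run_poms: %d testable nodes (min_tips=%d)", len(partitions), min_tips)

    bal = _balances.balance_matrix(taxa_table, partitions, pseudocount)

    if user_bsns is not None:
        bsns = list(user_bsns)
        g1, g2 = "group1", "group2"
        if design.mode == "two_group":
            g1, g2 = design.group1, design.group2
    elif design.mode == "two_group":
        bsns = _node_tests.bsn_two_group(bal, design, node_alpha)
        g1, g2 = design.group1, design.group2
    else:
        bsns = _node_tests.bsn_continuous(bal, design.covariate, node_alpha)
        g1, g2 = "high", "low"

    n_bsn = sum(1 for b in bsns if b.is_significant and b.direction)
    if n_bsn == 0:
        logger.warning(
            "run_poms: zero directional BSNs; all multinomial tests degenerate to p=1"
        )
    logger.info("run_poms: %d directional BSNs of %d tested nodes", n_bsn, len(partitions))

    fsns = _node_tests.fsn_all_nodes(partitions, function_table, node_alpha)
    counts_by_fn = classify_fsns(fsns, bsns)
    probs = null_probabilities(len(partitions), n_bsn)

    function_ids = list(function_table.columns)
    raw_p = np.empty(len(function_ids))
    for i, fid in enumerate(function_ids):
        c = counts_by_fn[fid]
        raw_p[i] = multinomial_exact_test(c.as_array(), probs)
    bh_p = multipletests(raw_p, method="fdr_bh")[1]

    records = [
        CefRecord(
            fid,
            counts_by_fn[fid],
            tuple(probs),
            float(raw_p[i]),
            float(bh_p[i]),
            _direction_summary(counts_by_fn[fid], g1, g2),
        )
        for i, fid in enumerate(function_ids)
    ]
    records.sort(key=lambda r: (r.bh_p, r.p_value, r.function_id))
    n_sig = sum(1 for r in records if r.bh_p < bh_alpha)
    logger.info("run_poms: %d CEFs at BH < %g", n_sig, bh_alpha)
    return PomsResult(records, bsns, fsns, bal, partitions, g1, g2)
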