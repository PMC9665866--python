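"""Node-level statistics: balance-significant and function-significant nodes.

A *balance-significant node* (BSN) is a testable node whose per-sample
balances differ between the two sample groups (Wilcoxon rank-sum test) or
correlate with a continuous covariate (Spearman).  Each significant BSN
carries a direction: the side of the node whose taxa are at relatively higher
levels in group 1 (or positively associated with the covariate).

A *function-significant node* (FSN) is a testable node where the proportion
of tips encoding a given function differs between the two sides (two-sided
Fisher's exact test on the encode/not-encode x left/right contingency table).
FSNs are computed at *all* testable nodes, not just at BSNs — the downstream
multinomial test needs the full FSN set.

Node-level p-values are deliberately left uncorrected (default alpha 0.05);
multiple-testing control happens across functions, not across nodes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_core import NodePartition
from .tables import SampleDesign, TableError

logger = logging.getLogger("poms")

__all__ = [
    "BsnResult",
    "FsnResult",
    "bsn_two_group",
    "bsn_continuous",
    "bsn_user",
    "fsn_test",
    "fsn_all_nodes",
    "fisher_exact_two_sided",
]


@dataclass(frozen=True)
class BsnResult:
    """Outcome of the balance test at one node.

    ``direction`` is the side ('lhs' or 'rhs') whose taxa are relatively more
    abundant in group 1 (two-group mode) or positively associated with the
    covariate (continuous mode); ``None`` when not significant or when the
    direction is tied (a tied node is excluded from CEF intersections).
    """

    node_id: str
    p_value: float
    is_significant: bool
    direction: Optional[str]
    test_used: str
    statistic: float = float("nan")


@dataclass(frozen=True)
class FsnResult:
    """Outcome of the function-enrichment test at one node.

    ``table`` holds ((encode_lhs, not_lhs), (encode_rhs, not_rhs)).
    ``enriched_side`` is the side with the greater encoding proportion, and is
    only meaningful when significant.
    """

    node_id: str
    function_id: str
    p_value: float
    is_significant: bool
    enriched_side: Optional[str]
    table: tuple


# ---------------------------------------------------------------------------
# Balance-significant nodes
# ---------------------------------------------------------------------------


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 25 and len(y) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bsn_two_group(balances: pd.DataFrame, design: SampleDesign, alpha: float = 0.05) -> list:
    """Wilcoxon rank-sum BSN test at every node of a balance matrix."""
    if design.mode != "two_group":
        raise TableError("bsn_two_group requires a two-group design")
    design.validate_against(balances.columns)
    s1 = [s for s in balances.columns if design.groups[s] == design.group1]
    s2 = [s for s in balances.columns if design.groups[s] == design.group2]
    if len(s1) < 2 or len(s2) < 2:
        raise TableError("each group needs >= 2 samples among the balance columns")
    b1 = balances[s1].to_numpy()
    b2 = balances[s2].to_numpy()
    results = []
    for i, node_id in enumerate(balances.index):
        p = _wilcoxon_p(b1[i], b2[i])
        sig = p < alpha
        direction = None
        if sig:
            diff = np.median(b1[i]) - np.median(b2[i])
            if diff > 0:
                direction = "lhs"  # lhs/rhs ratio higher in group1 => lhs up
            elif diff < 0:
                direction = "rhs"
            else:
                logger.info(
                    "node %s: significant balance shift but tied group medians; "
                    "treated as non-directional",
                    node_id,
                )
        results.append(BsnResult(node_id, p, sig, direction, "wilcoxon"))
    return results


@lru_cache(maxsize=16)
def _spearman_null_rhos(n: int) -> np.ndarray:
    """|rho| values over all n! rank permutations (tie-free exact null)."""
    base = np.arange(n)
    d = n * (n * n - 1)
    rhos = np.fromiter(
        (1.0 - 6.0 * float(((np.array(p) - base) ** 2).sum()) / d
         for p in itertools.permutations(range(n))),
        dtype=float,
    )
    return np.abs(rhos)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple:
    """(rho, two-sided p); exact permutation null when n <= 9 and tie-free."""
    n = len(x)
    rho, p = stats.spearmanr(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and tie_free:
        null = _spearman_null_rhos(n)
        p = float((null >= abs(rho) - 1e-12).mean())
    return float(rho), float(p)


def bsn_continuous(balances: pd.DataFrame, covariate: pd.Series, alpha: float = 0.05) -> list:
    """Spearman-correlation BSN test against a continuous covariate."""
    cov = covariate.reindex(balances.columns).astype(float)
    if cov.isna().any():
        raise TableError("covariate missing for some balance-matrix samples")
    if cov.nunique() < 4:
        raise TableError("continuous covariate needs >= 4 distinct values")
    x = cov.to_numpy()
    results = []
    for node_id in balances.index:
        rho, p = _spearman(x, balances.loc[node_id].to_numpy())
        sig = (not math.isnan(p)) and p < alpha
        direction = None
        if sig and rho != 0:
            # positive rho: lhs/rhs ratio rises with the covariate => lhs "high"
            direction = "lhs" if rho > 0 else "rhs"
        results.append(BsnResult(node_id, p, sig, direction, "spearman", statistic=rho))
    return results


def bsn_user(testable_node_ids, significance_flags, directions) -> list:
    """Wrap an external, user-defined node test into BSN records.

    ``significance_flags`` maps node_id -> bool for a subset of the testable
    nodes; ``directions`` must supply 'lhs'/'rhs' for every flagged node.
    Unflagged testable nodes are recorded as non-significant.
    """
    testable = list(testable_node_ids)
    known = set(testable)
    for nid in significance_flags:
        if nid not in known:
            raise KeyError(f"node {nid!r} is not among the testable nodes")
    results = []
    for nid in testable:
        sig = bool(significance_flags.get(nid, False))
        direction = None
        if sig:
            direction = directions.get(nid)
            if direction not in ("lhs", "rhs"):
                raise ValueError(f"significant node {nid!r} needs a direction 'lhs' or 'rhs'")
        results.append(BsnResult(nid, float("nan"), sig, direction, "user"))
    return results


# ---------------------------------------------------------------------------
# Function-significant nodes
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200000)
def _hypergeom_pmf(N: int, K: int, n: int) -> tuple:
    """(kmin, pmf over the support) for the hypergeometric(N, K, n)."""
    kmin = max(0, n - (N - K))
    kmax = min(n, K)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, N, K, n)
    pmf.flags.writeable = False
    return kmin, pmf


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Minimum-likelihood convention: sum of probabilities of all tables with the
    observed margins whose point probability does not exceed the observed
    one (relative tolerance 1e-7, matching the scipy implementation).
    Computed from a cached hypergeometric pmf so that sweeping many functions
    over the same node margins is cheap.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    N = a + b + c + d
    kmin, pmf = _hypergeom_pmf(N, a + c, a + b)
    p_obs = pmf[a - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fsn_test(partition: NodePartition, function_column, alpha: float = 0.05) -> FsnResult:
    """Fisher's exact test for side-wise enrichment of one function at one node.

    ``function_column`` maps taxon -> copy number; a taxon encodes the
    function iff its copy number is > 0.
    """
    enc_l = sum(1 for t in partition.lhs_tips if float(function_column[t]) > 0)
    enc_r = sum(1 for t in partition.rhs_tips if float(function_column[t]) > 0)
    return _fsn_from_counts(
        partition.node_id,
        getattr(function_column, "name", None) or "function",
        enc_l,
        partition.n_lhs,
        enc_r,
        partition.n_rhs,
        alpha,
    )


def _fsn_from_counts(node_id, function_id, enc_l, n_l, enc_r, n_r, alpha) -> FsnResult:
    a, b = enc_l, n_l - enc_l
    c, d = enc_r, n_r - enc_r
    p = fisher_exact_two_sided(a, b, c, d)
    sig = p < alpha
    frac_l, frac_r = enc_l / n_l, enc_r / n_r
    if frac_l > frac_r:
        side = "lhs"
    elif frac_r > frac_l:
        side = "rhs"
    else:
        side = None
    return FsnResult(node_id, function_id, p, sig, side, ((a, b), (c, d)))


def fsn_all_nodes(partitions, function_table: pd.DataFrame, alpha: float = 0.05) -> list:
    """FSN tests for every (testable node, function) pair.

    Vectorises the encoder counting; returns a flat list of
    :class:`FsnResult` ordered by node, then function.
    """
    partitions = list(partitions)
    encodes = (function_table.to_numpy() > 0)
    row = {t: i for i, t in enumerate(function_table.index)}
    results = []
    for p in partitions:
        li = [row[t] for t in p.lhs_tips]
        ri = [row[t] for t in p.rhs_tips]
        enc_l = encodes[li].sum(axis=0)
        enc_r = encodes[ri].sum(axis=0)
        for j, fid in enumerate(function_table.columns):
            results.append(
                _fsn_from_counts(
                    p.node_id, fid, int(enc_l[j]), p.n_lhs, int(enc_r[j]), p.n_rhs, alpha
                )
            )
    return results


def bsn_table(bsns) -> pd.DataFrame:
    """Per-node BSN summary as a DataFrame (TSV-exportable)."""
    return pd.DataFrame(
        {
            "node": [b.node_id for b in bsns],
            "p_value": [b.p_value for b in bsns],
            "significant": [b.is_significant for b in bsns],
            "direction": [b.direction if b.direction else "" for b in bsns],
            "test": [b.test_used for b in bsns],
        }
    ).set_index("node")


def fsn_table(fsns) -> pd.DataFrame:
    """Long-format FSN summary as a DataFrame (TSV-exportable)."""
    return pd.DataFrame(
        {
            "node": [f.node_id for f in fsns],
            "function": [f.function_id for f in fsns],
            "p_value": [f.p_value for f in fsns],
            "significant": [f.is_significant for f in fsns],
            "enriched_side": [f.enriched_side if f.enriched_side else "" for f in fsns],
        }
    )
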