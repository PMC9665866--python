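"""Per-node, per-sample isometric log-ratio (ILR) balances.

At an internal node *i* splitting the tips into a left set (size ``n_L``) and
a right set (size ``n_R``), the balance of a sample is

    b_i = sqrt(n_L * n_R / (n_L + n_R)) * ln( g(y_L) / g(y_R) )

where ``g`` is the geometric mean of the taxon abundances on each side.  The
square-root coefficient gives the coordinate unit length so balances are
comparable across nodes with different tip counts.  Because a single zero
abundance annihilates a geometric mean, a pseudocount (default 1) is added to
every taxon abundance before the log-ratio is taken.

Balances are scale-invariant: with a pseudocount of 0 and strictly positive
abundances, rescaling a sample's abundances by any constant leaves its
balances unchanged, which is what makes them a sound coordinate system for
compositional data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["geometric_mean", "node_balance", "balance_matrix", "BalanceError"]


class BalanceError(ValueError):
    """Raised when a balance is undefined (zero geometric mean, no pseudocount)."""


def geometric_mean(values) -> float:
    """Geometric mean of non-negative reals; 0 if any value is 0."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean of empty input")
    if (arr < 0).any():
        raise ValueError("geometric_mean requires non-negative values")
    if (arr == 0).any():
        return 0.0
    return float(math.exp(np.log(arr).mean()))


def _coefficient(n_lhs: int, n_rhs: int) -> float:
    return math.sqrt(n_lhs * n_rhs / (n_lhs + n_rhs))


def node_balance(partition, sample_abundances, pseudocount: float = 1.0) -> float:
    """ILR balance of one sample at one node.

    ``sample_abundances`` maps taxon label -> abundance (a mapping or
    ``pandas.Series``) and must cover every tip of the partition.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lhs = [float(sample_abundances[t]) + pseudocount for t in sorted(partition.lhs_tips)]
    rhs = [float(sample_abundances[t]) + pseudocount for t in sorted(partition.rhs_tips)]
    g_l = geometric_mean(lhs)
    g_r = geometric_mean(rhs)
    if g_l == 0.0 or g_r == 0.0:
        raise BalanceError(
            f"node {partition.node_id}: zero geometric mean with pseudocount "
            f"{pseudocount}; use a positive pseudocount"
        )
    return _coefficient(partition.n_lhs, partition.n_rhs) * math.log(g_l / g_r)


def balance_matrix(
    taxa_table: pd.DataFrame, partitions, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Balances at every partition (rows) for every sample (columns).

    Vectorised equivalent of calling :func:`node_balance` per cell.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    partitions = list(partitions)
    needed = set().union(*(p.lhs_tips | p.rhs_tips for p in partitions)) if partitions else set()
    missing = needed - set(taxa_table.index)
    if missing:
        raise KeyError(f"taxa table lacks partition tips: {sorted(missing)[:5]}")

    values = taxa_table.to_numpy(dtype=float) + pseudocount
    if (values <= 0).any():
        bad = taxa_table.index[(values <= 0).any(axis=1)][:3]
        raise BalanceError(
            f"zero abundances with pseudocount {pseudocount} (e.g. taxa {list(bad)}); "
            "balances undefined"
        )
    logs = np.log(values)
    row = {t: i for i, t in enumerate(taxa_table.index)}
    out = np.empty((len(partitions), taxa_table.shape[1]))
    for i, p in enumerate(partitions):
        li = [row[t] for t in p.lhs_tips]
        ri = [row[t] for t in p.rhs_tips]
        out[i] = _coefficient(p.n_lhs, p.n_rhs) * (
            logs[li].mean(axis=0) - logs[ri].mean(axis=0)
        )
    return pd.DataFrame(out, index=[p.node_id for p in partitions], columns=taxa_table.columns)
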