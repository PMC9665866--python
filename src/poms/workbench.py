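"""Orchestration: run configuration, summary reporting, method comparison.

Glue between the statistical modules and the command line: a validated
:class:`RunConfig` that can be echoed to JSON for bit-for-bit reproduction,
per-hit summaries (encoding-taxa counts and Faith's PD of the encoding set),
and a cross-method overlap report between the balance-tree and
phylogenetic-regression outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy.stats import rankdata

from .cef import CefRecord, PomsResult
from .phylo_core import Phylogeny
from .phyloreg import RegressionResult

logger = logging.getLogger("poms")

__all__ = ["RunConfig", "summarize_hits", "compare_methods", "write_config_echo"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a balance-tree / regression run."""

    min_tips: int = 10
    pseudocount: float = 1.0
    node_alpha: float = 0.05
    bh_alpha: float = 0.05
    mode: str = "two_group"  # two_group | continuous
    seed: int = 0
    min_encoding_taxa: int = 5
    min_encoding_fraction: float = 0.001
    filter_inputs: bool = True
    paths: Optional[dict] = None

    def __post_init__(self):
        if self.min_tips < 1:
            raise ValueError("min_tips must be >= 1")
        for name in ("node_alpha", "bh_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.mode not in ("two_group", "continuous"):
            raise ValueError("mode must be 'two_group' or 'continuous'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def write_config_echo(config: RunConfig, path) -> None:
    """Machine-readable echo of the run configuration."""
    with open(path, "w") as fh:
        fh.write(config.to_json() + "\n")


def _significant(results, bh_alpha):
    out = []
    for r in results:
        bh = r.bh_p
        if not math.isnan(bh) and bh < bh_alpha:
            out.append(r)
    return out


def summarize_hits(
    results,
    function_table: pd.DataFrame,
    tree: Phylogeny,
    bh_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per significant function: encoding-taxa count, Faith's PD, key statistics.

    Faith's PD of the encoding-taxa set quantifies how phylogenetically broad
    the support for the hit is — consistently enriched functions are expected
    to be encoded across independent lineages, hence high PD.
    """
    rows = []
    tree_tips = set(tree.tips)
    for r in _significant(results, bh_alpha):
        col = function_table[r.function_id]
        encoders = [t for t in col.index[col > 0] if t in tree_tips]
        pd_value = tree.faith_pd(encoders) if encoders else 0.0
        row = {
            "function": r.function_id,
            "n_encoding_taxa": len(encoders),
            "faith_pd": pd_value,
            "corrected_p": r.bh_p,
        }
        if isinstance(r, CefRecord):
            row.update(
                total_fsns=r.counts.total,
                fsns_group1=r.counts.n_group1,
                fsns_group2=r.counts.n_group2,
                fsns_nonintersecting=r.counts.n_nonintersecting,
                direction=r.direction_summary,
            )
        elif isinstance(r, RegressionResult):
            row.update(slope=r.slope, t=r.t_statistic)
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["function", "n_encoding_taxa", "faith_pd", "corrected_p"]
        ).set_index("function")
    return pd.DataFrame(rows).set_index("function")


def compare_methods(poms_results, phyloreg_results, bh_alpha: float = 0.05) -> dict:
    """Overlap report between balance-tree CEFs and regression hits.

    Returns counts of shared/unique significant functions, plus the rank of
    each CEF within the regression ordering (ascending raw p, mean rank on
    ties).
    """
    if isinstance(poms_results, PomsResult):
        poms_results = poms_results.cefs
    poms_ids = {r.function_id for r in poms_results}
    reg_ids = {r.function_id for r in phyloreg_results}
    if poms_ids != reg_ids:
        raise ValueError("the two methods tested different function sets")

    poms_sig = {r.function_id for r in _significant(poms_results, bh_alpha)}
    reg_sig = {r.function_id for r in _significant(phyloreg_results, bh_alpha)}

    reg_sorted = sorted(
        phyloreg_results,
        key=lambda r: (math.isnan(r.p_value), r.p_value if not math.isnan(r.p_value) else 1.0),
    )
    reg_ranks = rankdata(
        [r.p_value if not math.isnan(r.p_value) else 1.0 for r in reg_sorted],
        method="average",
    )
    rank_of = {r.function_id: float(reg_ranks[i]) for i, r in enumerate(reg_sorted)}

    return {
        "n_functions": len(poms_ids),
        "n_poms_significant": len(poms_sig),
        "n_phyloreg_significant": len(reg_sig),
        "n_shared": len(poms_sig & reg_sig),
        "poms_only": sorted(poms_sig - reg_sig),
        "phyloreg_only": sorted(reg_sig - poms_sig),
        "cef_rank_in_phyloreg": {fid: rank_of[fid] for fid in sorted(poms_sig)},
    }
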