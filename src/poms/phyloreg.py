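"""Phylogenetic regression of per-taxon responses on function copy numbers.

Fits the Brownian-motion phylogenetic linear model

    y ~ N(X beta, sigma^2 C),   X = [1, copy_number]

per function, where C is the shared root-to-MRCA path-length matrix of the
tree.  Generalised least squares is solved through Cholesky factors of C (no
explicit inversion); sigma^2 is the maximum-likelihood estimate RSS/n and the
slope is tested with a t statistic on n - 2 degrees of freedom.  On a star
tree C is diagonal and the fit reduces to (weighted) ordinary least squares.

Response constructions mirror the phylogenize-style per-taxon summaries:

* significance indicator — 1 if the taxon's relative abundance differs
  between groups (Wilcoxon, uncorrected p < alpha), or correlates with a
  continuous covariate (Spearman), else 0;
* prevalence — fraction of a group's samples in which the taxon is present;
* specificity — log-ratio of the taxon's mean relative abundance within the
  group to its overall mean, with an epsilon guard (a simple group-affinity
  score standing in for the upstream definition; see docs/methods.md).

Binary responses are deliberately fit with the Gaussian model, mirroring the
common practice of passing an indicator to a linear phylogenetic model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from statsmodels.stats.multitest import multipletests

from .node_tests import _spearman, _wilcoxon_p
from .phylo_core import BrownianCovariance, Phylogeny
from .tables import SampleDesign, TableError, filter_tables

logger = logging.getLogger("poms")

__all__ = [
    "RegressionResult",
    "significance_indicator_response",
    "prevalence_response",
    "specificity_response",
    "phylo_lm",
    "run_phyloreg",
]


@dataclass(frozen=True)
class RegressionResult:
    function_id: str
    intercept: float
    slope: float
    slope_se: float
    t_statistic: float
    p_value: float
    bh_p: float
    sigma2: float


def _relative_abundance(taxa_table: pd.DataFrame) -> pd.DataFrame:
    totals = taxa_table.sum(axis=0)
    if (totals == 0).any():
        raise TableError("cannot form relative abundances: some samples sum to 0")
    return taxa_table / totals


def significance_indicator_response(
    taxa_table: pd.DataFrame, design: SampleDesign, alpha: float = 0.05
) -> pd.Series:
    """Binary per-taxon indicator of differential relative abundance."""
    design.validate_against(taxa_table.columns)
    rel = _relative_abundance(taxa_table)
    out = pd.Series(0.0, index=taxa_table.index, name="significance_indicator")
    if design.mode == "two_group":
        s1 = [s for s in rel.columns if design.groups[s] == design.group1]
        s2 = [s for s in rel.columns if design.groups[s] == design.group2]
        if len(s1) < 2 or len(s2) < 2:
            raise TableError("each group needs >= 2 samples")
        a1, a2 = rel[s1].to_numpy(), rel[s2].to_numpy()
        for i, taxon in enumerate(rel.index):
            if np.ptp(np.concatenate([a1[i], a2[i]])) == 0:
                continue  # constant: no test needed, never significant
            if _wilcoxon_p(a1[i], a2[i]) < alpha:
                out[taxon] = 1.0
    else:
        x = design.covariate.reindex(rel.columns).to_numpy()
        for i, taxon in enumerate(rel.index):
            _, p = _spearman(x, rel.iloc[i].to_numpy())
            if not math.isnan(p) and p < alpha:
                out[taxon] = 1.0
    return out


def prevalence_response(taxa_table: pd.DataFrame, design: SampleDesign, group) -> pd.Series:
    """Fraction of the group's samples in which each taxon is present (>0)."""
    samples = design.samples_in(group)
    if not samples:
        raise TableError(f"group {group!r} has no samples")
    sub = taxa_table[samples]
    return ((sub > 0).sum(axis=1) / len(samples)).rename("prevalence")


def specificity_response(
    taxa_table: pd.DataFrame, design: SampleDesign, group, epsilon: float = None
) -> pd.Series:
    """Group-affinity score: log((mean rel. abund. in group + eps) / (overall + eps))."""
    samples = design.samples_in(group)
    if not samples:
        raise TableError(f"group {group!r} has no samples")
    rel = _relative_abundance(taxa_table)
    if epsilon is None:
        nonzero = rel.to_numpy()[rel.to_numpy() > 0]
        epsilon = float(nonzero.min()) if nonzero.size else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    mean_in = rel[samples].mean(axis=1)
    mean_all = rel.mean(axis=1)
    return np.log((mean_in + epsilon) / (mean_all + epsilon)).rename("specificity")


def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; one shot of diagonal jitter for rank-deficient C."""
    n = C.shape[0]
    jitter = 1e-10 * np.trace(C) / n
    try:
        return cholesky(C, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    try:
        return cholesky(C + jitter * np.eye(n), lower=True)
    except Exception as exc:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite even after jitter: {exc}"
        ) from exc


def _gls_fit(function_id, zX: np.ndarray, zy: np.ndarray) -> RegressionResult:
    """OLS on Cholesky-whitened design; zX is n x 2, zy length n."""
    n = zX.shape[0]
    XtX = zX.T @ zX
    if np.linalg.matrix_rank(XtX) < 2:
        nan = float("nan")
        return RegressionResult(function_id, nan, nan, nan, nan, nan, nan, nan)
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (zX.T @ zy)
    resid = zy - zX @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if se == 0.0:
        t = 0.0 if beta[1] == 0 else math.copysign(math.inf, beta[1])
        p = 1.0 if beta[1] == 0 else 0.0
    else:
        t = float(beta[1] / se)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return RegressionResult(
        function_id, float(beta[0]), float(beta[1]), se, t, p, float("nan"), sigma2
    )


def phylo_lm(response: pd.Series, predictor: pd.Series, cov: BrownianCovariance) -> RegressionResult:
    """Brownian-motion GLS of one response on one copy-number column."""
    taxa = list(cov.taxa)
    if len(taxa) < 3:
        raise ValueError("phylo_lm needs >= 3 tips")
    y = response.reindex(taxa).to_numpy(dtype=float)
    x = predictor.reindex(taxa).to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("response/predictor missing for some covariance taxa")
    L = _chol_with_jitter(cov.matrix)
    X = np.column_stack([np.ones(len(taxa)), x])
    zX = solve_triangular(L, X, lower=True)
    zy = solve_triangular(L, y, lower=True)
    fid = getattr(predictor, "name", None) or "predictor"
    return _gls_fit(fid, zX, zy)


def run_phyloreg(
    tree: Phylogeny,
    taxa_table: pd.DataFrame,
    function_table: pd.DataFrame,
    design: SampleDesign,
    response_kind: str = "significance",
    response: pd.Series = None,
    group=None,
    alpha: float = 0.05,
    filter_inputs: bool = True,
    min_encoding_taxa: int = 5,
    min_encoding_fraction: float = 0.001,
) -> list:
    """Per-function phylogenetic regression with BH correction across functions.

    ``response_kind`` is one of ``significance``, ``prevalence``,
    ``specificity`` or ``user`` (supply ``response``).  Prevalence and
    specificity need a ``group`` (defaults to group 1 of the design).
    Returns :class:`RegressionResult` records sorted by corrected p.
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

    if response_kind == "user":
        if response is None:
            raise ValueError("response_kind='user' requires a response series")
        y = response
    elif response_kind == "significance":
        y = significance_indicator_response(taxa_table, design, alpha)
    elif response_kind in ("prevalence", "specificity"):
        g = group if group is not None else design.group1
        builder = prevalence_response if response_kind == "prevalence" else specificity_response
        y = builder(taxa_table, design, g)
    else:
        raise ValueError(f"unknown response_kind {response_kind!r}")

    cov = tree.brownian_covariance()
    taxa = list(cov.taxa)
    L = _chol_with_jitter(cov.matrix)
    yv = y.reindex(taxa).to_numpy(dtype=float)
    X0 = np.ones(len(taxa))
    Z = solve_triangular(
        L,
        np.column_stack([X0, yv, function_table.reindex(taxa).to_numpy(dtype=float)]),
        lower=True,
    )
    z1, zy, zF = Z[:, 0], Z[:, 1], Z[:, 2:]

    results = []
    for j, fid in enumerate(function_table.columns):
        results.append(_gls_fit(fid, np.column_stack([z1, zF[:, j]]), zy))

    raw = np.array([r.p_value for r in results])
    valid = ~np.isnan(raw)
    bh = np.full(len(raw), np.nan)
    if valid.any():
        bh[valid] = multipletests(raw[valid], method="fdr_bh")[1]
    results = [
        RegressionResult(
            r.function_id, r.intercept, r.slope, r.slope_se, r.t_statistic,
            r.p_value, float(bh[i]), r.sigma2,
        )
        for i, r in enumerate(results)
    ]
    results.sort(
        key=lambda r: (
            math.isnan(r.bh_p), r.bh_p if not math.isnan(r.bh_p) else 1.0,
            r.p_value if not math.isnan(r.p_value) else 1.0, r.function_id,
        )
    )
    n_sig = sum(1 for r in results if not math.isnan(r.bh_p) and r.bh_p < 0.05)
    logger.info("run_phyloreg: %d functions significant at BH < 0.05", n_sig)
    return results


def regression_table(results) -> pd.DataFrame:
    """Regression summary as a DataFrame (TSV-exportable)."""
    return pd.DataFrame(
        {
            "function": [r.function_id for r in results],
            "intercept": [r.intercept for r in results],
            "slope": [r.slope for r in results],
            "t": [r.t_statistic for r in results],
            "raw_p": [r.p_value for r in results],
            "corrected_p": [r.bh_p for r in results],
            "sigma2": [r.sigma2 for r in results],
        }
    ).set_index("function")
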