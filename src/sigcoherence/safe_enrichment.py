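"""Sample-permutation pathway enrichment (SAFE-style).

Per gene, a *local* statistic measures association between the factor and
the residuals of the reduced model (the longitudinal GAMM or the
age-adjusted linear model *without* the factor term). Per pathway, a
*global* statistic — a standardized Wilcoxon rank-sum of the local
statistics of member genes against the background — summarizes coherent
regulation. Significance comes from permuting the factor labels across
exchangeable units (children for child-level factors, samples otherwise)
and recomputing all global statistics; because the reduced model does not
involve the factor, its residuals are computed once and reused across
permutations. Sample permutation keeps the gene-gene correlation structure
intact, which protects the pathway test from false positives driven by
correlated transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import (
    GammDesign, SplineSpec, bh_adjust, fit_all_genes,
)
from .formats_io import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "LocalStats",
    "compute_local_stats",
    "global_rank_stat",
    "safe_test",
    "aggregate_node_effect",
]

#: factors that are properties of the child, not the sample; their labels
#: are permuted across children so all samples of a child move together
CHILD_LEVEL_FACTORS = {"cs", "gender", "maternal_diabetes", "multiple_fdr"}


@dataclass
class LocalStats:
    """Reduced-model residuals and the per-gene local statistics."""

    gene_ids: list[str]
    local_t: np.ndarray
    reduced_residuals: np.ndarray   # genes x samples, cached for permutation
    factor: np.ndarray              # aligned 0/1 labels
    child_ids: np.ndarray
    model: str


def two_sample_t(R: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t of every row of ``R`` vs binary labels.

    Rows with zero pooled variance get t = 0.
    """
    return two_sample_t_multi(R, np.asarray(labels, float)[:, None])[:, 0]


def two_sample_t_multi(R: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Two-sample t for every row of ``R`` against every label column of
    ``L`` (n_samples x B), vectorized as matrix products."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    L = np.asarray(L, dtype=float)
    n = R.shape[1]
    n1 = L.sum(axis=0)                       # (B,)
    n0 = n - n1
    tot = R.sum(axis=1, keepdims=True)       # (G,1)
    tot2 = (R ** 2).sum(axis=1, keepdims=True)
    s1 = R @ L                               # (G,B)
    s2 = (R ** 2) @ L
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    ss1 = s2 - n1 * m1 ** 2
    ss0 = (tot2 - s2) - n0 * m0 ** 2
    sp2 = (ss1 + ss0) / (n - 2)
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m0) / denom, 0.0)
    return t


def compute_local_stats(
    study: ExpressionStudy,
    factor_name: str,
    model: str = "gamm",
    spec: SplineSpec | None = None,
) -> LocalStats:
    """Residual-based local gene statistics for a binary factor.

    Fits the reduced model per gene (spline + child intercept for ``gamm``,
    intercept + age for ``linear`` — the factor term excluded either way),
    keeps the residual matrix, and returns the pooled two-sample t of each
    gene's residuals between the two factor groups.
    """
    if model not in ("gamm", "linear"):
        raise ValueError(f"unknown model {model!r}")
    study = study.drop_missing_factor(factor_name)
    x = study.factor_values(factor_name)
    ages = study.metadata["age_years"].to_numpy(dtype=float)
    child = study.metadata["child_id"].to_numpy()
    Y = study.values

    if model == "linear":
        X0 = np.column_stack([np.ones(len(ages)), ages])
        H = X0 @ np.linalg.pinv(X0)
        R = Y - Y @ H.T
    else:
        design = GammDesign(ages, child, None, spec)
        R = np.empty_like(Y)
        for i in range(Y.shape[0]):
            R[i] = design.fit(Y[i], keep_residuals=True).residuals
    local_t = two_sample_t(R, x)
    return LocalStats(list(study.gene_ids), local_t, R, x, child, model)


# ---------------------------------------------------------------------------
# global statistic


def _tie_term(sorted_vals: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of a sorted 1-D array."""
    if sorted_vals.size < 2:
        return 0.0
    eq = sorted_vals[1:] == sorted_vals[:-1]
    if not eq.any():
        return 0.0
    total = 0.0
    run = 1
    for e in eq:
        if e:
            run += 1
        else:
            if run > 1:
                total += run ** 3 - run
            run = 1
    if run > 1:
        total += run ** 3 - run
    return total


def _ranksum_z(ranks: np.ndarray, member_idx: np.ndarray,
               tie_term: float) -> float:
    """Standardized Wilcoxon rank-sum of member ranks vs the rest."""
    N = ranks.size
    n1 = member_idx.size
    n2 = N - n1
    W = float(ranks[member_idx].sum())
    mean = n1 * (N + 1) / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 0.0
    return (W - mean) / np.sqrt(var)


def global_rank_stat(
    local_t: np.ndarray, member_mask: np.ndarray, signed: bool = False
) -> float:
    """Standardized rank-sum of |local t| for member genes vs background.

    Mean 0 and unit variance under random assignment of gene labels, with
    mid-ranks and tie correction; positive values mean member genes carry
    systematically larger local statistics. ``signed=True`` ranks the raw
    t instead of its magnitude.
    """
    local_t = np.asarray(local_t, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    n1 = int(member_mask.sum())
    if n1 < 2 or local_t.size - n1 < 2:
        raise ValueError("need >= 2 member and >= 2 non-member genes")
    vals = local_t if signed else np.abs(local_t)
    ranks = stats.rankdata(vals)
    member_idx = np.flatnonzero(member_mask)
    return _ranksum_z(ranks, member_idx, _tie_term(np.sort(vals)))


def _global_stats_matrix(t_matrix: np.ndarray, member_lists: list[np.ndarray],
                         signed: bool) -> np.ndarray:
    """Standardized rank-sum z for every pathway (rows) under every label
    column of ``t_matrix`` (genes x B)."""
    vals = t_matrix if signed else np.abs(t_matrix)
    ranks = stats.rankdata(vals, axis=0)
    G, B = vals.shape
    # tie corrections are zero for continuous statistics; recompute only
    # for columns where ties actually occur
    srt = np.sort(vals, axis=0)
    has_ties = (srt[1:] == srt[:-1]).any(axis=0)
    tie = np.zeros(B)
    for b in np.flatnonzero(has_ties):
        tie[b] = _tie_term(srt[:, b])
    out = np.empty((len(member_lists), B))
    base_var = (np.asarray([len(m) for m in member_lists])[:, None]
                * (G - np.asarray([len(m) for m in member_lists]))[:, None]
                / 12.0)
    var = base_var * ((G + 1) - tie[None, :] / (G * (G - 1)))
    for s, idx in enumerate(member_lists):
        W = ranks[idx].sum(axis=0)
        mean = len(idx) * (G + 1) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            out[s] = np.where(var[s] > 0, (W - mean) / np.sqrt(var[s]), 0.0)
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def permute_labels(
    factor: np.ndarray,
    child_ids: np.ndarray,
    unit: str,
    B: int,
    seed: int,
) -> np.ndarray:
    """B permuted label columns (n_samples x B).

    ``unit="child"`` permutes the child-level labels across children, so all
    samples of a child keep a common label; ``unit="sample"`` permutes
    freely. Each permutation uses its own counter-derived substream, so the
    result does not depend on how work is chunked.
    """
    factor = np.asarray(factor, dtype=float)
    n = factor.size
    L = np.empty((n, B))
    if unit == "child":
        uchild, inverse = np.unique(child_ids, return_inverse=True)
        child_label = np.full(uchild.size, np.nan)
        child_label[inverse] = factor
        for b in range(B):
            rng = np.random.default_rng([seed, b])
            L[:, b] = rng.permutation(child_label)[inverse]
    elif unit == "sample":
        for b in range(B):
            rng = np.random.default_rng([seed, b])
            L[:, b] = rng.permutation(factor)
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    return L


def default_unit(factor_name: str, model: str) -> str:
    if factor_name in CHILD_LEVEL_FACTORS or model == "gamm":
        return "child"
    return "sample"


def safe_pathway_pvalues(
    local: LocalStats,
    member_lists: list[np.ndarray],
    labels: np.ndarray,
    B: int,
    seed: int,
    unit: str,
    signed: bool = False,
    plus_one: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed global z and permutation p per pathway for given labels.

    The core of the SAFE test, reusable with relabeled factors (the outer
    permutations of the coherence analysis). Returns ``(z_obs, p_perm)``.
    """
    t_obs = two_sample_t(local.reduced_residuals, labels)
    z_obs = _global_stats_matrix(t_obs[:, None], member_lists, signed)[:, 0]
    L = permute_labels(labels, local.child_ids, unit, B, seed)
    t_perm = two_sample_t_multi(local.reduced_residuals, L)
    z_perm = _global_stats_matrix(t_perm, member_lists, signed)
    exceed = (np.abs(z_perm) >= np.abs(z_obs)[:, None]).sum(axis=1)
    if plus_one:
        p = (exceed + 1) / (B + 1)
    else:
        p = exceed / B
    return z_obs, p


def safe_test(
    study: ExpressionStudy,
    factor_name: str,
    gene_sets: GeneSetCollection,
    model: str = "gamm",
    spec: SplineSpec | None = None,
    B: int = 5000,
    seed: int = 0,
    signed_ranks: bool = False,
    plus_one: bool = False,
    unit: str | None = None,
    gene_fits: pd.DataFrame | None = None,
    local: LocalStats | None = None,
) -> pd.DataFrame:
    """Sample-permutation pathway enrichment for one factor.

    Returns one row per pathway with at least 2 matched member genes:
    ``name, n_genes_matched, global_stat, p_perm, q, directed_p, n_up,
    n_down``. ``q`` is Benjamini-Hochberg across pathways (permutation
    p-values floored at 1/B so zero counts stay rankable); ``directed_p``
    is -log10(p) signed by the mean full-model factor t over member genes;
    ``n_up``/``n_down`` count member genes by the sign of the full-model
    factor coefficient. ``gene_fits``/``local`` allow reuse of already
    computed sweeps.
    """
    if not gene_sets.sets:
        raise ValueError("empty gene-set collection")
    if B < 100:
        raise ValueError("need at least 100 permutations")
    alpha_res = 1.0 / B
    if alpha_res > 0.05:
        logger.warning("B=%d gives coarse p resolution %.3f", B, alpha_res)
    study = study.drop_missing_factor(factor_name)
    if local is None:
        local = compute_local_stats(study, factor_name, model, spec)
    if gene_fits is None:
        gene_fits = fit_all_genes(study, factor_name, model, spec)
    unit = unit or default_unit(factor_name, model)

    gene_index = {g: i for i, g in enumerate(local.gene_ids)}
    matched = gene_sets.match(local.gene_ids)
    names, member_lists = [], []
    for name, members in matched.items():
        if len(members) < 2:
            logger.info("skipping %s: %d matched members", name, len(members))
            continue
        names.append(name)
        member_lists.append(np.array([gene_index[g] for g in members]))
    if not names:
        raise ValueError("no pathway has >= 2 members in the study")

    z_obs, p_perm = safe_pathway_pvalues(
        local, member_lists, local.factor, B, seed, unit,
        signed=signed_ranks, plus_one=plus_one)

    est = gene_fits.set_index("gene_id")["estimate"]
    tstat = gene_fits.set_index("gene_id")["t"]
    rows = []
    for name, idx, z, p in zip(names, member_lists, z_obs, p_perm):
        genes = [local.gene_ids[i] for i in idx]
        member_est = est.loc[genes].to_numpy()
        member_t = tstat.loc[genes].to_numpy()
        n_up = int((member_est > 0).sum())
        direction = np.sign(member_t.mean())
        p_dir = max(p, 1.0 / B)
        rows.append({
            "name": name,
            "n_genes_matched": len(genes),
            "global_stat": z,
            "p_perm": p,
            "directed_p": -np.log10(p_dir) * direction,
            "n_up": n_up,
            "n_down": len(genes) - n_up,
        })
    out = pd.DataFrame(rows)
    out.insert(4, "q", bh_adjust(np.maximum(out["p_perm"], 1.0 / B)))
    return out[["name", "n_genes_matched", "global_stat", "p_perm", "q",
                "directed_p", "n_up", "n_down"]]


def aggregate_node_effect(values: Sequence[float]) -> float:
    """Collapse several genes annotated to one pathway node to one signed
    value: the member with the largest magnitude wins."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("node has no annotated genes")
    return float(vals[np.argmax(np.abs(vals))])
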