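"""Coherence of two risk-factor signatures, with a permutation null.

A *signature* is a vector of standardized effects over genes (the factor
t-statistics) or over pathways (the directed p-values,
``-log10(p) * sign(effect)``). Coherence between two factors is the Pearson
correlation of their signatures over the common ids; its significance comes
from relabeling one factor across exchangeable units, recomputing that
factor's entire signature, and counting how often the permuted correlation
magnitude exceeds the observed one:

    p_perm = (1/B) * sum_i I(|rho_i| > |rho_obs|)

The module also provides negative-control scans (factors expected to be
uncorrelated with the fixed signature) and a Wilcoxon shift test for
immune-annotated genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import SplineSpec, fit_all_genes
from .formats_io import (
    ExpressionStudy, GeneSetCollection, ImmuneAnnotation,
)
from .safe_enrichment import (
    compute_local_stats, default_unit, permute_labels, safe_pathway_pvalues,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureVector",
    "CoherenceResult",
    "directed_pvalue",
    "correlate_signatures",
    "permutation_p",
    "coherence_test",
    "control_factor_scan",
    "immune_set_shift",
    "read_signature",
    "write_signature",
]


@dataclass
class SignatureVector:
    """Standardized effects of one factor over genes or pathways."""

    ids: list[str]
    values: np.ndarray
    level: str                  # "gene" or "pathway"
    factor_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("gene", "pathway"):
            raise ValueError(f"level must be gene|pathway, got {self.level!r}")
        if len(self.ids) != self.values.size:
            raise ValueError("ids and values differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("signature ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature values must be finite")


@dataclass
class CoherenceResult:
    """Observed correlation, its permutation null and the empirical p."""

    rho_obs: float
    B: int
    null_rhos: np.ndarray
    p_perm: float
    n_common_ids: int
    factor_name: str = ""
    level: str = "gene"


def directed_pvalue(p: float, direction_stat: float) -> float:
    """Signed significance: ``-log10(p) * sign(direction_stat)``."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return float(-np.log10(p) * np.sign(direction_stat))


def correlate_signatures(
    a: SignatureVector, b: SignatureVector
) -> tuple[float, int]:
    """Pearson correlation of two signatures over their common ids."""
    if a.level != b.level:
        raise ValueError(f"signature levels differ: {a.level} vs {b.level}")
    common = [i for i in a.ids if i in set(b.ids)]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common ids; need >= 3")
    pos_a = {i: k for k, i in enumerate(a.ids)}
    pos_b = {i: k for k, i in enumerate(b.ids)}
    va = a.values[[pos_a[i] for i in common]]
    vb = b.values[[pos_b[i] for i in common]]
    for name, v in ((a.factor_name or "first", va),
                    (b.factor_name or "second", vb)):
        if np.ptp(v) == 0:
            raise ValueError(f"signature {name!r} has zero variance "
                             "over the common ids")
    rho = float(np.corrcoef(va, vb)[0, 1])
    return rho, len(common)


def permutation_p(null_rhos: np.ndarray, rho_obs: float) -> float:
    """Fraction of permuted correlations strictly exceeding the observed
    magnitude (two-sided; ties count as non-exceedances)."""
    null_rhos = np.asarray(null_rhos, dtype=float)
    if null_rhos.size == 0:
        raise ValueError("empty permutation null")
    return float(np.mean(np.abs(null_rhos) > abs(rho_obs)))


# ---------------------------------------------------------------------------
# signature computation


def _ols_t_for_labels(Y: np.ndarray, labels: np.ndarray, ages: np.ndarray,
                      extra: np.ndarray | None = None) -> np.ndarray:
    """Factor t-statistics of the age-adjusted linear model for one label
    vector, vectorized over genes; degenerate designs fall back to t=0.

    ``extra`` appends nuisance covariate columns (e.g. the primary factor
    when scanning negative controls).
    """
    n = labels.size
    cols = [np.ones(n), labels, ages]
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
    X = np.column_stack(cols)
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.zeros(Y.shape[0])
    P = Y @ X
    coefs = P @ XtX_inv
    rss = np.einsum("ij,ij->i", Y, Y) - np.einsum("ij,ij->i", coefs, P)
    sigma2 = np.maximum(rss, 0.0) / max(n - X.shape[1], 1)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, coefs[:, 1] / se, 0.0)


def _gene_signature(study: ExpressionStudy, factor_name: str, model: str,
                    spec: SplineSpec | None) -> SignatureVector:
    fits = fit_all_genes(study, factor_name, model, spec)
    return SignatureVector(fits["gene_id"].tolist(),
                           fits["t"].to_numpy(), "gene", factor_name)


def _pathway_signature_parts(study, factor_name, model, spec, gene_sets):
    """Local stats plus matched member index lists, shared by the observed
    and permuted pathway signatures."""
    local = compute_local_stats(study, factor_name, model, spec)
    gene_index = {g: i for i, g in enumerate(local.gene_ids)}
    names, member_lists = [], []
    for name, members in gene_sets.match(local.gene_ids).items():
        if len(members) < 2:
            continue
        names.append(name)
        member_lists.append(np.array([gene_index[g] for g in members]))
    if not names:
        raise ValueError("no pathway has >= 2 members in the study")
    return local, names, member_lists


def _pathway_directed_p(Y, local, names, member_lists, labels, ages,
                        inner_B, seed, unit) -> np.ndarray:
    """Directed p-value per pathway for an arbitrary labeling."""
    _, p = safe_pathway_pvalues(local, member_lists, labels, inner_B,
                                seed, unit)
    # direction from the mean factor t over members (the fast linear t on
    # the original expression serves both engines here: only its sign is
    # used, and the sign of the factor contrast is what matters)
    t_full = _ols_t_for_labels(Y, labels, ages)
    p_floor = np.maximum(p, 1.0 / inner_B)
    out = np.empty(len(names))
    for s, idx in enumerate(member_lists):
        out[s] = -np.log10(p_floor[s]) * np.sign(t_full[idx].mean())
    return out


def coherence_test(
    study: ExpressionStudy,
    fixed_signature: SignatureVector,
    permute_factor: str,
    level: str = "gene",
    model: str = "linear",
    gene_sets: GeneSetCollection | None = None,
    B: int = 5000,
    seed: int = 0,
    inner_B: int = 200,
    spec: SplineSpec | None = None,
    unit: str | None = None,
    adjust_for: str | None = None,
) -> CoherenceResult:
    """Permutation test for the coherence of two signatures.

    Computes the observed signature of ``permute_factor`` from ``study``
    (gene-level t-statistics, or pathway-level directed p-values when
    ``level="pathway"``; then ``gene_sets`` is required), correlates it with
    ``fixed_signature``, and builds the null by relabeling the factor
    (child-wise for child-level factors, sample-wise otherwise) and
    recomputing the full signature B times. Pathway-level recomputation
    uses ``inner_B`` label permutations for the within-permutation
    enrichment p-values.

    ``adjust_for`` adds another metadata factor as a nuisance covariate to
    the signature model (gene-level linear engine only). This matters for
    negative-control scans in a case-control arm: with few cases, a control
    factor's chance correlation with the case label would otherwise let it
    borrow the case-label signal and masquerade as coherent.
    """
    if level not in ("gene", "pathway"):
        raise ValueError(f"level must be gene|pathway, got {level!r}")
    if level != fixed_signature.level:
        raise ValueError("fixed signature level does not match requested level")
    if level == "pathway" and gene_sets is None:
        raise ValueError("pathway-level coherence requires gene_sets")
    if adjust_for is not None and (level != "gene" or model != "linear"):
        raise ValueError(
            "adjust_for is supported for the gene-level linear engine only")
    study = study.drop_missing_factor(permute_factor)
    if adjust_for is not None:
        study = study.drop_missing_factor(adjust_for)
    x = study.factor_values(permute_factor)
    ages = study.metadata["age_years"].to_numpy(dtype=float)
    child = study.metadata["child_id"].to_numpy()
    unit = unit or default_unit(permute_factor, model)
    extra = (study.factor_values(adjust_for)
             if adjust_for is not None else None)

    if level == "gene" and extra is not None:
        t_obs = _ols_t_for_labels(study.values, x, ages, extra)
        obs = SignatureVector(list(study.gene_ids), t_obs, "gene",
                              permute_factor)
    elif level == "gene":
        obs = _gene_signature(study, permute_factor, model, spec)
    else:
        local, names, member_lists = _pathway_signature_parts(
            study, permute_factor, model, spec, gene_sets)
        vals = _pathway_directed_p(study.values, local, names, member_lists,
                                   x, ages, inner_B, seed=_sub(seed, 0),
                                   unit=unit)
        obs = SignatureVector(names, vals, "pathway", permute_factor)

    rho_obs, n_common = correlate_signatures(fixed_signature, obs)

    # align the fixed signature once; permuted signatures preserve id order
    common = [i for i in fixed_signature.ids if i in set(obs.ids)]
    pos_f = {i: k for k, i in enumerate(fixed_signature.ids)}
    pos_o = {i: k for k, i in enumerate(obs.ids)}
    vf = fixed_signature.values[[pos_f[i] for i in common]]
    o_idx = np.array([pos_o[i] for i in common])

    null = np.empty(B)
    if level == "gene" and model == "linear":
        L = permute_labels(x, child, unit, B, _sub(seed, 1))
        for b in range(B):
            t_b = _ols_t_for_labels(study.values, L[:, b], ages,
                                    extra)[o_idx]
            null[b] = _pearson(vf, t_b)
    elif level == "gene":
        L = permute_labels(x, child, unit, B, _sub(seed, 1))
        for b in range(B):
            md = study.metadata.copy()
            md[permute_factor] = L[:, b]
            st_b = ExpressionStudy(list(study.gene_ids),
                                   list(study.sample_ids),
                                   study.values, md)
            sig_b = _gene_signature(st_b, permute_factor, model, spec)
            null[b] = _pearson(vf, sig_b.values[o_idx])
    else:
        L = permute_labels(x, child, unit, B, _sub(seed, 1))
        for b in range(B):
            vals_b = _pathway_directed_p(
                study.values, local, names, member_lists, L[:, b], ages,
                inner_B, seed=_sub(seed, 2 + b), unit=unit)
            null[b] = _pearson(vf, vals_b[o_idx])

    p = permutation_p(null, rho_obs)
    return CoherenceResult(rho_obs, B, null, p, n_common,
                           factor_name=permute_factor, level=level)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _sub(seed: int, k: int) -> int:
    # cheap deterministic substream index; stays below 2**31
    return (seed * 1000003 + k) % (2 ** 31 - 1)


def control_factor_scan(
    study: ExpressionStudy,
    fixed_signature: SignatureVector,
    control_factors: list[str],
    level: str = "gene",
    model: str = "linear",
    gene_sets: GeneSetCollection | None = None,
    B: int = 1000,
    seed: int = 0,
    inner_B: int = 200,
    spec: SplineSpec | None = None,
    adjust_for: str | None = None,
) -> pd.DataFrame:
    """Coherence of the fixed signature with each negative-control factor.

    Factors absent from the metadata (or without both levels observed) are
    skipped with a log entry. Returns one row per tested factor.
    ``adjust_for`` is forwarded to :func:`coherence_test`.
    """
    rows = []
    for k, factor in enumerate(control_factors):
        if factor not in study.metadata.columns:
            logger.warning("control factor %r missing; skipped", factor)
            continue
        x = study.metadata[factor].dropna()
        if x.nunique() < 2:
            logger.warning("control factor %r constant; skipped", factor)
            continue
        res = coherence_test(study, fixed_signature, factor, level, model,
                             gene_sets, B, _sub(seed, 7919 + k), inner_B,
                             spec, adjust_for=adjust_for)
        rows.append({"factor": factor, "rho_obs": res.rho_obs,
                     "p_perm": res.p_perm, "B": res.B,
                     "n_common_ids": res.n_common_ids})
    return pd.DataFrame(rows,
                        columns=["factor", "rho_obs", "p_perm", "B",
                                 "n_common_ids"])


# ---------------------------------------------------------------------------
# immune-gene shift


def immune_set_shift(
    gene_fits: pd.DataFrame,
    immune: ImmuneAnnotation,
    signed: bool = False,
) -> tuple[float, float]:
    """Wilcoxon rank-sum shift of |t| between immune and non-immune genes.

    Exact enumeration over group assignments when both strata have at most
    10 genes; otherwise the normal approximation with tie correction.
    Returns ``(rank_sum_stat, p)`` where the statistic is the rank sum of
    the immune stratum.
    """
    in_immune = gene_fits["gene_id"].isin(immune.immune_gene_ids).to_numpy()
    t = gene_fits["t"].to_numpy(dtype=float)
    vals = t if signed else np.abs(t)
    n1 = int(in_immune.sum())
    n2 = int((~in_immune).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 genes per stratum, found {n1} immune / {n2} other")
    ranks = stats.rankdata(vals)
    W = float(ranks[in_immune].sum())
    N = n1 + n2
    mean = n1 * (N + 1) / 2.0

    if n1 <= 10 and n2 <= 10:
        # exact two-sided p by enumeration of all immune-set assignments
        obs_dev = abs(W - mean)
        count = 0
        total = 0
        for comb in itertools.combinations(range(N), n1):
            w = ranks[list(comb)].sum()
            if abs(w - mean) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        tie = _tie_sum(np.sort(vals))
        var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var <= 0:
            return W, 1.0
        z = (W - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return W, min(p, 1.0)


def _tie_sum(sorted_vals: np.ndarray) -> float:
    total = 0.0
    run = 1
    for i in range(1, sorted_vals.size):
        if sorted_vals[i] == sorted_vals[i - 1]:
            run += 1
        else:
            if run > 1:
                total += run ** 3 - run
            run = 1
    if run > 1:
        total += run ** 3 - run
    return total


# ---------------------------------------------------------------------------
# signature I/O


def write_signature(sig: SignatureVector, path: str | Path) -> None:
    df = pd.DataFrame({"id": sig.ids, "value": sig.values,
                       "level": sig.level, "factor_name": sig.factor_name})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_signature(path: str | Path) -> SignatureVector:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"id": str, "level": str, "factor_name": str})
    level = df["level"].iloc[0]
    factor = df["factor_name"].iloc[0]
    return SignatureVector(df["id"].tolist(),
                           df["value"].to_numpy(dtype=float), level, factor)
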