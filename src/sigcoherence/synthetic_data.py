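"""Synthetic longitudinal and cross-sectional expression studies.

The generator emulates the statistical structure the downstream models
assume: a cohort of children sampled 1-4 times in the first year of life with
a child-level binary exposure (Cesarean section), a cross-sectional
case/control arm (islet autoantibody seroconversion), pathway-structured
gene effects for the two factors drawn with a controllable cross-factor
correlation, per-child random intercepts, smooth per-gene age trends, and
i.i.d. gene-wise noise on the log2 scale. Every draw is reproducible from
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import ExpressionStudy, GeneSetCollection, METADATA_COLUMNS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "draw_ground_truth",
    "simulate_longitudinal",
    "simulate_casecontrol",
    "simulate_activation_signature",
]

#: child-level binary attributes carried in metadata
_CHILD_FACTORS = ("cs", "gender", "maternal_diabetes", "multiple_fdr")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: ~87 children with
    1-4 blood samples each across the first year of life, weak child-level
    exposure effects concentrated in a minority of pathways, and a positive
    cross-factor effect correlation between the two risk factors.

    Units: expression values, effect sizes and noise are on the log2
    intensity scale; ages are in years.
    """

    n_children: int = 87
    samples_per_child_range: tuple[int, int] = (1, 4)
    age_range_years: tuple[float, float] = (0.04, 1.0)
    n_genes: int = 2000
    n_pathways: int = 25
    pathway_size_range: tuple[int, int] = (10, 30)
    frac_active_pathways: float = 0.2
    effect_sd: float = 0.1
    #: marginal sd of the case-label (ab) effects; None means effect_sd.
    #: The two factors may carry very different signal strengths; 0 makes
    #: the ab label independent of expression (the exchangeable null)
    ab_effect_sd: float | None = None
    cross_factor_correlation: float = 0.6
    child_intercept_sd: float = 0.3
    noise_sd: float = 0.3
    time_trend_amplitude: float = 0.2
    factor_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "cs": 0.45,
            "ab": 0.17,
            "gender": 0.5,
            "maternal_diabetes": 0.2,
            "multiple_fdr": 0.2,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("samples_per_child_range", "age_range_years",
                     "pathway_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if abs(self.cross_factor_correlation) > 1:
            raise ValueError("cross_factor_correlation must be in [-1, 1]")
        for name in ("effect_sd", "child_intercept_sd", "noise_sd",
                     "time_trend_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ab_effect_sd is not None and self.ab_effect_sd < 0:
            raise ValueError("ab_effect_sd must be >= 0")
        if self.noise_sd == 0:
            raise ValueError("noise_sd must be positive")
        for fac, p in self.factor_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence of {fac!r} must be in (0,1)")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SimulationConfig":
        """Build a config from a flat key:value mapping (CLI config files).

        Integer pairs and real pairs are comma-separated ("1,4"); factor
        prevalences use dotted keys ("prevalence.cs=0.45").
        """
        kwargs: dict = {}
        prev: dict[str, float] = dict(cls().factor_prevalences)
        for key, raw in mapping.items():
            key = key.strip()
            if key.startswith("prevalence."):
                prev[key.split(".", 1)[1]] = float(raw)
            elif key in ("samples_per_child_range", "pathway_size_range"):
                lo, hi = raw.split(",")
                kwargs[key] = (int(lo), int(hi))
            elif key == "age_range_years":
                lo, hi = raw.split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key in ("n_children", "n_genes", "n_pathways", "seed"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        kwargs["factor_prevalences"] = prev
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """The latent quantities a simulated study was generated from."""

    beta_cs: np.ndarray
    beta_ab: np.ndarray
    active_pathways: set[str]
    #: child id -> per-gene intercept vector; the random intercept is
    #: gene-specific (each gene has its own child offsets), so sharing one
    #: scalar across genes would induce spurious cross-gene correlation
    child_intercepts: dict[str, np.ndarray]
    time_trend_params: np.ndarray  # (n_genes, 3) cubic coefficients
    pathways: dict[str, list[str]]
    gene_ids: list[str]
    mu: np.ndarray
    beta_activation: np.ndarray | None = None

    def gene_set_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            {name: ("synthetic", list(members))
             for name, members in self.pathways.items()}
        )

    @property
    def active_gene_mask(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        mask = np.zeros(len(self.gene_ids), dtype=bool)
        for name in self.active_pathways:
            for g in self.pathways[name]:
                mask[idx[g]] = True
        return mask


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # distinct substreams keep truth/arm draws independent but reproducible
    return np.random.default_rng([config.seed, stream])


def draw_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw gene effects, pathway structure and age trends.

    Genes are partitioned into ``n_pathways`` disjoint sets with sizes drawn
    from ``pathway_size_range``; the remaining genes belong to no pathway. A
    fraction ``frac_active_pathways`` of pathways is active: their member
    genes receive (beta_cs, beta_ab) from a bivariate normal with marginal sd
    ``effect_sd`` and correlation ``cross_factor_correlation``; every other
    gene has exactly zero effect for both factors.
    """
    rng = _rng(config, 0)
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]
    sizes = rng.integers(config.pathway_size_range[0],
                         config.pathway_size_range[1] + 1,
                         size=config.n_pathways)
    if sizes.sum() > g:
        raise ValueError(
            f"n_genes={g} smaller than total pathway membership "
            f"{int(sizes.sum())}; increase n_genes or shrink pathways"
        )
    order = rng.permutation(g)
    pathways: dict[str, list[str]] = {}
    start = 0
    for p, size in enumerate(sizes):
        idx = order[start:start + size]
        pathways[f"PW{p:03d}"] = [gene_ids[i] for i in sorted(idx)]
        start += size
    n_active = int(round(config.frac_active_pathways * config.n_pathways))
    active = ({str(s) for s in rng.choice(list(pathways), size=n_active,
                                          replace=False)}
              if n_active else set())

    beta_cs = np.zeros(g)
    beta_ab = np.zeros(g)
    sd_ab = (config.effect_sd if config.ab_effect_sd is None
             else config.ab_effect_sd)
    if (config.effect_sd > 0 or sd_ab > 0) and active:
        rho = config.cross_factor_correlation
        idx = {gid: i for i, gid in enumerate(gene_ids)}
        active_idx = sorted({idx[gid] for name in sorted(active)
                             for gid in pathways[name]})
        z = rng.normal(size=(len(active_idx), 2))
        b_cs = z[:, 0]
        b_ab = rho * z[:, 0] + np.sqrt(max(1.0 - rho ** 2, 0.0)) * z[:, 1]
        beta_cs[active_idx] = config.effect_sd * b_cs
        beta_ab[active_idx] = sd_ab * b_ab

    mu = rng.normal(7.0, 1.0, size=g)
    trend = rng.normal(0.0, 1.0, size=(g, 3))
    return GroundTruth(
        beta_cs=beta_cs, beta_ab=beta_ab, active_pathways=active,
        child_intercepts={}, time_trend_params=trend, pathways=pathways,
        gene_ids=gene_ids, mu=mu,
    )


def _trend_matrix(truth: GroundTruth, ages: np.ndarray,
                  config: SimulationConfig) -> np.ndarray:
    """Smooth per-gene age trend: amplitude-scaled centred cubic in age."""
    lo, hi = config.age_range_years
    u = (ages - lo) / max(hi - lo, 1e-12)
    basis = np.stack([u - 0.5, (u - 0.5) ** 2, (u - 0.5) ** 3])  # (3, n)
    return config.time_trend_amplitude * (truth.time_trend_params @ basis)


def _child_table(config: SimulationConfig, rng: np.random.Generator,
                 n_children: int, prefix: str) -> pd.DataFrame:
    rows = {}
    rows["child_id"] = [f"{prefix}{i:03d}" for i in range(n_children)]
    for fac in _CHILD_FACTORS:
        p = config.factor_prevalences.get(fac, 0.5)
        rows[fac] = rng.binomial(1, p, size=n_children).astype(float)
    return pd.DataFrame(rows)


def _finish_metadata(md: pd.DataFrame) -> pd.DataFrame:
    for col in METADATA_COLUMNS:
        if col not in md.columns:
            md[col] = np.nan
    md = md[[c for c in METADATA_COLUMNS if c in md.columns]
            + [c for c in md.columns if c not in METADATA_COLUMNS]]
    return md.set_index("sample_id", drop=False)


def simulate_longitudinal(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the longitudinal arm: children with repeated samples.

    Each child receives a Bernoulli Cesarean-section label, a count of
    samples uniform in ``samples_per_child_range`` and ages uniform in
    ``age_range_years``. Expression is
    ``mu_g + trend_g(age) + beta_cs[g]*cs + child intercept + noise``.
    Islet-autoantibody status is left missing (it belongs to the
    cross-sectional arm).
    """
    if truth is None:
        truth = draw_ground_truth(config)
    rng = _rng(config, 1)
    children = _child_table(config, rng, config.n_children, "C")
    lo, hi = config.samples_per_child_range
    counts = rng.integers(lo, hi + 1, size=config.n_children)

    recs = []
    for (_, child), cnt in zip(children.iterrows(), counts):
        ages = np.sort(rng.uniform(*config.age_range_years, size=cnt))
        for s, age in enumerate(ages):
            recs.append({
                "sample_id": f"{child.child_id}_S{s}",
                "child_id": child.child_id,
                "age_years": age,
                **{fac: child[fac] for fac in _CHILD_FACTORS},
            })
    md = _finish_metadata(pd.DataFrame(recs))

    intercepts = rng.normal(0.0, config.child_intercept_sd,
                            size=(config.n_genes, config.n_children))
    truth.child_intercepts = {c: intercepts[:, j]
                              for j, c in enumerate(children.child_id)}

    ages = md["age_years"].to_numpy()
    cs = md["cs"].to_numpy()
    child_pos = {c: j for j, c in enumerate(children.child_id)}
    sample_child = md["child_id"].map(child_pos).to_numpy()
    y = (truth.mu[:, None]
         + _trend_matrix(truth, ages, config)
         + np.outer(truth.beta_cs, cs)
         + intercepts[:, sample_child]
         + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(md))))
    study = ExpressionStudy(list(truth.gene_ids), md["sample_id"].tolist(),
                            y, md)
    return study, truth


def simulate_casecontrol(
    config: SimulationConfig,
    n_cases: int = 15,
    n_control_children: int = 74,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the cross-sectional arm: seroconverted cases vs controls.

    One sample per case child (ab=1) taken shortly after seroconversion;
    control children (ab=0) with ages drawn from the same distribution as the
    cases, emulating age matching. Expression uses ``beta_ab`` plus a linear
    per-gene age effect.
    """
    if n_cases < 2 or n_control_children < 2:
        raise ValueError("need >= 2 cases and >= 2 control children")
    if truth is None:
        truth = draw_ground_truth(config)
    rng = _rng(config, 2)
    n = n_cases + n_control_children
    children = _child_table(config, rng, n, "K")
    ab = np.r_[np.ones(n_cases), np.zeros(n_control_children)]
    # case ages: seroconversion age plus a short post-seroconversion delay;
    # control ages drawn from the same construction (age matching emulation)
    sero = rng.uniform(0.2, 0.7, size=n)
    delay = rng.uniform(0.05, 0.45, size=n)
    ages = sero + delay

    recs = []
    for i, (_, child) in enumerate(children.iterrows()):
        recs.append({
            "sample_id": f"{child.child_id}_S0",
            "child_id": child.child_id,
            "age_years": ages[i],
            "ab": float(ab[i]),
            "serocon_age_years": sero[i] if ab[i] == 1 else np.nan,
            **{fac: child[fac] for fac in _CHILD_FACTORS},
        })
    md = _finish_metadata(pd.DataFrame(recs))

    intercepts = rng.normal(0.0, config.child_intercept_sd,
                            size=(config.n_genes, n))
    # linear age slope reuses the first cubic coefficient, amplitude-scaled
    slope = config.time_trend_amplitude * truth.time_trend_params[:, 0]
    y = (truth.mu[:, None]
         + np.outer(slope, ages)
         + np.outer(truth.beta_ab, ab)
         + intercepts
         + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n)))
    study = ExpressionStudy(list(truth.gene_ids), md["sample_id"].tolist(),
                            y, md)
    return study, truth


def simulate_activation_signature(
    config: SimulationConfig,
    corr_to_ab: float = 0.5,
    n_per_group: int = 20,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate a two-group immune-cell activation experiment.

    A stand-in for external naive-vs-activated cell datasets: expression for
    ``2*n_per_group`` samples with a binary ``activation`` factor whose
    per-gene effect vector is drawn with target correlation ``corr_to_ab`` to
    the autoimmunity effects (over active genes).
    """
    if abs(corr_to_ab) > 1:
        raise ValueError("corr_to_ab must be in [-1, 1]")
    if truth is None:
        truth = draw_ground_truth(config)
    rng = _rng(config, 3)
    mask = truth.active_gene_mask
    beta_act = np.zeros(config.n_genes)
    if config.effect_sd > 0 and mask.any():
        z = rng.normal(0.0, 1.0, size=int(mask.sum()))
        beta_act[mask] = (corr_to_ab * truth.beta_ab[mask]
                          + np.sqrt(1 - corr_to_ab ** 2)
                          * config.effect_sd * z)
    truth.beta_activation = beta_act

    n = 2 * n_per_group
    act = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    recs = [{
        "sample_id": f"A{i:03d}",
        "child_id": f"A{i:03d}",
        "age_years": 30.0,  # adult donors; age plays no role here
        "activation": act[i],
    } for i in range(n)]
    md = _finish_metadata(pd.DataFrame(recs))
    y = (truth.mu[:, None]
         + np.outer(beta_act, act)
         + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n)))
    study = ExpressionStudy(list(truth.gene_ids), md["sample_id"].tolist(),
                            y, md)
    return study, truth
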