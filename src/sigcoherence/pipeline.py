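"""End-to-end orchestration of the analysis arms.

* the longitudinal arm: first-year age filter, per-gene GAMM sweep for a
  child-level exposure, pathway enrichment;
* the cross-sectional arm: case selection within a post-seroconversion
  window, age-adjusted linear sweep, pathway enrichment;
* the coherence stage: gene- and pathway-level signature correlation with
  permutation p-values, negative-control factors, immune-gene shift;
* a single-command synthetic demo exercising all of the above.

Every run writes TSV tables through :mod:`sigcoherence.formats_io` with a
header recording package version, seed and config digest, plus a JSON
manifest with per-stage file digests and wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential_expression import SplineSpec, fit_all_genes
from .formats_io import (
    ExpressionStudy, GeneSetCollection, ImmuneAnnotation, read_expression,
    read_gmt, write_expression, write_gmt, write_results_table,
)
from .coherence import (
    SignatureVector, coherence_test, control_factor_scan, immune_set_shift,
    write_signature,
)
from .safe_enrichment import safe_test
from .synthetic_data import (
    SimulationConfig, draw_ground_truth, simulate_casecontrol,
    simulate_longitudinal,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "select_first_year",
           "select_case_control_samples", "run_cs_arm", "run_ab_arm",
           "run_demo"]

CONTROL_FACTORS = ["maternal_diabetes", "gender", "multiple_fdr"]


@dataclass
class RunConfig:
    """Flat configuration of a pipeline run."""

    expression: str = ""
    metadata: str = ""
    gmt: str = ""
    immune_list: str = ""
    output_dir: str = "out"
    arm: str = "demo"
    factor: str = "cs"
    model: str = "gamm"
    spline_k: int = 5
    fdr_level: float = 0.1
    permutations: int = 5000
    inner_permutations: int = 200
    age_cutoff_years: float = 1.0
    serocon_window_years: float = 0.5
    control_sample_policy: str = "nearest"   # or "all"
    signed_ranks: bool = False
    seed: int = 0
    workers: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file ('#' comments allowed)."""
        kwargs: dict = {}
        types = cls.__dataclass_fields__
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = types[key].type
            if typ == "int":
                kwargs[key] = int(raw)
            elif typ == "float":
                kwargs[key] = float(raw)
            elif typ == "bool":
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    #: fields excluded from the config digest: they name locations, not
    #: analysis parameters, so results must not depend on them
    _PATH_FIELDS = ("expression", "metadata", "gmt", "immune_list",
                    "output_dir")

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items()
             if k not in self._PATH_FIELDS},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (f"sigcoherence {__version__} | seed={self.seed} "
                f"| config={self.digest()}")

    def spline_spec(self) -> SplineSpec:
        return SplineSpec(k=self.spline_k)


@dataclass
class RunManifest:
    """Provenance of one run: config snapshot, digests, timings."""

    config: dict
    package_version: str = __version__
    files: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)

    def record_file(self, label: str, path: str | Path) -> None:
        data = Path(path).read_bytes()
        self.files[label] = {
            "path": str(path),
            "sha256": hashlib.sha256(data).hexdigest(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# sample selection rules


def select_first_year(study: ExpressionStudy,
                      cutoff_years: float = 1.0) -> ExpressionStudy:
    """Keep samples taken within the first ``cutoff_years`` of life
    (inclusive)."""
    ages = study.metadata["age_years"].to_numpy(dtype=float)
    keep = ages <= cutoff_years
    if not keep.any():
        raise ValueError(
            f"no samples left after the age_years <= {cutoff_years} filter")
    return study.subset_samples(keep)


def select_case_control_samples(
    study: ExpressionStudy,
    window_years: float = 0.5,
    control_policy: str = "nearest",
) -> ExpressionStudy:
    """Apply the cross-sectional selection rule.

    Cases: for every seroconverted child (ab=1), the earliest sample whose
    age falls within ``[0, window_years]`` after the recorded seroconversion
    age; children without such a sample are excluded. Controls (ab=0):
    either the single sample nearest the median selected case age
    (``"nearest"``, the default, which keeps one independent observation per
    child) or every available sample (``"all"``).
    """
    md = study.metadata
    ab = md["ab"].to_numpy(dtype=float)
    keep_ids: list[str] = []
    case_ages: list[float] = []
    for child, grp in md[ab == 1].groupby("child_id", sort=False):
        sero = grp["serocon_age_years"].to_numpy(dtype=float)
        ages = grp["age_years"].to_numpy(dtype=float)
        delta = ages - sero
        ok = (delta >= 0) & (delta <= window_years)
        if not ok.any():
            continue
        pick = grp.index[ok][np.argmin(ages[ok])]
        keep_ids.append(pick)
        case_ages.append(float(md.loc[pick, "age_years"]))
    if not keep_ids:
        raise ValueError(
            f"no case child has a sample within [0, {window_years}] years "
            f"after seroconversion")
    target = float(np.median(case_ages))
    for child, grp in md[ab == 0].groupby("child_id", sort=False):
        if control_policy == "all":
            keep_ids.extend(grp.index.tolist())
        elif control_policy == "nearest":
            ages = grp["age_years"].to_numpy(dtype=float)
            keep_ids.append(grp.index[np.argmin(np.abs(ages - target))])
        else:
            raise ValueError(f"unknown control policy {control_policy!r}")
    keep_set = set(keep_ids)
    return study.subset_samples([s in keep_set for s in study.sample_ids])


# ---------------------------------------------------------------------------
# analysis arms


def run_cs_arm(
    config: RunConfig,
    study: ExpressionStudy | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Longitudinal arm: age filter, GAMM sweep, pathway enrichment.

    ``study``/``gene_sets`` may be passed in memory; otherwise they are read
    from the configured paths. Writes ``cs_genes.tsv``, ``cs_pathways.tsv``
    and ``cs_manifest.json`` under ``output_dir``.
    """
    manifest = RunManifest(config=asdict(config))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = read_expression(config.expression, config.metadata)
    if gene_sets is None:
        gene_sets = read_gmt(config.gmt)

    t0 = time.perf_counter()
    study = select_first_year(study, config.age_cutoff_years)
    study = study.drop_missing_factor(config.factor)
    spec = config.spline_spec()
    fits = fit_all_genes(study, config.factor, "gamm", spec,
                         workers=config.workers)
    manifest.stage_seconds["gamm_sweep"] = round(time.perf_counter() - t0, 3)
    manifest.warnings["non_converged_genes"] = int(
        (~fits["converged"]).sum())

    t0 = time.perf_counter()
    pathways = safe_test(study, config.factor, gene_sets, "gamm", spec,
                         B=config.permutations, seed=config.seed,
                         signed_ranks=config.signed_ranks, gene_fits=fits)
    manifest.stage_seconds["enrichment"] = round(time.perf_counter() - t0, 3)

    genes_path = outdir / "cs_genes.tsv"
    pw_path = outdir / "cs_pathways.tsv"
    write_results_table(fits, genes_path, header=config.header())
    write_results_table(pathways, pw_path, header=config.header())
    manifest.record_file("cs_genes", genes_path)
    manifest.record_file("cs_pathways", pw_path)
    manifest.write(outdir / "cs_manifest.json")
    return fits, pathways, manifest


def run_ab_arm(
    config: RunConfig,
    study: ExpressionStudy | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Cross-sectional arm: case selection, linear sweep, enrichment."""
    manifest = RunManifest(config=asdict(config))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = read_expression(config.expression, config.metadata)
    if gene_sets is None:
        gene_sets = read_gmt(config.gmt)

    t0 = time.perf_counter()
    study = study.drop_missing_factor("ab")
    study = select_case_control_samples(
        study, config.serocon_window_years, config.control_sample_policy)
    fits = fit_all_genes(study, "ab", "linear")
    manifest.stage_seconds["linear_sweep"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    pathways = safe_test(study, "ab", gene_sets, "linear",
                         B=config.permutations, seed=config.seed,
                         signed_ranks=config.signed_ranks, gene_fits=fits)
    manifest.stage_seconds["enrichment"] = round(time.perf_counter() - t0, 3)

    genes_path = outdir / "ab_genes.tsv"
    pw_path = outdir / "ab_pathways.tsv"
    write_results_table(fits, genes_path, header=config.header())
    write_results_table(pathways, pw_path, header=config.header())
    manifest.record_file("ab_genes", genes_path)
    manifest.record_file("ab_pathways", pw_path)
    manifest.write(outdir / "ab_manifest.json")
    return fits, pathways, manifest


# ---------------------------------------------------------------------------
# demo


def demo_simulation_config(seed: int, n_genes: int = 2000,
                           n_pathways: int = 25) -> SimulationConfig:
    """The demo's study conditions: a cohort like the one the pipeline
    targets, with clear pathway-concentrated signal and cross-factor
    correlation 0.6."""
    return SimulationConfig(
        n_children=87,
        samples_per_child_range=(1, 4),
        age_range_years=(0.04, 1.0),
        n_genes=n_genes,
        n_pathways=n_pathways,
        pathway_size_range=(15, 30),
        frac_active_pathways=0.2,
        effect_sd=0.5,
        cross_factor_correlation=0.6,
        seed=seed,
    )


def run_demo(
    seed: int,
    output_dir: str | Path = "demo_out",
    sim_config: SimulationConfig | None = None,
    gene_B: int = 500,
    pathway_B: int = 200,
    inner_B: int = 200,
    enrich_B: int = 500,
    workers: int = 1,
) -> dict:
    """Simulate both arms and run the full inference chain.

    Returns a dict with the headline statistics (also written as
    ``demo_summary.tsv``): gene- and pathway-level coherence, the three
    negative-control correlations, the immune-gene shift, and the planted
    pathway recovery of each enrichment run.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config or demo_simulation_config(seed)
    config = RunConfig(output_dir=str(outdir), seed=seed,
                       permutations=enrich_B,
                       inner_permutations=inner_B, workers=workers)
    manifest = RunManifest(config={**asdict(config),
                                   "simulation": asdict(sim) | {
                                       "factor_prevalences":
                                       dict(sim.factor_prevalences)}})

    t0 = time.perf_counter()
    truth = draw_ground_truth(sim)
    study_cs, _ = simulate_longitudinal(sim, truth=truth)
    study_ab, _ = simulate_casecontrol(sim, 15, 74, truth=truth)
    gene_sets = truth.gene_set_collection()
    # a plausible "immune" annotation: the genes of the active pathways
    # plus a pad of unaffected genes
    rng = np.random.default_rng([sim.seed, 9])
    active_genes = sorted({g for name in sorted(truth.active_pathways)
                           for g in truth.pathways[name]})
    # cap at half the genes so both strata of the shift test are populated
    if len(active_genes) > sim.n_genes // 2:
        active_genes = list(rng.choice(active_genes, size=sim.n_genes // 2,
                                       replace=False))
    pool = [g for g in truth.gene_ids if g not in set(active_genes)]
    pad = rng.choice(pool, size=min(len(pool) // 2, 100, sim.n_genes // 10),
                     replace=False)
    immune = ImmuneAnnotation(set(map(str, active_genes))
                              | set(map(str, pad)))
    write_expression(study_cs, outdir / "cs_expression.tsv",
                     outdir / "cs_metadata.tsv", header=config.header())
    write_expression(study_ab, outdir / "ab_expression.tsv",
                     outdir / "ab_metadata.tsv", header=config.header())
    write_gmt(gene_sets, outdir / "pathways.gmt")
    manifest.stage_seconds["simulate"] = round(time.perf_counter() - t0, 3)

    cs_fits, cs_pathways, _ = run_cs_arm(config, study_cs, gene_sets)
    ab_fits, ab_pathways, _ = run_ab_arm(config, study_ab, gene_sets)

    cs_gene_sig = SignatureVector(cs_fits["gene_id"].tolist(),
                                  cs_fits["t"].to_numpy(), "gene", "cs")
    cs_pw_sig = SignatureVector(cs_pathways["name"].tolist(),
                                cs_pathways["directed_p"].to_numpy(),
                                "pathway", "cs")
    write_signature(cs_gene_sig, outdir / "cs_gene_signature.tsv")
    write_signature(cs_pw_sig, outdir / "cs_pathway_signature.tsv")

    t0 = time.perf_counter()
    co_gene = coherence_test(study_ab, cs_gene_sig, "ab", "gene", "linear",
                             B=gene_B, seed=seed)
    manifest.stage_seconds["gene_coherence"] = round(
        time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    co_pw = coherence_test(study_ab, cs_pw_sig, "ab", "pathway", "linear",
                           gene_sets=gene_sets, B=pathway_B, seed=seed,
                           inner_B=inner_B)
    manifest.stage_seconds["pathway_coherence"] = round(
        time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    # controls adjust for the case label: with 15 cases, a control factor's
    # chance correlation with ab would otherwise leak the ab signal into
    # its signature
    controls = control_factor_scan(study_ab, cs_gene_sig, CONTROL_FACTORS,
                                   "gene", "linear", B=pathway_B, seed=seed,
                                   adjust_for="ab")
    manifest.stage_seconds["controls"] = round(time.perf_counter() - t0, 3)

    W_ab, p_imm_ab = immune_set_shift(ab_fits, immune)
    W_cs, p_imm_cs = immune_set_shift(cs_fits, immune)

    np.savetxt(outdir / "gene_null_rhos.tsv", co_gene.null_rhos,
               fmt="%.6g", header=config.header())
    np.savetxt(outdir / "pathway_null_rhos.tsv", co_pw.null_rhos,
               fmt="%.6g", header=config.header())

    active = truth.active_pathways
    fdr = config.fdr_level
    summary_rows = [
        {"statistic": "rho_obs_gene", "value": co_gene.rho_obs},
        {"statistic": "p_perm_gene", "value": co_gene.p_perm},
        {"statistic": "rho_obs_pathway", "value": co_pw.rho_obs},
        {"statistic": "p_perm_pathway", "value": co_pw.p_perm},
        *({"statistic": f"rho_obs_control_{r.factor}", "value": r.rho_obs}
          for r in controls.itertuples()),
        *({"statistic": f"p_perm_control_{r.factor}", "value": r.p_perm}
          for r in controls.itertuples()),
        {"statistic": "immune_shift_p_cs", "value": p_imm_cs},
        {"statistic": "immune_shift_p_ab", "value": p_imm_ab},
        {"statistic": "n_sig_genes_ab",
         "value": int((ab_fits["q"] <= fdr).sum())},
        {"statistic": "n_sig_pathways_cs",
         "value": int((cs_pathways["q"] <= fdr).sum())},
        {"statistic": "n_sig_pathways_ab",
         "value": int((ab_pathways["q"] <= fdr).sum())},
        {"statistic": "n_active_recovered_cs",
         "value": int(cs_pathways.loc[cs_pathways["name"].isin(active),
                                      "q"].le(fdr).sum())},
        {"statistic": "n_active_recovered_ab",
         "value": int(ab_pathways.loc[ab_pathways["name"].isin(active),
                                      "q"].le(fdr).sum())},
        {"statistic": "n_active_pathways", "value": len(active)},
    ]
    summary = pd.DataFrame(summary_rows)
    write_results_table(summary, outdir / "demo_summary.tsv",
                        header=config.header())
    manifest.record_file("demo_summary", outdir / "demo_summary.tsv")
    for label in ("cs_genes", "cs_pathways", "ab_genes", "ab_pathways"):
        manifest.record_file(label, outdir / f"{label}.tsv")
    manifest.write(outdir / "demo_manifest.json")

    return {row["statistic"]: row["value"] for row in summary_rows}
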