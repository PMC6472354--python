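from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigcoherence.formats_io import ExpressionStudy
from sigcoherence.synthetic_data import SimulationConfig


def make_study(
    n_genes: int = 5,
    n_children: int = 6,
    samples_per_child: int = 2,
    seed: int = 0,
    factors: dict | None = None,
) -> ExpressionStudy:
    """Small hand-assembled study with child-level binary factors."""
    rng = np.random.default_rng(seed)
    recs = []
    factors = factors or {"cs": 0.5, "ab": 0.5, "gender": 0.5}
    child_levels = {
        f: rng.binomial(1, p, size=n_children).astype(float)
        for f, p in factors.items()
    }
    for c in range(n_children):
        for s in range(samples_per_child):
            recs.append({
                "sample_id": f"C{c}_S{s}",
                "child_id": f"C{c}",
                "age_years": float(rng.uniform(0.05, 1.0)),
                **{f: child_levels[f][c] for f in factors},
            })
    md = pd.DataFrame(recs)
    for col in ("maternal_diabetes", "multiple_fdr", "serocon_age_years"):
        if col not in md:
            md[col] = np.nan
    md = md.set_index("sample_id", drop=False)
    n = len(md)
    values = rng.normal(7.0, 1.0, size=(n_genes, n))
    gene_ids = [f"G{i}" for i in range(n_genes)]
    return ExpressionStudy(gene_ids, md["sample_id"].tolist(), values, md)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    return make_study()


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_children=30, n_genes=120, n_pathways=6,
        pathway_size_range=(8, 12), frac_active_pathways=0.34,
        effect_sd=0.5, seed=11,
    )
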