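"""Readers and writers for every external representation the pipeline touches.

All tabular formats are TSV. The expression matrix is genes x samples with a
``gene_id`` first column; sample metadata is one row per sample keyed by
``sample_id``; gene sets use the standard GMT layout (name, description,
members); results tables serialize floats with 6 significant digits and are
round-trippable at that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns every study carries; binary factors may be missing (NaN)
METADATA_COLUMNS = [
    "sample_id",
    "child_id",
    "age_years",
    "cs",
    "ab",
    "gender",
    "maternal_diabetes",
    "multiple_fdr",
    "serocon_age_years",
]

BINARY_FACTORS = ["cs", "ab", "gender", "maternal_diabetes", "multiple_fdr"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionStudy:
    """A normalized log2 expression matrix plus per-sample metadata.

    ``values`` has one row per entry of ``gene_ids`` and one column per entry
    of ``sample_ids``; ``metadata`` is indexed by sample_id in matrix column
    order. This is the unit every analysis stage consumes.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise FormatError(f"duplicated gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise FormatError(f"duplicated sample ids: {sorted(dupes)[:5]}")
        md = self.metadata
        if list(md.index) != list(self.sample_ids):
            missing = [s for s in self.sample_ids if s not in md.index]
            if missing:
                raise FormatError(
                    f"samples missing from metadata: {missing[:5]}"
                )
            md = md.loc[self.sample_ids]
        if md["child_id"].isna().any() or (md["child_id"] == "").any():
            raise FormatError("child_id must be non-empty for every sample")
        ages = md["age_years"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise FormatError("age_years must be finite and non-negative")
        for col in BINARY_FACTORS:
            if col in md:
                vals = md[col].dropna().unique()
                bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
                if bad:
                    raise FormatError(
                        f"factor {col!r} must be coded 0/1, found {bad[:3]}"
                    )
        self.metadata = md

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def factor_values(self, factor_name: str) -> np.ndarray:
        """Per-sample values of a metadata factor, NaN where missing."""
        if factor_name not in self.metadata.columns:
            raise KeyError(f"factor {factor_name!r} not in metadata")
        return self.metadata[factor_name].to_numpy(dtype=float)

    def subset_samples(self, keep: Sequence[bool] | np.ndarray) -> "ExpressionStudy":
        keep = np.asarray(keep, dtype=bool)
        sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return ExpressionStudy(
            gene_ids=list(self.gene_ids),
            sample_ids=sample_ids,
            values=self.values[:, keep],
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def drop_missing_factor(self, factor_name: str) -> "ExpressionStudy":
        """Drop samples missing a value for ``factor_name`` (logged count)."""
        x = self.factor_values(factor_name)
        keep = np.isfinite(x)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info(
                "dropping %d/%d samples with missing %s",
                n_drop, self.n_samples, factor_name,
            )
        return self.subset_samples(keep) if n_drop else self


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member gene ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def match(self, gene_ids: Sequence[str]) -> dict[str, list[str]]:
        """Resolve membership against a study's genes; unmatched are dropped
        with a logged count."""
        universe = set(gene_ids)
        matched: dict[str, list[str]] = {}
        for name, (_, members) in self.sets.items():
            hit = [g for g in members if g in universe]
            n_miss = len(members) - len(hit)
            if n_miss:
                logger.info("set %s: %d/%d members not in study",
                            name, n_miss, len(members))
            matched[name] = hit
        return matched


@dataclass
class ImmuneAnnotation:
    """A flat set of gene ids annotated as immune genes."""

    immune_gene_ids: set[str]

    def __post_init__(self) -> None:
        if not self.immune_gene_ids:
            raise FormatError("immune annotation is empty")


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionStudy:
    """Read an expression matrix TSV plus a sample-metadata TSV.

    The matrix has a ``gene_id`` first column and one column per sample;
    metadata rows are joined on ``sample_id`` and reordered to match the
    matrix column order. Any sample without a metadata row is a hard error.
    """
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", dtype={0: str})
    if mat.columns[0] != "gene_id":
        raise FormatError(
            f"first matrix column must be 'gene_id', found {mat.columns[0]!r}"
        )
    gene_ids = mat.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in mat.columns[1:]]
    body = mat.iloc[:, 1:]
    for j, col in enumerate(body.columns):
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric expression value at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}: {body[col].iloc[i]!r}"
            )
        if coerced.isna().any():
            i = int(np.flatnonzero(coerced.isna())[0])
            raise FormatError(
                f"missing expression value at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
    values = body.to_numpy(dtype=float)

    md = pd.read_csv(metadata_path, sep="\t", comment="#",
                     dtype={"sample_id": str, "child_id": str})
    required = {"sample_id", "child_id", "age_years"}
    missing_cols = required - set(md.columns)
    if missing_cols:
        raise FormatError(f"metadata missing columns: {sorted(missing_cols)}")
    if md["sample_id"].duplicated().any():
        dupes = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids in metadata: {dupes[:5]}")
    md = md.set_index("sample_id", drop=False)
    absent = [s for s in sample_ids if s not in md.index]
    if absent:
        raise FormatError(f"samples missing from metadata: {absent[:5]}")
    for col in METADATA_COLUMNS:
        if col not in md.columns and col not in ("sample_id",):
            md[col] = np.nan
    md = md.loc[sample_ids]
    return ExpressionStudy(gene_ids, sample_ids, values, md)


def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     metadata_path: str | Path, header: str | None = None) -> None:
    """Write a study to a matrix TSV and a metadata TSV (inverse of
    :func:`read_expression` up to float precision)."""
    mat = pd.DataFrame(study.values, columns=study.sample_ids)
    mat.insert(0, "gene_id", study.gene_ids)
    _write_tsv(mat, matrix_path, header=header, float_format="%.12g")
    md = study.metadata.reset_index(drop=True)
    cols = [c for c in METADATA_COLUMNS if c in md.columns]
    _write_tsv(md[cols], metadata_path, header=header, float_format="%.12g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, [m for m in members if m])
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_immune_list(path: str | Path) -> ImmuneAnnotation:
    """Read an immune-gene annotation file, one gene id per line."""
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    return ImmuneAnnotation(ids)


def write_results_table(records: pd.DataFrame, path: str | Path,
                        header: str | None = None) -> None:
    """Write a results table (GeneFit or PathwayResult rows) as TSV.

    Floats are serialized with 6 significant digits; row order is the input
    order, so output is deterministic.
    """
    _write_tsv(records, path, header=header, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None,
               float_format: str) -> None:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=float_format)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes
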