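"""Readers, writers and validators for the tabular formats the pipeline touches.

The in-memory containers are deliberately plain:

* **expression matrix** — :class:`pandas.DataFrame`, genes in rows (unique
  symbols as the index), samples in columns, log2-scale values.
* **clinical table** — :class:`pandas.DataFrame` indexed by ``sample_id``
  with ``os_time`` (non-negative, cohort-supplied unit), ``os_event``
  (0/1) and arbitrary covariate columns. Missing covariate values are kept
  as NaN and handled complete-case downstream.
* **mutation table** — long :class:`pandas.DataFrame` with columns
  ``sample_id``, ``gene``, ``variant_class``.
* **gene sets** — :class:`GeneSetCollection`, an ordered name → gene-list
  mapping parsed from GMT.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "collapse_duplicate_genes",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "read_gmt",
    "write_gmt",
    "load_packaged_gene_sets",
    "align_cohort",
]


class GeneSetCollection(Mapping):
    """Ordered collection of named, non-empty gene sets.

    Parameters
    ----------
    sets
        Mapping of set name to an iterable of gene symbols. Within-set
        duplicates are dropped (first occurrence wins) with a warning.
    descriptions
        Optional mapping of set name to a free-text description.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in sets.items():
            if name in self._sets:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(list(genes)):
                logger.warning("gene set %r contains duplicate genes; deduplicated", name)
            if not unique:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[name] = unique
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        missing = [n for n in names if n not in self._sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection({n: self._sets[n] for n in names}, self.descriptions)


def _default_sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, log_transform: bool = False, sep: str | None = None) -> pd.DataFrame:
    """Read a gene × sample expression table.

    The first column holds gene symbols; the remaining columns are samples.
    With ``log_transform=True`` the values are treated as non-negative raw
    intensities and mapped through ``log2(x + 1)``. Duplicate gene symbols
    are collapsed by keeping the row with the highest mean expression.

    Raises
    ------
    ValueError
        On an empty matrix, non-numeric cells, non-finite values, or
        negative values when ``log_transform`` is requested.
    """
    df = pd.read_csv(path, sep=sep or _default_sep(path), index_col=0, comment="#", float_precision="round_trip")
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in expression matrix {path}: {exc}") from exc
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"non-finite values in expression matrix {path}")
    if log_transform:
        if (df.to_numpy() < 0).any():
            raise ValueError("negative values are incompatible with log2(x+1) transform")
        df = np.log2(df + 1.0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    return collapse_duplicate_genes(df)


def collapse_duplicate_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols, keeping the max-mean-expression row.

    Row order of the surviving rows is preserved; applying the collapse to an
    already-unique matrix is a no-op.
    """
    if not expr.index.duplicated().any():
        return expr
    means = expr.mean(axis=1).to_numpy()
    keep = np.zeros(len(expr), dtype=bool)
    best: dict[str, int] = {}
    for i, gene in enumerate(expr.index):
        j = best.get(gene)
        if j is None or means[i] > means[j]:
            best[gene] = i
    keep[list(best.values())] = True
    n_dropped = (~keep).sum()
    logger.warning("collapsed %d duplicate gene rows (kept max-mean rows)", n_dropped)
    return expr.iloc[np.flatnonzero(keep)]


def write_expression(expr: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write an expression matrix as TSV (full float precision)."""
    _write_table(expr, path, index_label="gene", header_comment=header_comment)


def read_clinical(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a per-sample clinical table.

    Requires columns ``sample_id``, ``os_time`` and ``os_event``; everything
    else is carried along as covariates. Missing covariate values stay NaN.
    """
    df = pd.read_csv(path, sep=sep or _default_sep(path), comment="#", float_precision="round_trip")
    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    df = df.set_index("sample_id")
    df["os_time"] = df["os_time"].astype(float)
    if (df["os_time"] < 0).any():
        raise ValueError("negative os_time values")
    events = df["os_event"].astype(float)
    if not np.isin(events.dropna(), [0.0, 1.0]).all():
        raise ValueError("os_event must be binary 0/1")
    df["os_event"] = events.astype(int)
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    _write_table(clin, path, index_label="sample_id", header_comment=header_comment)


def read_mutations(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a MAF-like long mutation table (sample_id, gene, variant_class)."""
    df = pd.read_csv(path, sep=sep or _default_sep(path), comment="#")
    required = {"sample_id", "gene", "variant_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return df.astype({"sample_id": str, "gene": str, "variant_class": str})


def write_mutations(mut: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    _write_table(mut, path, index_label=None, header_comment=header_comment)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes; tab-separated).

    Set order is preserved; within-set duplicate genes are dropped with a
    warning; an empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        return GeneSetCollection({})
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection | Mapping[str, Iterable[str]], path: str | Path) -> None:
    descriptions = getattr(sets, "descriptions", {})
    with open(path, "w") as fh:
        for name in sets:
            desc = descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")


def load_packaged_gene_sets(which: str = "immune") -> GeneSetCollection:
    """Load a GMT shipped with the package.

    ``which`` is ``"immune"`` (APM/CYT/IFNG6/GEP/cancer-immunity-cycle/
    immune-cell sets) or ``"tme"`` (ESTIMATE-style immune & stromal stand-in
    lists).
    """
    from importlib.resources import files

    names = {"immune": "immune_signatures.gmt", "tme": "tme_signatures_synthetic.gmt"}
    if which not in names:
        raise ValueError(f"unknown packaged collection {which!r}; choose from {sorted(names)}")
    return read_gmt(str(files("gbpscore.data").joinpath(names[which])))


def align_cohort(expr: pd.DataFrame, clin: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict expression and clinical tables to their shared samples.

    Both outputs follow the expression matrix's column order restricted to
    the intersection. The number of dropped samples is logged.
    """
    shared = [s for s in expr.columns if s in set(clin.index)]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    dropped = (expr.shape[1] - len(shared)) + (len(clin) - len(shared))
    if dropped:
        logger.info("align_cohort dropped %d unmatched samples", dropped)
    return expr.loc[:, shared], clin.loc[shared]


def _write_table(df: pd.DataFrame, path: str | Path, index_label: str | None, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # %.17g round-trips float64 exactly
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label, float_format="%.17g")
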