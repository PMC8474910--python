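"""Reading, writing and cross-validation of the three pipeline inputs.

Formats
-------
* Trees: newick (via dendropy); polytomies, inner labels and zero-length
  branches are preserved.
* Presence/absence matrices: either a Roary-style CSV whose first two
  columns are ``Gene`` and ``Annotation`` followed by one column of locus
  tags per strain, or a plain binary TSV (genes in rows, strain ids in the
  header, cells literally 0/1).
* Phenotypes: a replicate-level TSV with header
  ``strain  replicate  offspring  [cfu]  [weight]  [treatment]``.

Strain-id matching across the three sources is exact string match after
stripping surrounding whitespace; no fuzzy matching is attempted because a
silent mismatch would corrupt the group means that feed the association
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import StrainTree

__all__ = [
    "PAMatrix",
    "PhenotypeTable",
    "ValidationReport",
    "read_pa_matrix",
    "write_pa_matrix",
    "read_tree",
    "write_tree",
    "read_phenotypes",
    "write_phenotypes",
    "validate_inputs",
]

log = logging.getLogger(__name__)

PHENO_COLUMNS = ("strain", "replicate", "offspring")
PHENO_OPTIONAL = ("cfu", "weight", "treatment")


@dataclass
class PAMatrix:
    """Binary gene-cluster x strain presence/absence table.

    ``values`` is a genes-by-strains DataFrame of 0/1 (int8); ``annotations``
    optionally carries one free-text annotation string per gene (as in a
    Roary/panX export).
    """

    values: pd.DataFrame
    annotations: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate strain ids in matrix header")
        if self.values.shape[1] == 0:
            raise ValueError("presence/absence matrix has no strains")
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence/absence values must be 0/1")
        self.values = self.values.astype(np.int8)
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.columns = self.values.columns.astype(str).str.strip()
        self.values.index.name = "gene"
        self.values.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    def annotation_of(self, gene: str) -> str:
        if self.annotations is None:
            return ""
        return str(self.annotations.get(gene, "") or "")

    def subset_strains(self, strains: list[str]) -> "PAMatrix":
        return PAMatrix(self.values[strains].copy(), self.annotations)


@dataclass
class PhenotypeTable:
    """Replicate-level host measurements keyed by strain.

    Always replicate-level: strain means and medians are computed on demand
    so that the definition of every summary statistic stays auditable.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = self.df.copy()
        df["strain"] = df["strain"].astype(str).str.strip()
        off = df["offspring"]
        if (off < 0).any():
            raise ValueError("offspring counts must be >= 0")
        if not np.allclose(off, np.round(off)):
            raise ValueError("offspring counts must be integers")
        df["offspring"] = off.astype(np.int64)
        if "cfu" in df.columns and (df["cfu"].dropna() < 0).any():
            raise ValueError("cfu must be >= 0")
        self.df = df

    @property
    def strains(self) -> list[str]:
        return sorted(self.df["strain"].unique())

    def strain_means(self, column: str = "offspring") -> pd.Series:
        return self.df.groupby("strain")[column].mean()

    def strain_medians(self, column: str = "offspring") -> pd.Series:
        return self.df.groupby("strain")[column].median()

    def subset_strains(self, strains: list[str]) -> "PhenotypeTable":
        keep = self.df["strain"].isin(set(strains))
        return PhenotypeTable(self.df.loc[keep].reset_index(drop=True))


@dataclass
class ValidationReport:
    """Cross-reference report for a (tree, matrix, phenotype) triple."""

    analysis_strains: list[str]
    missing_from_tree: list[str] = field(default_factory=list)
    missing_from_matrix: list[str] = field(default_factory=list)
    missing_from_phenotypes: list[str] = field(default_factory=list)
    n_genes: int = 0
    n_invariant_genes: int = 0
    scoreable_genes: list[str] = field(default_factory=list)

    @property
    def flagged_strains(self) -> list[str]:
        return sorted(
            set(self.missing_from_tree)
            | set(self.missing_from_matrix)
            | set(self.missing_from_phenotypes)
        )


# ----------------------------------------------------------------------
# trees


def read_tree(path: str | Path) -> StrainTree:
    """Read a newick tree; duplicate tip labels are a hard error."""
    text = Path(path).read_text()
    return StrainTree.from_newick(text)


def write_tree(tree: StrainTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
# presence/absence matrices


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    first = [c.strip().strip('"') for c in header.split(",")[:2]]
    if first[:1] == ["Gene"] and (len(first) < 2 or first[1] == "Annotation"):
        return "roary_csv"
    return "binary_tsv"


def read_pa_matrix(path: str | Path, dialect: str | None = None) -> PAMatrix:
    """Load a presence/absence matrix.

    ``dialect`` is ``"roary_csv"``, ``"binary_tsv"`` or ``None`` (sniffed
    from the header). In the Roary dialect any non-empty locus-tag cell —
    including multi-copy, semicolon-separated entries — binarizes to 1; in
    the binary dialect every cell must literally be 0 or 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _sniff_dialect(path)
    if dialect == "roary_csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(raw.columns[:2]) != ["Gene", "Annotation"]:
            raise ValueError(
                "Roary dialect requires leading columns 'Gene','Annotation'"
            )
        genes = raw["Gene"].astype(str).str.strip()
        if genes.duplicated().any():
            raise ValueError(
                f"duplicate gene ids: {list(genes[genes.duplicated()])[:5]}"
            )
        strains = list(raw.columns[2:])
        presence = (
            raw[strains].apply(lambda s: s.str.strip() != "").astype(np.int8)
        )
        presence.index = genes
        ann = raw.set_index(genes)["Annotation"]
        return PAMatrix(presence, ann)
    if dialect == "binary_tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
        bad = ~raw.isin(["0", "1"])
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-binary cell at gene {raw.index[r]!r}, "
                f"strain {raw.columns[c]!r}: {raw.iat[r, c]!r}"
            )
        return PAMatrix(raw.astype(np.int8))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_pa_matrix(
    pa: PAMatrix, path: str | Path, dialect: str = "binary_tsv"
) -> None:
    path = Path(path)
    if dialect == "binary_tsv":
        out = pa.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
    elif dialect == "roary_csv":
        ann = (
            pa.annotations.reindex(pa.genes).fillna("")
            if pa.annotations is not None
            else pd.Series("", index=pa.genes)
        )
        out = pd.DataFrame({"Gene": pa.genes, "Annotation": ann.to_numpy()})
        for s in pa.strains:
            col = pa.values[s].to_numpy()
            out[s] = np.where(col == 1, [f"{g}_{s}" for g in pa.genes], "")
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ----------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# cross-validation


def validate_inputs(
    tree: StrainTree, pa: PAMatrix, pheno: PhenotypeTable
) -> ValidationReport:
    """Cross-reference the three inputs and define the analysis strain set.

    The analysis set is the intersection of tree tips, matrix strains and
    phenotyped strains; strains missing from any source are flagged, not
    dropped silently. Genes invariant (all-0 or all-1) over the analysis
    set cannot be scored and are counted here; fewer than 3 shared strains,
    or no variable gene at all, is a hard error.
    """
    tips = set(tree.tip_labels)
    mat = set(pa.strains)
    phe = set(pheno.strains)
    shared = sorted(tips & mat & phe)
    union = tips | mat | phe
    report = ValidationReport(
        analysis_strains=shared,
        missing_from_tree=sorted(union - tips),
        missing_from_matrix=sorted(union - mat),
        missing_from_phenotypes=sorted(union - phe),
        n_genes=len(pa.genes),
    )
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} strains shared between tree, matrix and "
            "phenotypes; need at least 3"
        )
    sub = pa.values[shared]
    counts = sub.sum(axis=1)
    variable = (counts > 0) & (counts < len(shared))
    report.n_invariant_genes = int((~variable).sum())
    report.scoreable_genes = list(sub.index[variable])
    if not report.scoreable_genes:
        raise ValueError("nothing to test: all genes invariant over analysis strains")
    if report.n_invariant_genes:
        log.info(
            "%d invariant genes excluded from scoring (of %d)",
            report.n_invariant_genes,
            report.n_genes,
        )
    if report.flagged_strains:
        log.warning("strains missing from some source: %s", report.flagged_strains)
    return report
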