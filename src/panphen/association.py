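"""Presence/absence association scores and their null distributions.

The association score for gene g is

    score_g = sqrt(n_g) * D_g / sigma

where ``D_g`` is the difference in mean host phenotype (offspring per
female) between strains carrying and lacking the gene, ``sigma`` is the
global phenotype standard deviation, and ``n_g`` is the minimum number of
gain/loss events explaining the gene's distribution on the strain
phylogeny. Weighting by ``sqrt(n_g)`` up-ranks genes whose pattern arose
repeatedly (high homoplasy), which discounts the strong gene-to-gene
correlation that vertical descent imposes on pan-genome presence/absence
patterns: two genes with identical histories necessarily receive identical
scores, and only independent arrivals add evidence.

Three tree-aware companion statistics (terminal, simultaneous, subsequent)
adapt the treeWAS score family to a continuous phenotype, with empirical
p-values from genotype vectors simulated under the observed homoplasy
(``n_g`` events placed on branches with probability proportional to branch
length). A strain-label permutation test provides the model-free null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import _rng
from .ancestral_events import (
    event_counts,
    parsimony_node_states,
    squared_change_reconstruction,
)
from .data_io import PAMatrix, PhenotypeTable, validate_inputs
from .tree import StrainTree

__all__ = [
    "AssociationResult",
    "AssociationTable",
    "pa_score",
    "score_all",
    "permutation_test",
    "tree_null_scores",
    "fdr_adjust",
    "run_gwas",
    "SIGMA_MODES",
]

SIGMA_MODES = ("strain-means", "replicates")

RESULT_COLUMNS = [
    "gene",
    "annotation",
    "D_g",
    "sigma",
    "n_g",
    "pa_score",
    "perm_p",
    "terminal_p",
    "simultaneous_p",
    "subsequent_p",
    "q",
]

# comparisons of permuted/simulated statistics against the observed one use
# a small slack so exact float ties count as "at least as extreme"
_TIE_EPS = 1e-12


@dataclass
class AssociationResult:
    """Per-gene association record."""

    gene: str
    annotation: str
    d_g: float
    sigma: float
    n_g: int
    pa_score: float
    perm_p: float | None = None
    terminal_p: float | None = None
    simultaneous_p: float | None = None
    subsequent_p: float | None = None
    q: float | None = None


def pa_score(
    strain_means: Mapping[str, float],
    presence: Mapping[str, int],
    n_g: int,
    sigma: float,
) -> float:
    """sqrt(n_g) * (mean with gene - mean without gene) / sigma, signed."""
    if sigma == 0:
        raise ValueError("degenerate phenotype: sigma is zero")
    if n_g < 1:
        raise ValueError("n_g must be >= 1 for a scoreable gene")
    with_g = [strain_means[s] for s in strain_means if presence[s] == 1]
    without = [strain_means[s] for s in strain_means if presence[s] == 0]
    if not with_g or not without:
        raise ValueError("both presence groups must be non-empty")
    d_g = float(np.mean(with_g) - np.mean(without))
    return float(np.sqrt(n_g) * d_g / sigma)


class AssociationTable:
    """Scored genes plus the aligned arrays the null machinery reuses.

    Built by :func:`score_all`; :func:`permutation_test` and
    :func:`tree_null_scores` fill in the p-value columns in place.
    """

    def __init__(
        self,
        tree: StrainTree,
        strains: list[str],
        genes: list[str],
        annotations: list[str],
        presence: np.ndarray,
        strain_means: np.ndarray,
        sigma: float,
        sigma_mode: str,
        n_g: np.ndarray,
    ) -> None:
        self.tree = tree
        self.strains = strains
        self.genes = genes
        self.annotations = annotations
        self.presence = presence  # (G, S) int8, columns ordered like strains
        self.strain_means = strain_means  # (S,)
        self.sigma = sigma
        self.sigma_mode = sigma_mode
        self.n_g = n_g
        n1 = presence.sum(axis=1)
        n0 = presence.shape[1] - n1
        self.d_g = presence @ strain_means / n1 - (1 - presence) @ strain_means / n0
        self.scores = np.sqrt(n_g) * self.d_g / sigma
        g = len(genes)
        self.perm_p = np.full(g, np.nan)
        self.terminal_p = np.full(g, np.nan)
        self.simultaneous_p = np.full(g, np.nan)
        self.subsequent_p = np.full(g, np.nan)
        self.q = np.full(g, np.nan)

    def __len__(self) -> int:
        return len(self.genes)

    def results(self) -> list[AssociationResult]:
        def opt(x: float) -> float | None:
            return None if np.isnan(x) else float(x)

        return [
            AssociationResult(
                gene=self.genes[i],
                annotation=self.annotations[i],
                d_g=float(self.d_g[i]),
                sigma=float(self.sigma),
                n_g=int(self.n_g[i]),
                pa_score=float(self.scores[i]),
                perm_p=opt(self.perm_p[i]),
                terminal_p=opt(self.terminal_p[i]),
                simultaneous_p=opt(self.simultaneous_p[i]),
                subsequent_p=opt(self.subsequent_p[i]),
                q=opt(self.q[i]),
            )
            for i in range(len(self))
        ]

    def frame(self) -> pd.DataFrame:
        """Results table sorted by |score| descending, gene id on ties."""
        df = pd.DataFrame(
            {
                "gene": self.genes,
                "annotation": self.annotations,
                "D_g": self.d_g,
                "sigma": self.sigma,
                "n_g": self.n_g,
                "pa_score": self.scores,
                "perm_p": self.perm_p,
                "terminal_p": self.terminal_p,
                "simultaneous_p": self.simultaneous_p,
                "subsequent_p": self.subsequent_p,
                "q": self.q,
            }
        )
        df["_abs"] = df["pa_score"].abs()
        df = df.sort_values(["_abs", "gene"], ascending=[False, True], kind="mergesort")
        return df.drop(columns="_abs").reset_index(drop=True)


def _global_sigma(
    pheno: PhenotypeTable, strains: list[str], mode: str
) -> float:
    if mode == "strain-means":
        vals = pheno.strain_means().loc[strains].to_numpy()
    elif mode == "replicates":
        df = pheno.df
        vals = df.loc[df["strain"].isin(set(strains)), "offspring"].to_numpy()
    else:
        raise ValueError(f"unknown sigma mode {mode!r}; use one of {SIGMA_MODES}")
    sigma = float(np.std(vals, ddof=1))
    if sigma == 0:
        raise ValueError("degenerate phenotype: sigma is zero")
    return sigma


def score_all(
    tree: StrainTree,
    pa: PAMatrix,
    pheno: PhenotypeTable,
    sigma_mode: str = "strain-means",
) -> AssociationTable:
    """Score every gene variable over the shared strain set.

    Inputs are cross-validated first; the analysis runs on the intersection
    of tree tips, matrix strains and phenotyped strains, with invariant
    genes excluded. ``sigma`` is computed once, globally, from either the
    per-strain mean offspring (default) or the pooled replicates.
    """
    report = validate_inputs(tree, pa, pheno)
    analysis = report.analysis_strains
    ptree = tree.prune_to(analysis)
    strains = ptree.tip_labels  # tree tip order over the analysis set
    sub = pa.values.loc[report.scoreable_genes, strains]
    presence = sub.to_numpy()
    means = pheno.strain_means().loc[strains].to_numpy()
    sigma = _global_sigma(pheno, strains, sigma_mode)
    n_g = event_counts(ptree, presence.T)
    annotations = [pa.annotation_of(g) for g in report.scoreable_genes]
    return AssociationTable(
        tree=ptree,
        strains=strains,
        genes=list(report.scoreable_genes),
        annotations=annotations,
        presence=presence,
        strain_means=means,
        sigma=sigma,
        sigma_mode=sigma_mode,
        n_g=n_g,
    )


def permutation_test(
    table: AssociationTable, n_perm: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Strain-label permutation p-values for every scored gene.

    Per-strain mean phenotypes are shuffled across strain labels while the
    tree and matrix stay fixed — the minimal exchangeable null at the unit
    of the design (the strain). ``p = (1 + #{|score*| >= |score|}) /
    (1 + n_perm)`` per the add-one rule; sigma is re-derived per
    permutation, which for either definition equals the observed sigma
    because permutation only relabels which strain carries which values.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = _rng.stage_rng(seed, _rng.STAGE_PERMUTATION)
    m = table.strain_means
    perms = rng.permuted(np.tile(m, (n_perm, 1)), axis=1)  # (n_perm, S)
    p1 = table.presence
    n1 = p1.sum(axis=1)
    n0 = p1.shape[1] - n1
    d_star = (p1 @ perms.T) / n1[:, None] - ((1 - p1) @ perms.T) / n0[:, None]
    scores_star = np.sqrt(table.n_g)[:, None] * d_star / table.sigma
    exceed = (
        np.abs(scores_star) >= np.abs(table.scores)[:, None] - _TIE_EPS
    ).sum(axis=1)
    table.perm_p = (1.0 + exceed) / (1.0 + n_perm)
    table.q = fdr_adjust(table.perm_p)
    return table.perm_p


# ----------------------------------------------------------------------
# tree-aware statistics


def _branch_geometry(tree: StrainTree):
    parents = tree.parent[1:]
    lengths = tree.resolved_lengths(default=1.0, zero_eps=None)[1:]
    total = lengths.sum()
    rel = lengths / total if total > 0 else np.full_like(lengths, 1.0 / len(lengths))
    # ancestor-path indicator: pathmat[v, e] == 1 iff edge e lies on the
    # root-to-v path (edges indexed by child node - 1)
    n = tree.n_nodes
    pathmat = np.zeros((n, n - 1), dtype=np.int8)
    for v in range(1, n):
        pathmat[v] = pathmat[tree.parent[v]]
        pathmat[v, v - 1] = 1
    return parents, rel, pathmat


def _abs_corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| between each row of x and the vector y; 0 if a row is flat."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        return np.zeros(x.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    return np.abs(np.where(sx > 0, r, 0.0))


def tree_statistics(
    tree: StrainTree, presence: np.ndarray, strain_means: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (terminal, simultaneous, subsequent) statistics per gene.

    ``presence`` is (G, S) with strains in tree tip order. Terminal is the
    absolute tip-level correlation between presence and strain means;
    simultaneous pairs the parsimony genotype change on each branch with
    the reconstructed phenotype change; subsequent integrates reconstructed
    genotype state against phenotype change, weighted by relative branch
    length.
    """
    parents, rel, _ = _branch_geometry(tree)
    node_y = squared_change_reconstruction(tree, strain_means)
    dy = node_y[1:] - node_y[parents]
    states = parsimony_node_states(tree, presence.T)  # (n_nodes, G)
    dx = (states[1:] - states[parents]).astype(float)
    xbar = (states[1:] + states[parents]) / 2.0
    terminal = _abs_corr_rows(presence.astype(float), strain_means)
    simultaneous = np.abs(dy @ dx)
    subsequent = np.abs((rel * dy) @ xbar)
    return terminal, simultaneous, subsequent


def tree_null_scores(
    table: AssociationTable, n_sims: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Simulation-based p-values for the three tree-aware statistics.

    For each observed homoplasy count ``n_g``, ``n_sims`` genotype vectors
    are generated by dropping ``n_g`` state-flip events on branches with
    probability proportional to branch length (root state fair Bernoulli),
    so the null preserves both the tree and the gene's amount of homoplasy.
    All genes sharing an ``n_g`` share one null sample. Empirical p-values
    use the add-one rule.
    """
    if n_sims < 99:
        raise ValueError("n_sims must be >= 99")
    rng = _rng.stage_rng(seed, _rng.STAGE_TREE_NULL)
    tree = table.tree
    parents, rel, pathmat = _branch_geometry(tree)
    node_y = squared_change_reconstruction(tree, table.strain_means)
    dy = node_y[1:] - node_y[parents]
    w_dy = rel * dy
    obs_term, obs_sim, obs_sub = tree_statistics(
        tree, table.presence, table.strain_means
    )
    lengths = tree.resolved_lengths(default=1.0)[1:]
    total = lengths.sum()
    pvals = (
        lengths / total if total > 0 else np.full_like(lengths, 1.0 / len(lengths))
    )
    tip_nodes = tree.tip_nodes
    term_p = np.empty(len(table))
    sim_p = np.empty(len(table))
    sub_p = np.empty(len(table))
    for k in np.unique(table.n_g):
        events = rng.multinomial(int(k), pvals, size=n_sims)  # (n_sims, E)
        root = rng.integers(0, 2, size=(n_sims, 1), dtype=np.int8)
        parity = (events @ pathmat.T) % 2  # (n_sims, n_nodes)
        st = (root ^ parity.astype(np.int8)).astype(np.int8)
        dxs = (st[:, 1:] - st[:, parents]).astype(float)
        xbars = (st[:, 1:] + st[:, parents]) / 2.0
        null_term = _abs_corr_rows(
            st[:, tip_nodes].astype(float), table.strain_means
        )
        null_sim = np.abs(dxs @ dy)
        null_sub = np.abs(xbars @ w_dy)
        sel = np.flatnonzero(table.n_g == k)
        term_p[sel] = (
            1.0 + (null_term[None, :] >= obs_term[sel, None] - _TIE_EPS).sum(axis=1)
        ) / (1.0 + n_sims)
        sim_p[sel] = (
            1.0 + (null_sim[None, :] >= obs_sim[sel, None] - _TIE_EPS).sum(axis=1)
        ) / (1.0 + n_sims)
        sub_p[sel] = (
            1.0 + (null_sub[None, :] >= obs_sub[sel, None] - _TIE_EPS).sum(axis=1)
        ) / (1.0 + n_sims)
    table.terminal_p = term_p
    table.simultaneous_p = sim_p
    table.subsequent_p = sub_p
    return pd.DataFrame(
        {
            "gene": table.genes,
            "terminal_p": term_p,
            "simultaneous_p": sim_p,
            "subsequent_p": sub_p,
        }
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def run_gwas(
    tree: StrainTree,
    pa: PAMatrix,
    pheno: PhenotypeTable,
    n_perm: int = 10_000,
    n_null_sims: int = 1000,
    sigma_mode: str = "strain-means",
    seed: int = 0,
) -> pd.DataFrame:
    """Full association pipeline; returns the sorted per-gene results table."""
    table = score_all(tree, pa, pheno, sigma_mode=sigma_mode)
    permutation_test(table, n_perm=n_perm, seed=seed)
    tree_null_scores(table, n_sims=n_null_sims, seed=seed)
    return table.frame()
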