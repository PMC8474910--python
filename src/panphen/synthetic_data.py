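"""Synthetic pan-genome datasets with known ground truth.

Generates the statistical structure the association analysis assumes:

* a strain phylogeny (pure-birth/Yule, rescaled to unit depth, or a
  user-supplied newick);
* a gene presence/absence matrix in which each gene evolves independently
  down the tree as a two-state continuous-time Markov chain (gain
  ``0 -> 1`` at rate ``a``, loss ``1 -> 0`` at rate ``b`` per unit branch
  length, root state Bernoulli(pi0)), with the *true* number of state-flip
  events per gene recorded — parsimony counts can then be checked against
  this lower-bounded truth;
* replicate-level offspring counts per strain: the strain mean is
  ``mu0 + sum_causal beta * presence + Normal(0, tau^2)`` (clamped at a
  small positive floor) and replicates are negative-binomial around it,
  since the phenotype is a count with overdispersion between vials.

Default rates and sample sizes mirror a mono-association fitness assay
over a small panel of closely related isolates: the ``paperlike`` preset
produces 17 strains, 2,000 gene clusters and 5-13 replicates per strain,
and plants a six-gene linked "pathway block" (identical gain/loss history,
total effect split evenly) to mimic an operon-level causal pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _rng
from .data_io import (
    PAMatrix,
    PhenotypeTable,
    write_pa_matrix,
    write_phenotypes,
    write_tree,
)
from .tree import StrainTree

__all__ = [
    "SimConfig",
    "paperlike_config",
    "simulate_tree",
    "simulate_presence_absence",
    "resolve_causal_genes",
    "strain_mean_parameters",
    "simulate_phenotypes",
    "simulate_supplementation",
    "make_fixture",
]

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """All simulator knobs.

    Rates are events per unit branch length on the (unit-depth) tree;
    ``causal_genes`` lists ``(gene_index, beta)`` pairs with beta in
    offspring units — a ``None`` index means "auto-select the variable gene
    whose presence frequency is closest to 1/2 (minor group >= 3 strains,
    lowest index on ties)". With ``link_causal`` all auto-selected causal
    genes share the history of the first, emulating operon linkage.
    """

    n_strains: int = 17
    tree_newick: str | None = None  # None -> random Yule tree, unit depth
    gain_rate: float = 0.3
    loss_rate: float = 0.6
    root_presence_prob: float = 1.0 / 3.0
    n_genes: int = 2000
    causal_genes: list[tuple[int | None, float]] = field(default_factory=list)
    link_causal: bool = False
    baseline_mean: float = 40.0  # offspring per female, mu0
    strain_noise_sd: float = 4.0  # tau, offspring units
    nb_size: float = 10.0  # negative-binomial size k; large k -> Poisson
    replicates: int | tuple[int, int] = 10  # fixed, or inclusive (lo, hi) range
    mean_floor: float = 0.5  # keeps the NB mean positive
    include_covariates: bool = True  # emit cfu + weight columns
    cfu_log10_mean: float = 4.0
    cfu_log10_sd: float = 0.6
    weight_mean: float = 0.9  # mg per fly
    weight_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        # 2 tips suffice for simulator-level checks; association runs
        # enforce >= 3 strains at validate_inputs time
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        for name in ("gain_rate", "loss_rate", "strain_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.root_presence_prob <= 1.0:
            raise ValueError("root_presence_prob must lie in [0, 1]")
        if self.baseline_mean <= 0 or self.nb_size <= 0 or self.mean_floor <= 0:
            raise ValueError("baseline_mean, nb_size and mean_floor must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.replicate_range()
        if lo < 1 or hi < lo:
            raise ValueError("replicates must be >= 1 (and a valid range)")

    def replicate_range(self) -> tuple[int, int]:
        if isinstance(self.replicates, (tuple, list)):
            lo, hi = self.replicates
            return int(lo), int(hi)
        return int(self.replicates), int(self.replicates)

    # YAML mirrors the dataclass field-for-field
    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["causal_genes"] = [list(c) for c in self.causal_genes]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "causal_genes" in data:
            data["causal_genes"] = [
                (c[0], float(c[1])) for c in data["causal_genes"]
            ]
        if isinstance(data.get("replicates"), list):
            data["replicates"] = tuple(data["replicates"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def paperlike_config(seed: int = 0) -> SimConfig:
    """17 strains, 2,000 genes, 5-13 replicates, a linked 6-gene pathway.

    The six causal genes share one gain/loss history and split a total
    effect of 12 offspring (two null strain-mean SDs) evenly.
    """
    return SimConfig(
        n_strains=17,
        n_genes=2000,
        replicates=(5, 13),
        causal_genes=[(None, 2.0)] * 6,
        link_causal=True,
        seed=seed,
    )


# ----------------------------------------------------------------------
# tree simulation


def simulate_tree(cfg: SimConfig) -> StrainTree:
    """Unit-depth ultrametric pure-birth tree, or the supplied newick."""
    cfg.validate()
    if cfg.tree_newick is not None:
        return StrainTree.from_newick(cfg.tree_newick)
    rng = _rng.stage_rng(cfg.seed, _rng.STAGE_TREE)
    n = cfg.n_strains
    # grow: each active lineage splits at rate 1
    parent = [-1]
    children: list[list[int]] = [[]]
    birth = [0.0]
    active = []
    t = 0.0
    for _ in range(2):  # root bifurcates at time 0
        parent.append(0)
        children[0].append(len(parent) - 1)
        children.append([])
        birth.append(0.0)
        active.append(len(parent) - 1)
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        for _ in range(2):
            parent.append(v)
            children[v].append(len(parent) - 1)
            children.append([])
            birth.append(t)
            active.append(len(parent) - 1)
    t_final = t + rng.exponential(1.0 / n)
    end = [t_final if not children[v] else None for v in range(len(parent))]
    for v in range(len(parent) - 1, 0, -1):
        if children[v]:
            end[v] = birth[children[v][0]]
    end[0] = 0.0
    lengths = [
        np.nan if parent[v] == -1 else (end[v] - birth[v]) / t_final
        for v in range(len(parent))
    ]
    # renumber to preorder and label tips S01, S02, ... in traversal order
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    new_id = {old: i for i, old in enumerate(order)}
    width = len(str(n))
    labels: list[str | None] = [None] * len(order)
    k = 0
    for old in order:
        if not children[old]:
            k += 1
            labels[new_id[old]] = f"S{k:0{width}d}"
    return StrainTree(
        parent=[(-1 if parent[o] == -1 else new_id[parent[o]]) for o in order],
        children=[[new_id[c] for c in children[o]] for o in order],
        edge_length=[lengths[o] for o in order],
        labels=labels,
    )


# ----------------------------------------------------------------------
# gene gain/loss


def _evolve_branch(
    states: np.ndarray,
    t: float,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve all genes along one branch in place; returns event counts."""
    g = states.shape[0]
    events = np.zeros(g, dtype=np.int64)
    time_left = np.full(g, t)
    while True:
        rates = np.where(states == 0, a, b)
        with np.errstate(divide="ignore"):
            waits = np.where(rates > 0, rng.exponential(1.0, g) / rates, np.inf)
        hit = waits < time_left
        if not hit.any():
            return events
        states[hit] ^= 1
        events[hit] += 1
        time_left = np.where(hit, time_left - waits, 0.0)


def simulate_presence_absence(
    tree: StrainTree, cfg: SimConfig
) -> tuple[PAMatrix, np.ndarray]:
    """Evolve ``cfg.n_genes`` genes down the tree; returns true event counts.

    Each gene follows an independent two-state CTMC (gain rate ``a``, loss
    rate ``b``); the returned array holds the exact number of state flips
    that occurred anywhere on the tree — an upper bound on any parsimony
    count for the resulting tip pattern.
    """
    cfg.validate()
    rng = _rng.stage_rng(cfg.seed, _rng.STAGE_PRESENCE_ABSENCE)
    g = cfg.n_genes
    lengths = tree.resolved_lengths(default=1.0)
    node_states = np.empty((tree.n_nodes, g), dtype=np.int8)
    node_states[0] = rng.random(g) < cfg.root_presence_prob
    true_events = np.zeros(g, dtype=np.int64)
    for v in range(1, tree.n_nodes):
        st = node_states[tree.parent[v]].copy()
        true_events += _evolve_branch(
            st, float(lengths[v]), cfg.gain_rate, cfg.loss_rate, rng
        )
        node_states[v] = st
    width = len(str(g))
    genes = [f"g{i + 1:0{width}d}" for i in range(g)]
    values = pd.DataFrame(
        node_states[tree.tip_nodes].T, index=genes, columns=tree.tip_labels
    )
    return PAMatrix(values), true_events


def resolve_causal_genes(
    pa: PAMatrix, cfg: SimConfig, tree: StrainTree | None = None
) -> list[tuple[int, float]]:
    """Concrete (index, beta) pairs, auto-selecting ``None`` indices.

    Auto slots pick variable genes with minor-group size >= 3, preferring
    the most homoplastic pattern (highest parsimony event count on
    ``tree``) and, within that, presence frequency closest to 1/2; lowest
    index on ties; already-taken indices are skipped. Homoplastic causal
    patterns are the regime the association score targets — a causal gene
    whose pattern needs a single event is indistinguishable from clade
    identity and is down-weighted by design — and they mirror a pathway
    repeatedly lost and regained (e.g. by horizontal transfer). Without a
    tree only the frequency criterion applies.
    """
    counts = pa.values.sum(axis=1).to_numpy()
    n = len(pa.strains)
    eligible = np.flatnonzero((counts >= 3) & (counts <= n - 3))
    if eligible.size == 0:
        eligible = np.flatnonzero((counts > 0) & (counts < n))
    balance = np.abs(counts[eligible] / n - 0.5)
    if tree is not None:
        from .ancestral_events import event_counts

        cols = pa.values.iloc[eligible][tree.tip_labels].to_numpy().T
        n_g = event_counts(tree, cols)
        order = eligible[np.lexsort((eligible, balance, -n_g))]
    else:
        order = eligible[np.argsort(balance, kind="stable")]
    taken = {i for i, _ in cfg.causal_genes if i is not None}
    resolved: list[tuple[int, float]] = []
    auto_iter = (int(i) for i in order if i not in taken)
    for idx, beta in cfg.causal_genes:
        if idx is None:
            try:
                idx = next(auto_iter)
            except StopIteration:
                raise ValueError("not enough variable genes to auto-select") from None
            taken.add(idx)
        elif not 0 <= idx < len(pa.genes):
            raise ValueError(f"causal gene index {idx} out of range")
        resolved.append((int(idx), float(beta)))
    return resolved


def strain_mean_parameters(
    pa: PAMatrix, cfg: SimConfig, causal: list[tuple[int, float]] | None = None
) -> pd.Series:
    """Deterministic part of the strain means (before strain-level noise)."""
    if causal is None:
        causal = resolve_causal_genes(pa, cfg)
    base = np.full(len(pa.strains), cfg.baseline_mean)
    for idx, beta in causal:
        base += beta * pa.values.iloc[idx].to_numpy()
    return pd.Series(base, index=pa.strains)


def simulate_phenotypes(
    pa: PAMatrix, cfg: SimConfig, causal: list[tuple[int, float]] | None = None
) -> PhenotypeTable:
    """Replicate-level offspring counts (and optional CFU/weight columns).

    Strain mean = ``max(floor, mu0 + sum beta*presence + Normal(0, tau^2))``;
    replicates are negative-binomial with that mean and size ``k``. CFU is
    drawn log10-normally, independent of strain identity (a pure-noise
    covariate); weight per fly is normal around ``weight_mean``.
    """
    cfg.validate()
    if causal is None:
        causal = resolve_causal_genes(pa, cfg) if cfg.causal_genes else []
    for idx, _ in causal:
        if not 0 <= idx < len(pa.genes):
            raise ValueError(f"causal gene index {idx} out of range")
    rng = _rng.stage_rng(cfg.seed, _rng.STAGE_PHENOTYPES)
    base = strain_mean_parameters(pa, cfg, causal)
    noise = rng.normal(0.0, cfg.strain_noise_sd, len(base))
    means = base.to_numpy() + noise
    clamped = means < cfg.mean_floor
    if clamped.any():
        log.warning(
            "%d strain means clamped at the %.2f floor", clamped.sum(), cfg.mean_floor
        )
    means = np.maximum(means, cfg.mean_floor)
    lo, hi = cfg.replicate_range()
    rows = []
    k = cfg.nb_size
    for s, m in zip(pa.strains, means):
        r = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        p = k / (k + m)
        offspring = rng.negative_binomial(k, p, r)
        for j, off in enumerate(offspring, start=1):
            rows.append({"strain": s, "replicate": f"r{j}", "offspring": int(off)})
    df = pd.DataFrame(rows)
    if cfg.include_covariates:
        cov_rng = _rng.stage_rng(cfg.seed, _rng.STAGE_COVARIATES)
        df["cfu"] = np.round(
            10 ** cov_rng.normal(cfg.cfu_log10_mean, cfg.cfu_log10_sd, len(df))
        ).astype(np.int64)
        df["weight"] = np.round(
            cov_rng.normal(cfg.weight_mean, cfg.weight_sd, len(df)), 4
        )
    return PhenotypeTable(df)


def simulate_supplementation(
    n_minus: int = 3,
    n_plus: int = 4,
    replicates: int = 8,
    deficit: float = 0.30,
    lift: float = 0.30,
    baseline_mean: float = 40.0,
    strain_noise_sd: float = 4.0,
    nb_size: float = 10.0,
    seed: int = 0,
) -> tuple[PhenotypeTable, dict[str, str]]:
    """Two-arm supplementation experiment for the relative-offspring contrast.

    Pathway-negative strains start ``deficit`` below baseline; the
    supplemented arm multiplies their means by ``1 + lift`` while the
    pathway-positive controls are unaffected. Returns the replicate table
    (treatment labels ``-`` / ``+``) and the strain -> group assignment.
    """
    rng = _rng.stage_rng(seed, _rng.STAGE_PHENOTYPES)
    strains = [f"M{i + 1}" for i in range(n_minus)] + [
        f"P{i + 1}" for i in range(n_plus)
    ]
    groups = {s: ("TBP-" if s.startswith("M") else "TBP+") for s in strains}
    base = {
        s: max(
            0.5,
            baseline_mean * (1.0 - (deficit if groups[s] == "TBP-" else 0.0))
            + rng.normal(0.0, strain_noise_sd),
        )
        for s in strains
    }
    rows = []
    for treatment in ("-", "+"):
        for s in strains:
            m = base[s]
            if treatment == "+" and groups[s] == "TBP-":
                m *= 1.0 + lift
            p = nb_size / (nb_size + m)
            for j, off in enumerate(
                rng.negative_binomial(nb_size, p, replicates), start=1
            ):
                rows.append(
                    {
                        "strain": s,
                        "replicate": f"t{treatment}{j}",
                        "offspring": int(off),
                        "treatment": treatment,
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows)), groups


# ----------------------------------------------------------------------
# fixtures


def make_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic dataset to ``outdir``.

    Files: ``tree.nwk``, ``pa_matrix.tsv``, ``phenotypes.tsv`` and
    ``truth.tsv`` (per-gene true event count and causal effect). Identical
    configs produce byte-identical files.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(cfg)
    pa, true_events = simulate_presence_absence(tree, cfg)
    causal = resolve_causal_genes(pa, cfg, tree) if cfg.causal_genes else []
    if cfg.link_causal and len(causal) > 1:
        # copy the first causal gene's history onto the others: one linked
        # pathway block with identical presence patterns and event counts
        src, _ = causal[0]
        for idx, _ in causal[1:]:
            pa.values.iloc[idx] = pa.values.iloc[src].to_numpy()
            true_events[idx] = true_events[src]
    pheno = simulate_phenotypes(pa, cfg, causal)
    beta = np.zeros(len(pa.genes))
    for idx, b in causal:
        beta[idx] = b
    truth = pd.DataFrame(
        {"gene": pa.genes, "true_events": true_events, "causal_beta": beta}
    )
    paths = {
        "tree": outdir / "tree.nwk",
        "pa_matrix": outdir / "pa_matrix.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_tree(tree, paths["tree"])
    write_pa_matrix(pa, paths["pa_matrix"])
    write_phenotypes(pheno, paths["phenotypes"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
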