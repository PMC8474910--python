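"""Validation experiments run at study-design scale.

Self-contained, seed-driven experiments that measure the pipeline's
statistical behaviour under the conditions the synthetic generator
emulates: parsimony correctness against exhaustive enumeration, type-I
calibration of the permutation test, causal-gene recovery power, affine
invariance, and the parsimony lower bound against simulated truth. The
test suite asserts on these numbers and the acceptance script reports
them.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from . import association
from .ancestral_events import event_counts, fitch_count
from .data_io import PhenotypeTable
from .synthetic_data import (
    SimConfig,
    resolve_causal_genes,
    simulate_phenotypes,
    simulate_presence_absence,
    simulate_tree,
)
from .tree import StrainTree

__all__ = [
    "exhaustive_min_changes",
    "fitch_bruteforce_agreement",
    "null_strain_mean_sd",
    "type_one_error_fractions",
    "causal_recovery",
    "affine_invariance_check",
    "parsimony_bound_violations",
]


def exhaustive_min_changes(tree: StrainTree, tip_states: dict[str, int]) -> int:
    """Minimum state changes by enumerating all internal labelings.

    Independent oracle for the parsimony dynamic program; exponential in
    the number of internal nodes, so only usable on small trees.
    """
    states = np.zeros(tree.n_nodes, dtype=np.int8)
    for v, lbl in zip(tree.tip_nodes, tree.tip_labels):
        states[v] = tip_states[lbl]
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    parents = tree.parent[1:]
    best = np.inf
    for bits in product((0, 1), repeat=len(internal)):
        states[internal] = bits
        changes = int((states[1:] != states[parents]).sum())
        best = min(best, changes)
    return int(best)


def fitch_bruteforce_agreement(n_cases: int = 200, seed: int = 0) -> int:
    """Number of random (tree, pattern) cases where DP and enumeration agree.

    Trees have 3-8 tips (random pure-birth topologies); patterns are
    uniform random binary tip assignments.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_cases):
        n_tips = int(rng.integers(3, 9))
        cfg = SimConfig(n_strains=n_tips, seed=int(rng.integers(2**31)))
        tree = simulate_tree(cfg)
        pattern = {lbl: int(rng.integers(2)) for lbl in tree.tip_labels}
        if fitch_count(tree, pattern) == exhaustive_min_changes(tree, pattern):
            agree += 1
    return agree


def null_strain_mean_sd(cfg: SimConfig) -> float:
    """SD of observed strain means under beta = 0 for a generator config.

    Strain-level noise plus negative-binomial sampling noise of the
    replicate mean: sqrt(tau^2 + (mu0 + mu0^2/k) / r) at the smallest
    replicate count.
    """
    mu0, k = cfg.baseline_mean, cfg.nb_size
    r = cfg.replicate_range()[0]
    return float(np.sqrt(cfg.strain_noise_sd**2 + (mu0 + mu0**2 / k) / r))


def _simulated_dataset(cfg: SimConfig):
    tree = simulate_tree(cfg)
    pa, true_events = simulate_presence_absence(tree, cfg)
    causal = resolve_causal_genes(pa, cfg, tree) if cfg.causal_genes else []
    pheno = simulate_phenotypes(pa, cfg, causal)
    return tree, pa, pheno, causal, true_events


def type_one_error_fractions(
    seeds: tuple[int, ...] = (1, 2, 3),
    n_strains: int = 20,
    n_genes: int = 500,
    n_perm: int = 999,
) -> tuple[list[float], np.ndarray]:
    """Fraction of genes at perm_p < 0.05 in null (beta = 0) datasets.

    Returns the per-seed fractions and the pooled p-values (for
    distributional checks)."""
    fractions = []
    pooled = []
    for s in seeds:
        cfg = SimConfig(
            n_strains=n_strains, n_genes=n_genes, replicates=10,
            causal_genes=[], seed=s,
        )
        tree, pa, pheno, _, _ = _simulated_dataset(cfg)
        table = association.score_all(tree, pa, pheno)
        p = association.permutation_test(table, n_perm=n_perm, seed=s)
        fractions.append(float((p < 0.05).mean()))
        pooled.append(p)
    return fractions, np.concatenate(pooled)


def causal_recovery(
    n_sims: int = 100,
    seed: int = 20_000,
    n_strains: int = 20,
    n_genes: int = 2000,
    replicates: int = 10,
) -> tuple[int, list[int]]:
    """Top-1 recovery of a single causal gene at beta = 2 x null SD.

    One causal gene per dataset (the most homoplastic balanced pattern),
    effect two null strain-mean SDs. Rank is competition rank on
    |pa_score|: genes with strictly greater |score| count against the
    causal gene; exact ties (e.g. identical histories) do not. Returns
    (number of rank-1 datasets, all ranks).
    """
    base = SimConfig(n_strains=n_strains, n_genes=n_genes, replicates=replicates)
    beta = 2.0 * null_strain_mean_sd(base)
    wins = 0
    ranks = []
    for i in range(n_sims):
        cfg = SimConfig(
            n_strains=n_strains, n_genes=n_genes, replicates=replicates,
            causal_genes=[(None, beta)], seed=seed + i,
        )
        tree, pa, pheno, causal, _ = _simulated_dataset(cfg)
        table = association.score_all(tree, pa, pheno)
        ci = table.genes.index(pa.genes[causal[0][0]])
        a = np.abs(table.scores)
        rank = int((a > a[ci] + 1e-12).sum()) + 1
        ranks.append(rank)
        wins += rank == 1
    return wins, ranks


def affine_invariance_check(
    data_seed: int = 3, perm_seed: int = 7, n_perm: int = 499
) -> dict[str, float | bool]:
    """Effect of y -> 3y + 7 on |scores|, permutation p and ranking.

    Runs the paperlike fixture twice (raw and affinely transformed
    offspring) with the same permutation seed.
    """
    from .synthetic_data import paperlike_config

    cfg = paperlike_config(seed=data_seed)
    tree, pa, pheno, _, _ = _simulated_dataset(cfg)
    t1 = association.score_all(tree, pa, pheno)
    association.permutation_test(t1, n_perm=n_perm, seed=perm_seed)
    df = pheno.df.copy()
    df["offspring"] = 3 * df["offspring"] + 7
    t2 = association.score_all(tree, pa, PhenotypeTable(df))
    association.permutation_test(t2, n_perm=n_perm, seed=perm_seed)
    def ranking(table):
        # round away float fuzz (an affine transform rescales means and
        # sigma by the same factor only up to ~1e-15) before tie-breaking
        key = np.round(np.abs(table.scores), 9)
        order = sorted(range(len(table)), key=lambda i: (-key[i], table.genes[i]))
        return [table.genes[i] for i in order]

    return {
        "max_abs_score_shift": float(
            np.max(np.abs(np.abs(t1.scores) - np.abs(t2.scores)))
        ),
        "perm_p_identical": bool(np.array_equal(t1.perm_p, t2.perm_p)),
        "rank_order_identical": bool(ranking(t1) == ranking(t2)),
        "n_genes": len(t1),
    }


def parsimony_bound_violations(seed: int = 3, n_fixtures: int = 3) -> tuple[int, int]:
    """Genes whose parsimony count exceeds the simulated event count.

    The minimum-change count can never exceed the number of events that
    actually occurred; returns (violations, genes checked) over several
    simulated datasets.
    """
    violations = 0
    checked = 0
    for i in range(n_fixtures):
        cfg = SimConfig(n_strains=17, n_genes=500, replicates=5, seed=seed + i)
        tree = simulate_tree(cfg)
        pa, true_events = simulate_presence_absence(tree, cfg)
        cols = pa.values[tree.tip_labels].to_numpy().T
        n_g = event_counts(tree, cols)
        violations += int((n_g > true_events).sum())
        checked += len(n_g)
    return violations, checked
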