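"""Strain-group fitness contrasts.

Replicate-level offspring counts are compared across strains and between
pathway-defined strain groups:

* Kruskal-Wallis heterogeneity across all mono-associated strains;
* Mann-Whitney on per-strain *medians* between pathway-positive and
  pathway-negative groups (exact null for small strain panels);
* a linear model adjusting the strain effect for bacterial load
  (``offspring ~ strain + log10(CFU + 1)``) plus the load-only model;
* the supplementation contrast on relative offspring (each
  pathway-negative replicate divided by the mean offspring of the
  pathway-positive controls in the same treatment arm), tested with a
  linear mixed model (treatment fixed, strain random intercept);
* pairwise fold differences between strain means.

Strain medians feed the group test and strain means feed the association
score; the two conventions are kept separate deliberately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data_io import PAMatrix, PhenotypeTable

__all__ = [
    "derive_groups",
    "kruskal_across_strains",
    "group_median_test",
    "load_adjusted_model",
    "relative_offspring",
    "relative_offspring_contrast",
    "fold_difference",
    "LoadModelResult",
    "ContrastResult",
    "FoldDifference",
    "DEFAULT_PATHWAY_GENES",
]

log = logging.getLogger(__name__)

# joint presence of these genes defines the pathway-positive group by default
DEFAULT_PATHWAY_GENES = ("thiC", "thiD", "thiO", "thiS", "thiG", "thiE")


@dataclass
class LoadModelResult:
    strain_p: float
    load_p_adjusted: float
    load_only_p: float
    load_only_r2: float
    n_used: int
    n_dropped: int
    transform: str = "log10(cfu + 1)"


@dataclass
class ContrastResult:
    cell_means: pd.DataFrame  # strain x treatment means with standard errors
    treatment_effect: float
    treatment_p: float
    n_values: int
    model: str = "value ~ treatment, random intercept per strain (REML, Wald z)"


@dataclass
class FoldDifference:
    ratio: float  # >= 1 by convention
    larger: str
    smaller: str
    infinite: bool = False


def derive_groups(
    pa: PAMatrix,
    gene_set: tuple[str, ...] = DEFAULT_PATHWAY_GENES,
    positive: str = "TBP+",
    negative: str = "TBP-",
) -> dict[str, str]:
    """Strain -> group label from joint presence of a gene set (all-of)."""
    missing = [g for g in gene_set if g not in pa.values.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    complete = (pa.values.loc[list(gene_set)] == 1).all(axis=0)
    return {s: (positive if complete[s] else negative) for s in pa.strains}


def kruskal_across_strains(pheno: PhenotypeTable) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across strains."""
    groups = [
        g["offspring"].to_numpy()
        for _, g in pheno.df.groupby("strain")
        if len(g) >= 1
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 strains")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def group_median_test(
    pheno: PhenotypeTable,
    groups: dict[str, str],
    column: str = "offspring",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-strain medians between two groups.

    Uses the exact null distribution when the strain panel is small
    (<= 20 strains total), the normal approximation above that.
    """
    medians = pheno.strain_medians(column)
    labels = sorted({groups[s] for s in medians.index if s in groups})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = medians[[s for s in medians.index if groups.get(s) == labels[0]]].to_numpy()
    b = medians[[s for s in medians.index if groups.get(s) == labels[1]]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def load_adjusted_model(pheno: PhenotypeTable) -> LoadModelResult:
    """Strain effect on offspring adjusted for bacterial load, and load alone.

    Load enters as ``log10(CFU + 1)``; replicates with missing CFU are
    dropped with a log message. The strain p-value is the type-II ANOVA
    p for the strain term in ``offspring ~ strain + load``; the load-only
    p is the slope test of ``offspring ~ load``.
    """
    if "cfu" not in pheno.df.columns:
        raise ValueError("phenotype table has no cfu column")
    df = pheno.df.copy()
    n_total = len(df)
    df = df.dropna(subset=["cfu"])
    if df.empty:
        raise ValueError("all CFU values missing")
    dropped = n_total - len(df)
    if dropped:
        log.info("dropped %d replicates with missing CFU", dropped)
    df["load"] = np.log10(df["cfu"].astype(float) + 1.0)
    load_only = smf.ols("offspring ~ load", data=df).fit()
    if df["strain"].nunique() < 2:
        # no strain contrast estimable; only the load slope is defined
        return LoadModelResult(
            strain_p=float("nan"),
            load_p_adjusted=float(load_only.pvalues["load"]),
            load_only_p=float(load_only.pvalues["load"]),
            load_only_r2=float(load_only.rsquared),
            n_used=len(df),
            n_dropped=dropped,
        )
    full = smf.ols("offspring ~ C(strain) + load", data=df).fit()
    aov = anova_lm(full, typ=2)
    return LoadModelResult(
        strain_p=float(aov.loc["C(strain)", "PR(>F)"]),
        load_p_adjusted=float(aov.loc["load", "PR(>F)"]),
        load_only_p=float(load_only.pvalues["load"]),
        load_only_r2=float(load_only.rsquared),
        n_used=len(df),
        n_dropped=dropped,
    )


def relative_offspring(
    pheno: PhenotypeTable, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-replicate relative offspring of pathway-negative strains.

    Within each treatment arm, every negative-group replicate is divided
    by the mean offspring over all positive-group replicates of that arm;
    a value of one signals parity between the groups.
    """
    if "treatment" not in pheno.df.columns:
        raise ValueError("phenotype table has no treatment column")
    df = pheno.df.copy()
    df["group"] = df["strain"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "strain"].unique())
        raise ValueError(f"strains without group assignment: {missing}")
    neg, pos = sorted(df["group"].unique())  # "TBP-" < "TBP+"
    rows = []
    for treatment, arm in df.groupby("treatment"):
        ref = arm.loc[arm["group"] == pos, "offspring"]
        if ref.empty:
            raise ValueError(f"no {pos} replicates in treatment {treatment!r}")
        ref_mean = float(ref.mean())
        for _, row in arm.loc[arm["group"] == neg].iterrows():
            rows.append(
                {
                    "strain": row["strain"],
                    "treatment": treatment,
                    "value": row["offspring"] / ref_mean,
                }
            )
    if not rows:
        raise ValueError(f"no {neg} replicates found")
    return pd.DataFrame(rows)


def relative_offspring_contrast(
    pheno: PhenotypeTable, groups: dict[str, str]
) -> ContrastResult:
    """Treatment effect on relative offspring via a linear mixed model.

    Fixed effect: treatment (two levels required); random intercept per
    pathway-negative strain; REML fit with a Wald z p-value for the
    treatment coefficient. Cell means and standard errors per
    strain x treatment accompany the test.
    """
    rel = relative_offspring(pheno, groups)
    levels = sorted(rel["treatment"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 treatment levels, got {levels}")
    model = smf.mixedlm("value ~ C(treatment)", data=rel, groups=rel["strain"])
    with warnings.catch_warnings():
        # a near-zero strain variance puts REML on the boundary; the fixed
        # effect and its Wald test remain well defined
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(reml=True)
    coef_name = f"C(treatment)[T.{levels[1]}]"
    effect = float(fit.params[coef_name])
    p = float(fit.pvalues[coef_name])
    cells = (
        rel.groupby(["strain", "treatment"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    return ContrastResult(
        cell_means=cells,
        treatment_effect=effect,
        treatment_p=p,
        n_values=len(rel),
    )


def fold_difference(
    pheno: PhenotypeTable, strain_a: str, strain_b: str
) -> FoldDifference:
    """Ratio of the larger to the smaller strain mean (>= 1 by convention)."""
    means = pheno.strain_means()
    for s in (strain_a, strain_b):
        if s not in means.index:
            raise ValueError(f"strain {s!r} has no replicates")
    ma, mb = float(means[strain_a]), float(means[strain_b])
    hi, lo = (strain_a, strain_b) if ma >= mb else (strain_b, strain_a)
    top, bottom = max(ma, mb), min(ma, mb)
    if bottom == 0:
        return FoldDifference(ratio=np.inf, larger=hi, smaller=lo, infinite=True)
    return FoldDifference(ratio=top / bottom, larger=hi, smaller=lo)
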