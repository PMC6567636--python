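"""Synthetic genotype/trait generation and the outlier-robustness study.

The generators emulate a biallelic SNP study under Hardy-Weinberg
equilibrium: genotype dosages (counts of the minor allele, 0/1/2) are
i.i.d. Binomial(2, MAF) and quantitative traits are i.i.d. N(0, 1)
under the null.  Robustness is probed with a genotype-linked
contamination model: samples carrying two minor alleles draw their
trait from a N(outlier_mean, outlier_sd^2) component with probability
pi instead of N(0, 1) — a caricature of the extreme assay outliers seen
in real protein/expression data, concentrated in one genotype class so
that it biases a naive trend estimate.

The rejection-rate study runs B independent single-feature replicates
per (MAF, pi) cell, applies both the JT test and its parametric
counterpart (least-squares slope of trait on dosage, t-test with n-2
df), and reports the fraction of two-sided p-values below alpha with a
binomial Monte-Carlo standard error.  Everything is a pure function of
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .kernel import jt_test
from .scan import OrdinalFeatureMatrix, TraitMatrix

__all__ = [
    "SimulationConfig",
    "OLSResult",
    "simulate_genotypes",
    "simulate_traits_null",
    "simulate_trait_outlier",
    "ols_slope_test",
    "rejection_rate_study",
    "plot_rejection_rates",
]

#: pi grid spanning the contamination interval [0, 0.03].
DEFAULT_PI_GRID = (0.0, 0.005, 0.01, 0.015, 0.02, 0.025, 0.03)
DEFAULT_MAF_GRID = (0.2, 0.3, 0.4, 0.5)


@dataclass
class SimulationConfig:
    """Study conditions for the simulation suite.

    Defaults are the single-pair robustness setting: n=500 samples, one
    feature, one trait, nominal level 0.05, B=2000 replicates.
    """

    n: int = 500
    m: int = 1
    p: int = 1
    maf: float = 0.5
    pi: float = 0.0
    outlier_mean: float = 8.0
    outlier_sd: float = 1.0
    B: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.p, self.B) < 1:
            raise ValueError("n, m, p and B must be positive")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class OLSResult:
    """Simple linear regression slope test; fields None when undefined."""

    slope: Optional[float]
    t: Optional[float]
    p_two_sided: Optional[float]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, m: int, maf: float, seed) -> OrdinalFeatureMatrix:
    """i.i.d. Binomial(2, maf) dosage codes for m SNPs x n samples."""
    rng = _rng(seed)
    codes = rng.binomial(2, maf, size=(m, n)).astype(np.int16)
    return OrdinalFeatureMatrix(
        codes=codes,
        feature_ids=[f"snp_{i + 1}" for i in range(m)],
        sample_ids=[f"sample_{j + 1}" for j in range(n)],
        level_count=3,
    )


def simulate_traits_null(n: int, p: int, seed) -> TraitMatrix:
    """i.i.d. standard normal traits for n samples x p traits."""
    rng = _rng(seed)
    return TraitMatrix(
        values=rng.standard_normal((n, p)),
        trait_ids=[f"trait_{i + 1}" for i in range(p)],
        sample_ids=[f"sample_{j + 1}" for j in range(n)],
    )


def simulate_trait_outlier(
    genotype_codes,
    pi: float,
    outlier_mean: float = 8.0,
    outlier_sd: float = 1.0,
    seed=0,
) -> np.ndarray:
    """Trait with genotype-linked contamination.

    Samples with dosage 0 or 1 draw from N(0,1); samples with dosage 2
    draw from N(outlier_mean, outlier_sd^2) with probability ``pi``
    (binomial thinning) and from N(0,1) otherwise.
    """
    rng = _rng(seed)
    codes = np.asarray(genotype_codes)
    n = codes.size
    trait = rng.standard_normal(n)
    is_outlier = (codes == 2) & (rng.random(n) < pi)
    k = int(is_outlier.sum())
    if k:
        trait[is_outlier] = outlier_mean + outlier_sd * rng.standard_normal(k)
    return trait


def ols_slope_test(genotype, trait) -> OLSResult:
    """Least-squares slope of trait on numeric dosage, two-sided t-test.

    The parametric counterpart of the JT trend test: t = slope / SE with
    n - 2 degrees of freedom.  A constant genotype leaves the slope
    undefined (flagged with None fields); a perfect fit has zero
    residual variance and is reported as t = +/-inf, p = 0.
    """
    x = np.asarray(genotype, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return OLSResult(slope=None, t=None, p_two_sided=None)
    yc = y - y.mean()
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    s2 = float(resid @ resid) / (n - 2)
    if s2 == 0.0:
        tval = math.inf if slope > 0 else (-math.inf if slope < 0 else 0.0)
        return OLSResult(slope=slope, t=tval, p_two_sided=0.0 if slope else 1.0)
    se = math.sqrt(s2 / sxx)
    tval = slope / se
    p = 2.0 * float(t_dist.sf(abs(tval), n - 2))
    return OLSResult(slope=slope, t=tval, p_two_sided=min(p, 1.0))


def rejection_rate_study(
    mafs: Sequence[float] = DEFAULT_MAF_GRID,
    pis: Sequence[float] = DEFAULT_PI_GRID,
    n: int = 500,
    B: int = 2000,
    alpha: float = 0.05,
    outlier_mean: float = 8.0,
    outlier_sd: float = 1.0,
    seed: int = 0,
    methods: Sequence[str] = ("JT", "OLS"),
) -> pd.DataFrame:
    """Empirical rejection rates over a MAF x pi grid.

    Each cell runs B independent replicates of a single feature-trait
    pair (one Binomial(2, MAF) genotype vector, one trait under the
    contamination model), tests with each requested method at level
    ``alpha``, and reports the empirical rejection rate with its
    Monte-Carlo standard error sqrt(rate * (1 - rate) / B).

    Per-cell RNG streams are spawned from a single SeedSequence so the
    whole table is a pure function of ``seed`` and independent of the
    grid iteration order.
    """
    methods = tuple(methods)
    for meth in methods:
        if meth not in ("JT", "OLS"):
            raise ValueError(f"unknown method {meth!r}")
    cells = [(maf, pi) for maf in mafs for pi in pis]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (maf, pi), ss in zip(cells, children):
        rng = np.random.default_rng(ss)
        rej = {meth: 0 for meth in methods}
        for _ in range(B):
            geno = rng.binomial(2, maf, size=n)
            trait = simulate_trait_outlier(
                geno, pi, outlier_mean, outlier_sd, seed=rng
            )
            if "JT" in rej:
                out = jt_test(trait, geno)
                if out.p_two_sided is not None and out.p_two_sided < alpha:
                    rej["JT"] += 1
            if "OLS" in rej:
                ols = ols_slope_test(geno, trait)
                if ols.p_two_sided is not None and ols.p_two_sided < alpha:
                    rej["OLS"] += 1
        for meth in methods:
            rate = rej[meth] / B
            rows.append(
                {
                    "method": meth,
                    "maf": maf,
                    "pi": pi,
                    "empirical_rate": rate,
                    "B": B,
                    "mc_stderr": math.sqrt(rate * (1.0 - rate) / B),
                }
            )
    return pd.DataFrame(rows)


def plot_rejection_rates(table: pd.DataFrame, path) -> None:
    """One panel per MAF: rejection rate vs pi for each method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mafs = sorted(table["maf"].unique())
    fig, axes = plt.subplots(
        1, len(mafs), figsize=(3.2 * len(mafs), 3.0), sharey=True, squeeze=False
    )
    for ax, maf in zip(axes[0], mafs):
        sub = table[table["maf"] == maf]
        for meth, grp in sub.groupby("method"):
            grp = grp.sort_values("pi")
            ax.plot(grp["pi"], grp["empirical_rate"], marker="o", label=meth)
        ax.axhline(0.05, color="red", lw=1)
        ax.set_title(f"MAF = {maf}")
        ax.set_xlabel("outlier proportion pi")
    axes[0][0].set_ylabel("empirical rejection rate")
    axes[0][-1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
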