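"""Multi-trait GWAS simulator.

Generates K correlated quantitative traits from a shared SNP panel:
effect vectors beta_j for the C causal SNPs are drawn from N_K(0, D)
with d_kk = h2_k / C and d_lm = rho_lm sqrt(d_ll d_mm), non-causal
effects are exactly zero, and phenotypes follow
y_ki = sum_j x_kij beta_kj + e_ki with e_ki ~ N(0, 1 - h2_k) on
standardized genotypes, so var(y) = 1 and the genetic variance equals
h2_k by construction.

Genotypes are hard-call dosages binomial(2, MAF) with per-SNP MAF drawn
uniformly from ``maf_range``; by default SNPs are independent (no LD).
An optional block-autoregressive mode correlates haplotypes within
windows for stress-testing partitioned updates. Real cohorts differ in
both respects (empirical MAF spectrum, pervasive LD), which is the main
caveat when reading simulation results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ctpr.harmonize import marginal_effects
from ctpr.io_formats import GenotypeMatrix, SummaryStatSet, TraitSet, standardize
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "build_covariance",
    "simulate_effects",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_sumstats",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    Defaults give two traits measured on disjoint cohorts of 2000, a
    1000-SNP panel with 50 fully shared causal SNPs, heritabilities
    0.45 (primary) and 0.25 (secondary), and effect correlation 0.75 —
    a desk-scale replica of a biobank two-trait design with a strongly
    genetically correlated helper trait.
    """

    K: int = 2
    P: int = 1000
    C: int = 50
    n: tuple = (2000, 2000)
    h2: tuple = (0.45, 0.25)
    rho: float | np.ndarray = 0.75
    maf_range: tuple = (0.05, 0.5)
    shared_causal_fraction: float = 1.0
    overlap: bool = False
    seed: int = 0
    ld_block_size: int | None = None
    ld_rho: float = 0.0

    def rho_matrix(self) -> np.ndarray:
        if np.isscalar(self.rho):
            R = np.full((self.K, self.K), float(self.rho))
            np.fill_diagonal(R, 1.0)
            return R
        R = np.asarray(self.rho, dtype=np.float64)
        if R.shape != (self.K, self.K):
            raise ValueError(f"rho must be scalar or {self.K}x{self.K}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("rho must be symmetric with unit diagonal")
        return R

    def __post_init__(self) -> None:
        if not self.C <= self.P:
            raise ValueError("C must not exceed P")
        if len(self.n) != self.K or len(self.h2) != self.K:
            raise ValueError("n and h2 need one entry per trait")
        if any(not 0.0 < h < 1.0 for h in self.h2):
            raise ValueError("heritabilities must lie in (0, 1)")
        if not 0.0 <= self.shared_causal_fraction <= 1.0:
            raise ValueError("shared_causal_fraction must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: list[GenotypeMatrix]  # one per trait (aliases when overlap)
    traits: TraitSet
    beta_true: np.ndarray  # (K, P)
    causal: list[np.ndarray]  # per-trait causal SNP indices
    mafs: np.ndarray


def build_covariance(h2, rho, C: int) -> tuple[np.ndarray, np.ndarray]:
    """Effect covariance D and error variances sigma2 from (h2, rho, C).

    d_kk = h2_k / C; d_lm = rho_lm sqrt(d_ll d_mm); sigma2_k = 1 - h2_k.
    Raises if D is not positive semidefinite, naming the offending rho.
    """
    h2 = np.asarray(h2, dtype=np.float64)
    K = h2.shape[0]
    if np.isscalar(rho):
        R = np.full((K, K), float(rho))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(rho, dtype=np.float64)
    d_diag = h2 / C
    sd = np.sqrt(d_diag)
    D = R * np.outer(sd, sd)
    np.fill_diagonal(D, d_diag)  # keep h2/C exact (no sqrt round trip)
    eigmin = float(np.linalg.eigvalsh(D).min())
    if eigmin < -1e-12 * max(1.0, float(d_diag.max())):
        raise ValueError(
            f"effect covariance not positive semidefinite (min eigenvalue {eigmin:.3g}) "
            f"for rho=\n{R}"
        )
    return D, 1.0 - h2


def simulate_effects(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the (K, P) true-effect matrix and causal index sets.

    Causal SNPs are chosen uniformly without replacement. With
    ``shared_causal_fraction`` f, round(f*C) causal SNPs are common to
    all traits with effects from N_K(0, D); each trait's remaining
    causal SNPs come from disjoint pools with independent N(0, d_kk)
    effects, so every trait has exactly C causal SNPs and heritability
    h2_k either way.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K, P, C = config.K, config.P, config.C
    D, _ = build_covariance(np.asarray(config.h2), config.rho_matrix(), C)
    n_shared = int(round(config.shared_causal_fraction * C))
    n_specific = C - n_shared
    need = n_shared + n_specific * K
    if need > P:
        raise ValueError(
            f"need {need} distinct causal SNPs (shared + per-trait) but P={P}"
        )
    pool = rng.choice(P, size=need, replace=False)
    shared = np.sort(pool[:n_shared])
    beta = np.zeros((K, P))
    if n_shared:
        L = np.linalg.cholesky(D + 1e-15 * np.eye(K))
        beta[:, shared] = L @ rng.standard_normal((K, n_shared))
    causal = []
    offset = n_shared
    for k in range(K):
        own = np.sort(pool[offset : offset + n_specific])
        offset += n_specific
        if n_specific:
            beta[k, own] = rng.normal(0.0, np.sqrt(D[k, k]), size=n_specific)
        causal.append(np.sort(np.concatenate([shared, own])))
    return beta, causal


def simulate_genotypes(
    n: int,
    P: int,
    maf_range=(0.05, 0.5),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mafs: np.ndarray | None = None,
    ld_block_size: int | None = None,
    ld_rho: float = 0.0,
    sample_prefix: str = "ind",
) -> GenotypeMatrix:
    """Raw hard-call dosages for one cohort.

    Per-SNP MAF ~ Uniform(maf_range) unless ``mafs`` is given (pass the
    same vector to every cohort of a study so they share a panel). With
    ``ld_block_size`` set, the two haplotypes per individual follow an
    AR(1) latent-Gaussian process with lag correlation ``ld_rho`` inside
    each block, giving within-block LD; blocks are independent.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if mafs is None:
        mafs = rng.uniform(maf_range[0], maf_range[1], size=P)
    if ld_block_size is None or ld_rho == 0.0:
        dosages = rng.binomial(2, mafs, size=(n, P)).astype(np.float64)
    else:
        thresholds = norm.ppf(mafs)
        dosages = np.zeros((n, P))
        for _hap in range(2):
            z = np.empty((n, P))
            e = rng.standard_normal((n, P))
            for j in range(P):
                if j % ld_block_size == 0:
                    z[:, j] = e[:, j]
                else:
                    z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * e[:, j]
            dosages += (z < thresholds).astype(np.float64)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"snp{j + 1}" for j in range(P)]),
        chrom=np.array(["1"] * P),
        pos=np.arange(1, P + 1),
        allele1=np.array(["A"] * P),
        allele2=np.array(["B"] * P),
        sample_ids=np.array([f"{sample_prefix}{i + 1}" for i in range(n)]),
    )


def simulate_phenotypes(
    G: GenotypeMatrix,
    beta: np.ndarray,
    sigma2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    names: list[str] | None = None,
) -> TraitSet:
    """Phenotypes y_k = X beta_k + e, e ~ N(0, sigma2_k), for one cohort.

    X is the standardized version of ``G`` (standardized in place of the
    raw dosages; ``G`` itself is left untouched).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    beta = np.atleast_2d(np.asarray(beta, dtype=np.float64))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=np.float64))
    K = beta.shape[0]
    X = G.dosages if G.standardized else standardize(G).dosages
    names = names or [f"trait{k + 1}" for k in range(K)]
    values = [
        X @ beta[k] + rng.normal(0.0, np.sqrt(sigma2[k]), size=G.n_samples)
        for k in range(K)
    ]
    return TraitSet(
        names=names,
        values=values,
        sample_ids=[G.sample_ids.copy() for _ in range(K)],
        primary_index=0,
    )


def simulate_sumstats(G_secondary: GenotypeMatrix, y_secondary: np.ndarray) -> SummaryStatSet:
    """Marginal single-SNP effects on a secondary cohort, as an external
    GWAS would report them (one linear regression per SNP)."""
    Gs = G_secondary if G_secondary.standardized else standardize(G_secondary)
    yc = np.asarray(y_secondary, dtype=np.float64)
    yc = yc - yc.mean()
    betas = marginal_effects(Gs, yc)
    table = pd.DataFrame(
        {
            "snp_id": Gs.snp_ids,
            "effect_allele": Gs.allele2,
            "other_allele": Gs.allele1,
            "beta": betas,
            "n": Gs.n_samples,
        }
    )
    return SummaryStatSet(trait="secondary", table=table, aligned=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One complete multi-trait dataset under the configured design.

    With ``overlap`` the K traits share one cohort (and genotype
    matrix); otherwise each trait gets an independent cohort drawn from
    the same SNP panel (same MAFs). Fixed seed gives bitwise-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.P)
    beta, causal = simulate_effects(config, rng)
    _, sigma2 = build_covariance(np.asarray(config.h2), config.rho_matrix(), config.C)
    if config.overlap:
        if len(set(config.n)) != 1:
            raise ValueError("overlapping traits must share the sample size")
        G = simulate_genotypes(
            config.n[0], config.P, rng=rng, mafs=mafs,
            ld_block_size=config.ld_block_size, ld_rho=config.ld_rho,
        )
        traits = simulate_phenotypes(G, beta, sigma2, rng=rng)
        genotypes = [G] * config.K
    else:
        genotypes, names, values, ids = [], [], [], []
        for k in range(config.K):
            G = simulate_genotypes(
                config.n[k], config.P, rng=rng, mafs=mafs,
                ld_block_size=config.ld_block_size, ld_rho=config.ld_rho,
                sample_prefix=f"t{k + 1}_ind",
            )
            ts = simulate_phenotypes(G, beta[k], sigma2[k], rng=rng, names=[f"trait{k + 1}"])
            genotypes.append(G)
            names.append(ts.names[0])
            values.append(ts.values[0])
            ids.append(ts.sample_ids[0])
        traits = TraitSet(names=names, values=values, sample_ids=ids, primary_index=0)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        traits=traits,
        beta_true=beta,
        causal=causal,
        mafs=mafs,
    )
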