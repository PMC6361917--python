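"""Put traits and external summary statistics on a common scale/direction.

External GWAS effect sizes live on the phenotype scale of their own
study. Before they can anchor the cross-trait penalty they must be
(1) allele-aligned to the genotype panel's counted allele and
(2) rescaled so that the regression slope of the primary trait's
marginal SNP effects on the secondary trait's effects equals 1. The
rescaling also flips the direction of negatively correlated traits
(e.g. predicting height with the aid of BMI), so the quadratic coupling
always pulls toward positively oriented anchors.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from ctpr.io_formats import GenotypeMatrix, SummaryStatSet

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = ["marginal_effects", "rescale_secondary", "align_sumstats"]


def marginal_effects(G, y: np.ndarray) -> np.ndarray:
    """Per-SNP marginal regression coefficients beta_j = (x_j . y) / n.

    With standardized genotype columns (sum x^2 = n) and a centered
    phenotype this equals the one-variable least-squares slope, which is
    what single-SNP GWAS software reports for standardized data.

    ``G`` may be a standardized GenotypeMatrix or a bare (n, P) array.
    """
    if isinstance(G, GenotypeMatrix):
        if not G.standardized:
            raise ValueError("genotypes must be standardized first")
        X = G.dosages
    else:
        X = np.asarray(G, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} genotype rows vs {y.shape[0]} phenotype values")
    if abs(y.sum()) > 1e-8 * max(1.0, np.abs(y).max()):
        raise ValueError("phenotype must be centered")
    return X.T @ y / X.shape[0]


def rescale_secondary(
    beta_primary: np.ndarray, beta_secondary: np.ndarray
) -> tuple[float, np.ndarray]:
    """Rescale secondary-trait effects so the primary-on-secondary slope is 1.

    Fits the no-intercept least-squares slope of ``beta_primary`` on
    ``beta_secondary`` (slope = sum(p*q) / sum(q*q)) and multiplies the
    secondary effects by it. A proportional rescaling (no intercept)
    keeps null SNPs anchored at exactly zero. Negative correlation flips
    sign, so the rescaled anchors are always positively oriented with
    the primary trait.
    """
    p = np.asarray(beta_primary, dtype=np.float64)
    q = np.asarray(beta_secondary, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1 or p.shape[0] < 2:
        raise ValueError("expect two equal-length 1-d vectors of length >= 2")
    denom = float(q @ q)
    if denom == 0.0:
        raise ValueError("no shared signal to rescale: secondary effects are all zero")
    scale = float(p @ q) / denom
    return scale, scale * q


def align_sumstats(
    ss: SummaryStatSet, G: GenotypeMatrix, drop_ambiguous: bool = True
) -> tuple[np.ndarray, SummaryStatSet]:
    """Align a summary-statistic set to a genotype panel's counted allele.

    Returns a dense effect vector over ``G``'s SNPs (order of the .bim
    file) plus the aligned SummaryStatSet. For each genotype SNP:

    * effect_allele == allele2 (counted): beta kept as is;
    * effect_allele == allele1 and other_allele == allele2: beta negated;
    * strand-ambiguous (A/T or C/G) SNPs: excluded with a warning when
      ``drop_ambiguous`` (the default), since strand cannot be resolved;
    * absent from the summary statistics or allele-mismatched: effect 0,
      flagged.
    """
    tab = ss.table.set_index("snp_id")
    effects = np.zeros(G.n_snps, dtype=np.float64)
    status = np.full(G.n_snps, "missing", dtype=object)
    a1 = np.char.upper(G.allele1.astype(str))
    a2 = np.char.upper(G.allele2.astype(str))
    n_flip = n_amb = 0
    for j, snp in enumerate(G.snp_ids):
        if snp not in tab.index:
            continue
        rec = tab.loc[snp]
        ea, oa = rec["effect_allele"], rec["other_allele"]
        if drop_ambiguous and _COMPLEMENT.get(ea) == oa:
            status[j] = "ambiguous"
            n_amb += 1
            continue
        if ea == a2[j] and oa == a1[j]:
            effects[j] = rec["beta"]
            status[j] = "kept"
        elif ea == a1[j] and oa == a2[j]:
            effects[j] = -rec["beta"]
            status[j] = "flipped"
            n_flip += 1
        else:
            status[j] = "allele_mismatch"
    if n_amb:
        logger.warning("%s: %d strand-ambiguous SNP(s) excluded from alignment", ss.trait, n_amb)
    if n_flip:
        logger.info("%s: %d SNP(s) sign-flipped to the counted allele", ss.trait, n_flip)
    aligned_table = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "effect_allele": a2,
            "other_allele": a1,
            "beta": effects,
            "status": status,
        }
    )
    aligned = SummaryStatSet(
        trait=ss.trait,
        table=aligned_table[["snp_id", "effect_allele", "other_allele", "beta"]],
        aligned=True,
        rescale_factor=ss.rescale_factor,
        flags=aligned_table[["snp_id", "status"]],
    )
    return effects, aligned


def rescale_sumstat_set(
    ss: SummaryStatSet, beta_primary: np.ndarray, effects: np.ndarray
) -> tuple[float, np.ndarray, SummaryStatSet]:
    """Apply :func:`rescale_secondary` to an aligned effect vector."""
    scale, scaled = rescale_secondary(beta_primary, effects)
    table = ss.table.copy()
    table["beta"] = scaled
    return scale, scaled, replace(ss, table=table, rescale_factor=ss.rescale_factor * scale)
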