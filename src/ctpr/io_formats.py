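"""Genotype, phenotype, summary-statistic, and coefficient file I/O.

The solver assumes a strict standardization contract: every genotype
column has mean 0 and sum of squares equal to the sample size, and every
phenotype is centered, so no intercept enters the model. This module
owns that contract.

Dosage orientation: we count copies of ``allele2`` (the second allele
column of the .bim file), i.e. a homozygote for allele1 has dosage 0.
The counted allele is what summary-statistic effect alleles are aligned
against, so the convention is fixed here and recorded in outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitSet",
    "SummaryStatSet",
    "StandardizationTransform",
    "read_plink",
    "write_plink",
    "standardize",
    "center_phenotype",
    "read_phenotypes",
    "read_sumstats",
    "write_coefficients",
    "read_coefficients",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> dosage counting allele2; 0b01 is missing.
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Files that must agree (bed/bim/fam) are mutually inconsistent."""


@dataclass(frozen=True)
class StandardizationTransform:
    """Column statistics frozen at training time.

    Applying a training-set transform to validation genotypes prevents
    leakage of validation allele frequencies into the model.
    """

    means: np.ndarray  # per-SNP mean dosage (after mean imputation)
    scales: np.ndarray  # per-SNP divisor giving sum(x^2) = n
    monomorphic: np.ndarray  # bool mask: column zeroed and excluded


@dataclass
class GenotypeMatrix:
    """An n_samples x n_snps real dosage matrix with SNP/sample metadata.

    ``dosages`` uses NaN for missing genotypes until standardization,
    which mean-imputes them.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    sample_ids: np.ndarray
    standardized: bool = False
    transform: StandardizationTransform | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, p = self.dosages.shape
        for name in ("snp_ids", "chrom", "pos", "allele1", "allele2"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != p:
                raise IntegrityError(
                    f"{name} has length {arr.shape[0]}, expected {p} (one per SNP)"
                )
            setattr(self, name, arr)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape[0] != n:
            raise IntegrityError(
                f"sample_ids has length {self.sample_ids.shape[0]}, expected {n}"
            )
        if len(np.unique(self.snp_ids)) != p:
            raise IntegrityError("snp_ids are not unique")
        if len(np.unique(self.sample_ids)) != n:
            raise IntegrityError("sample_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TraitSet:
    """K phenotype vectors with per-trait sample alignment.

    Traits need not be measured on the same individuals; each trait
    carries its own sample-id vector. ``primary_index`` marks the trait
    being predicted. ``means`` holds the pre-centering means so
    predictions can be mapped back to the original scale.
    """

    names: list[str]
    values: list[np.ndarray]
    sample_ids: list[np.ndarray]
    primary_index: int = 0
    means: list[float] | None = None

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.values) == len(self.sample_ids)):
            raise IntegrityError("names/values/sample_ids lengths differ")
        self.values = [np.asarray(v, dtype=np.float64) for v in self.values]
        self.sample_ids = [np.asarray(s) for s in self.sample_ids]
        for name, v, s in zip(self.names, self.values, self.sample_ids):
            if v.shape[0] != s.shape[0]:
                raise IntegrityError(f"trait {name}: values/sample_ids lengths differ")

    @property
    def n_traits(self) -> int:
        return len(self.names)

    def n_k(self, k: int) -> int:
        return self.values[k].shape[0]

    def centered(self) -> "TraitSet":
        """Return a copy with every trait centered (mean retained)."""
        out_vals, means = [], []
        for v in self.values:
            c, m = center_phenotype(v)
            out_vals.append(c)
            means.append(m)
        return TraitSet(
            names=list(self.names),
            values=out_vals,
            sample_ids=[s.copy() for s in self.sample_ids],
            primary_index=self.primary_index,
            means=means,
        )


@dataclass
class SummaryStatSet:
    """Fixed marginal SNP effects for one secondary trait.

    ``table`` columns: snp_id, effect_allele, other_allele, beta, and
    optionally se and n. After alignment against a GenotypeMatrix the
    effect allele matches the genotype file's counted allele (allele2)
    for every record; SNPs absent from the genotype panel get beta 0 and
    are flagged.
    """

    trait: str
    table: pd.DataFrame
    aligned: bool = False
    rescale_factor: float = 1.0
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "beta"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"summary statistics missing columns: {sorted(missing)}")
        dup = self.table["snp_id"][self.table["snp_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate snp_id in summary statistics: {dup.iloc[0]}")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a SNP-major PLINK .bed/.bim/.fam triple into a GenotypeMatrix.

    ``bed_path`` may be a prefix (then .bim/.fam are inferred). Dosages
    count allele2; missing genotypes become NaN.
    """
    bed_path = str(bed_path)
    if bim_path is None:
        prefix = bed_path[:-4] if bed_path.endswith(".bed") else bed_path
        bed_path, bim_path, fam_path = (
            prefix + ".bed",
            prefix + ".bim",
            prefix + ".fam",
        )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (expected SNP-major 6c1b01)"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise IntegrityError(
            f"{bed_path}: {body.size} data bytes, expected {bytes_per_snp * p} "
            f"for {n} samples x {p} variants"
        )
    body = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # (n, p)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        allele1=bim["allele1"].to_numpy(),
        allele2=bim["allele2"].to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
    )


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write hard-call dosages back to .bed/.bim/.fam (SNP-major)."""
    if G.standardized:
        raise ValueError("refusing to write standardized dosages as hard calls")
    prefix = str(prefix)
    n, p = G.dosages.shape
    code_of = {0.0: 0, 1.0: 2, 2.0: 3}  # dosage -> 2-bit code; NaN -> 1
    codes = np.full((p, n), 1, dtype=np.uint8)
    for value, code in code_of.items():
        codes[(G.dosages.T == value)] = code
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded.reshape(p, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    )
    packed = np.bitwise_or.reduce(packed, axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": G.chrom,
            "snp_id": G.snp_ids,
            "cm": 0,
            "pos": G.pos,
            "allele1": G.allele1,
            "allele2": G.allele2,
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Standardization / centering


def standardize(
    G: GenotypeMatrix, transform: StandardizationTransform | None = None
) -> GenotypeMatrix:
    """Standardize columns so each has sum 0 and sum of squares n.

    Missing values are imputed to the column mean first (which keeps the
    column sum exactly 0 after centering). Monomorphic (zero-variance,
    including all-missing) columns are set to all-zero and flagged in the
    transform; the solver excludes them.

    When ``transform`` is given (validation data), the stored training
    means/scales are applied instead of recomputing them.
    """
    if G.standardized:
        raise ValueError("GenotypeMatrix is already standardized")
    X = G.dosages.copy()
    n = X.shape[0]
    nan_mask = np.isnan(X)
    has_nan = bool(nan_mask.any())
    if transform is None:
        if has_nan:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                means = np.nanmean(X, axis=0)
        else:
            means = X.mean(axis=0)
        all_missing = ~np.isfinite(means)
        means = np.where(all_missing, 0.0, means)
        # impute, center, then scale to sum(x^2) = n
        if has_nan:
            X[nan_mask] = np.broadcast_to(means, X.shape)[nan_mask]
        X -= means
        ss = np.einsum("ij,ij->j", X, X)
        scales = np.sqrt(ss / n)
        monomorphic = (scales == 0.0) | all_missing
        transform = StandardizationTransform(
            means=means, scales=np.where(monomorphic, 1.0, scales), monomorphic=monomorphic
        )
        if np.any(all_missing):
            warnings.warn(
                f"{int(all_missing.sum())} all-missing SNP column(s) excluded",
                stacklevel=2,
            )
    else:
        if has_nan:
            X[nan_mask] = np.broadcast_to(transform.means, X.shape)[nan_mask]
        X -= transform.means
    X /= transform.scales
    X[:, transform.monomorphic] = 0.0
    return replace(G, dosages=X, standardized=True, transform=transform)


def center_phenotype(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a phenotype vector; return (centered, original_mean)."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 samples to center a phenotype")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    m = float(y.mean())
    return y - m, m


# ---------------------------------------------------------------------------
# Phenotypes, summary statistics, coefficients


def read_phenotypes(path, primary: str | None = None) -> TraitSet:
    """Read a whitespace-delimited phenotype table: FID IID trait1 [...].

    A header row naming the traits is required. Missing values (NA/nan)
    are dropped per trait, so traits may have different sample counts.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    for col in ("FID", "IID"):
        if col not in df.columns:
            raise FormatError(f"phenotype file must have a header with {col}")
    trait_cols = [c for c in df.columns if c not in ("FID", "IID")]
    if not trait_cols:
        raise FormatError("phenotype file has no trait columns")
    names, values, ids = [], [], []
    for c in trait_cols:
        v = pd.to_numeric(df[c], errors="coerce")
        keep = v.notna()
        names.append(c)
        values.append(v[keep].to_numpy(dtype=np.float64))
        ids.append(df["IID"][keep].to_numpy())
    primary_index = 0 if primary is None else names.index(primary)
    return TraitSet(names=names, values=values, sample_ids=ids, primary_index=primary_index)


_DEFAULT_SUMSTAT_COLUMNS = {
    "snp_id": ("snp_id", "snp", "rsid", "id", "markername"),
    "effect_allele": ("effect_allele", "a1", "allele1", "ea"),
    "other_allele": ("other_allele", "a2", "allele2", "oa"),
    "beta": ("beta", "effect", "b"),
    "se": ("se", "stderr"),
    "n": ("n", "nsample", "n_samples"),
}


def read_sumstats(path, trait_label: str, column_map: dict | None = None) -> SummaryStatSet:
    """Read delimited per-SNP marginal effects for one secondary trait.

    Header names are matched case-insensitively against common synonyms;
    ``column_map`` overrides (e.g. ``{"beta": "EFFECT_HGT"}``). Rows with
    unparseable effect sizes are dropped with a warning naming their line
    numbers.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, synonyms in _DEFAULT_SUMSTAT_COLUMNS.items():
        if column_map and canon in column_map:
            if column_map[canon] not in df.columns:
                raise FormatError(
                    f"column {column_map[canon]!r} (mapped to {canon}) not in {path}"
                )
            resolved[canon] = column_map[canon]
            continue
        for s in synonyms:
            if s in lower:
                resolved[canon] = lower[s]
                break
    for canon in ("snp_id", "effect_allele", "other_allele", "beta"):
        if canon not in resolved:
            raise FormatError(f"summary statistics file {path} lacks a {canon} column")
    out = pd.DataFrame(
        {
            "snp_id": df[resolved["snp_id"]],
            "effect_allele": df[resolved["effect_allele"]].str.upper(),
            "other_allele": df[resolved["other_allele"]].str.upper(),
            "beta": pd.to_numeric(df[resolved["beta"]], errors="coerce"),
        }
    )
    for opt in ("se", "n"):
        if opt in resolved:
            out[opt] = pd.to_numeric(df[resolved[opt]], errors="coerce")
    bad = out.index[out["beta"].isna()]
    if len(bad):
        # +2: one for the header, one for 0-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:10])
        warnings.warn(
            f"{path}: dropped {len(bad)} row(s) with unparseable beta (lines {lines})",
            stacklevel=2,
        )
        out = out.drop(index=bad).reset_index(drop=True)
    return SummaryStatSet(trait=trait_label, table=out)


def write_coefficients(beta, snp_ids, trait_names, path, counted_allele=None) -> None:
    """Write a K x P coefficient matrix as a TSV (snp_id, trait, beta).

    Floats are written with full round-trip precision so read-back is
    bitwise exact.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=np.float64))
    rows = []
    for k, name in enumerate(trait_names):
        for j, snp in enumerate(snp_ids):
            rows.append((snp, name, np.format_float_scientific(beta[k, j], unique=True)))
    df = pd.DataFrame(rows, columns=["snp_id", "trait", "beta"])
    if counted_allele is not None:
        df["counted_allele"] = np.tile(np.asarray(counted_allele), len(trait_names))
    df.to_csv(path, sep="\t", index=False)


def read_coefficients(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read back a coefficient TSV; returns (beta K x P, snp_ids, trait_names)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "trait": str}, float_precision="round_trip"
    )
    trait_names = list(dict.fromkeys(df["trait"]))
    snp_ids = df.loc[df["trait"] == trait_names[0], "snp_id"].to_numpy()
    beta = np.empty((len(trait_names), len(snp_ids)), dtype=np.float64)
    for k, name in enumerate(trait_names):
        sub = df[df["trait"] == name]
        if not np.array_equal(sub["snp_id"].to_numpy(), snp_ids):
            raise IntegrityError(f"coefficient file {path}: SNP order differs by trait")
        beta[k] = sub["beta"].to_numpy(dtype=np.float64)
    return beta, snp_ids, trait_names
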