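"""Genotype and covariate input/output with variant-level quality control.

Genotypes are held in a :class:`GenotypeMatrix`: samples x biallelic SNPs,
with calls coded 0/1/2 as copies of allele B and ``MISSING`` (-1) for no-calls.
PLINK 1 binary filesets (BED/BIM/FAM, SNP-major) are the on-disk format.

QC follows the conventional array pipeline: drop SNPs with minor allele
frequency below 1% and SNPs deviating from Hardy-Weinberg proportions at an
exact-test p-value below 1e-3.  Coordinates are 1-based inclusive base pairs
throughout; non-autosomal variants are dropped on load because every
downstream quantity (ROH burden, F_ROH, F_IS) is defined on autosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: chromosome labels accepted as autosomes (PLINK numeric convention)
_AUTOSOMES = {str(i) for i in range(1, 23)}


class GenotypeFormatError(ValueError):
    """Raised for malformed or mutually inconsistent PLINK files."""


@dataclass
class GenotypeMatrix:
    """Samples x variants genotype matrix with variant metadata.

    Attributes
    ----------
    sample_ids : list of str
        Individual identifiers, one per row of ``calls``.
    variants : pandas.DataFrame
        One row per SNP with columns ``chrom`` (str), ``pos`` (int, 1-based),
        ``id``, ``allele_a``, ``allele_b``; within a chromosome positions are
        strictly increasing.
    calls : numpy.ndarray of int8, shape (n_samples, n_variants)
        Copies of ``allele_b`` in {0, 1, 2} or ``MISSING``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("need at least one sample and one variant")
        if self.calls.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        pos = self.variants["pos"].to_numpy()
        for chrom, idx in self.variants.groupby("chrom", sort=False).groups.items():
            p = pos[self.variants.index.get_indexer(idx)]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix keeping variants where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
        )

    def allele_b_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele B over non-missing calls (NaN if no calls)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# PLINK 1 binary fileset
# ---------------------------------------------------------------------------

# Decode table indexed by 2-bit code, counting copies of allele A2 (allele_b,
# the BIM sixth column):
#   0b00 = hom A1A1 -> 0 copies of A2
#   0b01 = missing
#   0b10 = het      -> 1
#   0b11 = hom A2A2 -> 2
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    drop_non_autosomes: bool = True,
) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    Only SNP-major v1.00 BED files are accepted.  Missing calls map to
    ``MISSING``; variant order is taken from the BIM file.  Non-autosomal
    variants (X, Y, MT, 0) are dropped unless ``drop_non_autosomes=False``.
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele_a", "allele_b"],
        dtype={"chrom": str, "id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, usecols=[0, 1], dtype=str)
    sample_ids = fam[1].tolist()
    n_samples, n_variants = len(sample_ids), len(bim)
    if n_samples == 0:
        raise GenotypeFormatError(f"{fam_path}: no samples")
    if n_variants == 0:
        raise GenotypeFormatError(f"{bim_path}: no variants")

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (want {_BED_MAGIC.hex()})"
        )
    bytes_per_variant = (n_samples + 3) // 4
    expected = 3 + bytes_per_variant * n_variants
    if len(raw) != expected:
        raise GenotypeFormatError(
            f"{bed_path}: payload is {len(raw)} bytes, expected {expected} for "
            f"{n_samples} samples x {n_variants} variants (BIM/FAM mismatch or truncation)"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    payload = payload.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
    calls = _DECODE[codes].T  # -> samples x variants

    variants = bim[["chrom", "pos", "id", "allele_a", "allele_b"]].copy()
    variants["pos"] = variants["pos"].astype(np.int64)
    if drop_non_autosomes:
        keep = variants["chrom"].isin(_AUTOSOMES).to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d non-autosomal variants", n_dropped)
        if not keep.any():
            raise GenotypeFormatError(f"{bim_path}: no autosomal variants")
        variants = variants.loc[keep].reset_index(drop=True)
        calls = calls[:, keep]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


def write_plink(
    g: GenotypeMatrix, bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK 1 SNP-major fileset."""
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "allele_a": g.variants["allele_a"],
            "allele_b": g.variants["allele_b"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    with open(fam_path, "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")

    n_samples = g.n_samples
    bytes_per_variant = (n_samples + 3) // 4
    # map genotype -> 2-bit code via lookup on geno+1 (MISSING=-1 -> index 0)
    lut = np.empty(4, dtype=np.uint8)
    lut[MISSING + 1] = 0b01
    lut[0 + 1] = 0b00
    lut[1 + 1] = 0b10
    lut[2 + 1] = 0b11
    codes = lut[(g.calls + 1).astype(np.intp)]  # samples x variants
    pad = bytes_per_variant * 4 - n_samples
    if pad:
        codes = np.vstack([codes, np.zeros((pad, g.n_variants), dtype=np.uint8)])
    codes = codes.T.reshape(g.n_variants, bytes_per_variant, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value conditional on allele counts.

    Sums the conditional probabilities of all heterozygote counts whose
    probability does not exceed that of the observed count (the standard
    exact conditional test for genotype-array QC).  Monomorphic sites return
    1.0.

    Parameters are genotype counts for the three classes (hom A, het, hom B).
    """
    if n_aa < 0 or n_ab < 0 or n_bb < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: only one configuration exists

    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_ab = h | allele counts) up to a constant:
    #   P(h) ∝ 2^h * n! / (n_aa! n_ab! n_bb!)  with n_aa=(n_a-h)/2 etc.
    from scipy.special import gammaln

    n_aa_h = (n_a - hets) // 2
    n_bb_h = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(n_aa_h + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb_h + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_ab)[0][0]]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value for each variant of ``g`` (NaN for zero call rate)."""
    out = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = g.calls[:, j]
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if n_aa + n_ab + n_bb == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_exact_pvalue(n_aa, n_ab, n_bb)
    return out


def apply_variant_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float | None = 0.001,
) -> GenotypeMatrix:
    """Drop SNPs with MAF < ``maf_min`` or exact-HWE p-value < ``hwe_p_min``.

    Both filters are strict ``<`` comparisons, so a SNP sitting exactly at a
    threshold is retained.  MAF is computed on non-missing calls; SNPs with
    zero call rate are removed.  Pass ``hwe_p_min=None`` (or 0) to skip the
    HWE screen.  Raises ``ValueError`` if nothing survives.
    """
    maf = g.maf()
    callrate_zero = np.isnan(maf)
    maf_fail = callrate_zero | (np.nan_to_num(maf, nan=0.0) < maf_min)
    if hwe_p_min:
        hwe = hwe_pvalues(g)
        hwe_fail = np.isnan(hwe) | (np.nan_to_num(hwe, nan=0.0) < hwe_p_min)
    else:
        hwe_fail = np.zeros(g.n_variants, dtype=bool)
    keep = ~(maf_fail | hwe_fail)
    logger.info(
        "variant QC: %d/%d retained (%d failed MAF<%g, %d failed HWE p<%s)",
        int(keep.sum()), g.n_variants, int(maf_fail.sum()), maf_min,
        int(hwe_fail.sum()), hwe_p_min,
    )
    if not keep.any():
        raise ValueError("variant filters removed every SNP")
    return g.subset_variants(keep)


# ---------------------------------------------------------------------------
# Covariate table
# ---------------------------------------------------------------------------

EDUCATION_LEVELS = [
    "primary_informal",
    "secondary",
    "technical",
    "postgraduate",
    "university",
    "missing",
]

COHORT_COLUMNS = [
    "sample_id",
    "sex",
    "age",
    "education",
    "bmi",
    "aymara_quechua_pct",
    "mapuche_huilliche_pct",
    "gsd_prs",
    "f_roh",
    "outcome",
]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort covariate table (returns it unchanged on success).

    Expected columns: ``sample_id``, ``sex`` (male/female), ``age`` (years,
    > 0), ``education`` (one of :data:`EDUCATION_LEVELS`), ``bmi`` (kg/m^2,
    > 10), ``aymara_quechua_pct`` and ``mapuche_huilliche_pct`` (proportions
    in [0, 1] summing to <= 1), ``gsd_prs`` (> 0), ``f_roh`` (in [0, 1]) and
    the binary ``outcome``.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    if not cohort["sex"].isin(["male", "female"]).all():
        raise ValueError("sex must be 'male' or 'female'")
    if not cohort["education"].isin(EDUCATION_LEVELS).all():
        raise ValueError(f"education must be one of {EDUCATION_LEVELS}")
    if (cohort["age"] <= 0).any():
        raise ValueError("age must be positive")
    if (cohort["bmi"] <= 10).any():
        raise ValueError("bmi must exceed 10 kg/m^2")
    for col in ("aymara_quechua_pct", "mapuche_huilliche_pct", "f_roh"):
        if ((cohort[col] < 0) | (cohort[col] > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    if ((cohort["aymara_quechua_pct"] + cohort["mapuche_huilliche_pct"]) > 1 + 1e-9).any():
        raise ValueError("ancestry proportions sum above 1")
    if (cohort["gsd_prs"] <= 0).any():
        raise ValueError("gsd_prs must be positive (it enters the model on a log scale)")
    if not cohort["outcome"].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated cohort covariate table."""
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, sep="\t", index=False)
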