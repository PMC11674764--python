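"""Per-sample inbreeding coefficients and ROH length-class summaries.

Three coefficients are computed and related through the classical partition
of total inbreeding, (1 - F_IT) = (1 - F_IS)(1 - F_ST):

* ``F_IS`` -- excess individual homozygosity relative to Hardy-Weinberg
  expectation under the observed sample allele frequencies, (O(HOM) -
  E(HOM)) / (N - E(HOM)).  Positive values indicate consanguinity, negative
  values inbreeding avoidance.
* ``F_ROH`` -- fraction of the autosomal genome covered by ROH strictly
  longer than 1.5 Mb, conventionally divided by 3 Gb; a genomic proxy for
  the total inbreeding coefficient F_IT.
* ``F_ST`` (implied) -- the panmictic/drift component backed out of the
  partition as 1 - (1 - F_ROH)/(1 - F_IS); may be negative, and is then
  reported as-is.

ROH burden is also summarized as NROH/SROH above the F_ROH length threshold
and as summed lengths over six tract-length classes ([0.3, 0.5), [0.5, 1),
[1, 2), [2, 4), [4, 8) and [8, inf) Mb, half-open below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .roh_caller import ROHSegment

#: lower edges (Mb) of the six ROH length classes; last class is unbounded
CLASS_EDGES_MB = (0.3, 0.5, 1.0, 2.0, 4.0, 8.0)
CLASS_LABELS = ("0.3-0.5", "0.5-1", "1-2", "2-4", "4-8", ">=8")

#: conventional autosomal genome length used as the F_ROH denominator (Gb)
GENOME_GB_DEFAULT = 3.0
#: conventional F_ROH minimum segment length (Mb, strict)
FROH_MIN_MB_DEFAULT = 1.5


@dataclass
class InbreedingProfile:
    """Per-sample inbreeding summary."""

    sample_id: str
    f_roh: float
    f_is: float | None
    f_st_implied: float | None
    nroh: int
    sroh_mb: float
    class_sums_mb: tuple[float, float, float, float, float, float]


def f_is_all(g: GenotypeMatrix) -> np.ndarray:
    """F_IS for every sample of ``g`` (method-of-moments, sample frequencies).

    O(HOM) counts the sample's homozygous non-missing calls; E(HOM) sums the
    per-SNP expected homozygosity 1 - 2*p*q*N/(N-1) over the SNPs the sample
    is genotyped at, with p the allele-B frequency and N the number of
    non-missing individuals at that SNP (the small-sample correction used by
    standard genotype toolkits); N_geno is the sample's non-missing SNP
    count.  Samples with N_geno == E(HOM) get NaN.
    """
    nonmiss = g.calls != MISSING
    n_per_snp = nonmiss.sum(axis=0).astype(float)
    p = g.allele_b_frequency()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n_per_snp > 1, n_per_snp / (n_per_snp - 1.0), np.nan)
    e_hom_snp = 1.0 - 2.0 * p * (1.0 - p) * corr  # per-SNP expectation
    e_hom_snp = np.where(n_per_snp > 1, e_hom_snp, np.nan)

    usable = nonmiss & ~np.isnan(e_hom_snp)[None, :]
    o_hom = (((g.calls == 0) | (g.calls == 2)) & usable).sum(axis=1).astype(float)
    e_hom = np.where(usable, e_hom_snp[None, :], 0.0).sum(axis=1)
    n_geno = usable.sum(axis=1).astype(float)
    denom = n_geno - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (o_hom - e_hom) / denom
    out[np.isclose(denom, 0.0)] = np.nan
    return out


def f_is(g: GenotypeMatrix, sample: str | int) -> float:
    """F_IS for one sample (by id or row index); raises if undefined."""
    idx = sample if isinstance(sample, int) else g.sample_ids.index(sample)
    val = f_is_all(g)[idx]
    if np.isnan(val):
        raise ValueError(
            f"F_IS undefined for sample {sample!r}: no informative SNPs "
            "(N equals expected homozygous count)"
        )
    return float(val)


def f_roh(
    segments: list[ROHSegment],
    min_len_mb: float = FROH_MIN_MB_DEFAULT,
    genome_gb: float = GENOME_GB_DEFAULT,
) -> float:
    """Genomic inbreeding coefficient: summed length of ROH strictly longer
    than ``min_len_mb`` divided by ``genome_gb``.  Empty input gives 0."""
    total_mb = sum(s.length_mb for s in segments if s.length_mb > min_len_mb)
    return total_mb / (genome_gb * 1000.0)


def f_st_implied(f_roh_value: float, f_is_value: float) -> float:
    """Drift component implied by the partition (1-F_IT) = (1-F_IS)(1-F_ST),
    with F_ROH standing in for F_IT.  May be negative (reported as-is)."""
    if f_is_value >= 1.0:
        raise ZeroDivisionError("F_IS = 1 leaves the drift component undefined")
    return 1.0 - (1.0 - f_roh_value) / (1.0 - f_is_value)


def class_sums(segments: list[ROHSegment]) -> tuple[float, ...]:
    """Summed ROH length (Mb) in the six half-open length classes.

    Segments shorter than 0.3 Mb are ignored; a segment of exactly a class
    boundary falls in the upper class (e.g. 1.0 Mb is in [1, 2))."""
    sums = [0.0] * len(CLASS_EDGES_MB)
    edges = list(CLASS_EDGES_MB) + [np.inf]
    for s in segments:
        mb = s.length_mb
        if mb < CLASS_EDGES_MB[0]:
            continue
        for k in range(len(CLASS_EDGES_MB)):
            if edges[k] <= mb < edges[k + 1]:
                sums[k] += mb
                break
    return tuple(sums)


def profile_from_segments(
    sample_id: str,
    segments: list[ROHSegment],
    f_is_value: float | None = None,
    min_len_mb: float = FROH_MIN_MB_DEFAULT,
    genome_gb: float = GENOME_GB_DEFAULT,
) -> InbreedingProfile:
    """Build an :class:`InbreedingProfile` from one sample's ROH calls."""
    froh = f_roh(segments, min_len_mb=min_len_mb, genome_gb=genome_gb)
    long_segs = [s for s in segments if s.length_mb > min_len_mb]
    fst = None
    if f_is_value is not None and not np.isnan(f_is_value) and f_is_value < 1.0:
        fst = f_st_implied(froh, f_is_value)
    return InbreedingProfile(
        sample_id=sample_id,
        f_roh=froh,
        f_is=None if f_is_value is None or np.isnan(f_is_value) else float(f_is_value),
        f_st_implied=fst,
        nroh=len(long_segs),
        sroh_mb=float(sum(s.length_mb for s in long_segs)),
        class_sums_mb=class_sums(segments),
    )


def profiles_table(
    g: GenotypeMatrix | None,
    segments: list[ROHSegment],
    min_len_mb: float = FROH_MIN_MB_DEFAULT,
    genome_gb: float = GENOME_GB_DEFAULT,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample inbreeding profiles as a DataFrame.

    If a genotype matrix is given, F_IS (and the implied F_ST) are computed
    from it; otherwise those columns are NaN.  ``sample_ids`` defaults to the
    matrix's samples, or to the samples present in ``segments``.
    """
    if sample_ids is None:
        sample_ids = (
            list(g.sample_ids) if g is not None
            else sorted({s.sample_id for s in segments})
        )
    fis_map: dict[str, float] = {}
    if g is not None:
        vals = f_is_all(g)
        fis_map = dict(zip(g.sample_ids, vals))
    by_sample: dict[str, list[ROHSegment]] = {sid: [] for sid in sample_ids}
    for s in segments:
        if s.sample_id in by_sample:
            by_sample[s.sample_id].append(s)
    rows = []
    for sid in sample_ids:
        prof = profile_from_segments(
            sid, by_sample[sid], fis_map.get(sid), min_len_mb, genome_gb
        )
        row = {
            "sample_id": sid,
            "f_roh": prof.f_roh,
            "f_is": np.nan if prof.f_is is None else prof.f_is,
            "f_st_implied": np.nan if prof.f_st_implied is None else prof.f_st_implied,
            "nroh": prof.nroh,
            "sroh_mb": prof.sroh_mb,
        }
        for label, val in zip(CLASS_LABELS, prof.class_sums_mb):
            row[f"sum_mb_{label}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inbreeding depression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepressionModel:
    """Additive multi-locus model of inbreeding depression.

    ``m0`` is the population trait mean before inbreeding; each locus
    contributes (d, p, q) with d the heterozygote genotypic value and p + q
    = 1 the allele frequencies.  The inbred mean is m0 - 2*F*sum(d*p*q), so
    the depression is linear in the inbreeding coefficient F and vanishes
    without directional dominance (all d = 0).
    """

    m0: float
    loci: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for d, p, q in self.loci:
            if abs(p + q - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies must sum to 1 (got p={p}, q={q})")


def depression_mean(model: DepressionModel, f: float) -> float:
    """Population trait mean at inbreeding coefficient ``f`` in [0, 1]."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    return model.m0 - 2.0 * f * sum(d * p * q for d, p, q in model.loci)
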