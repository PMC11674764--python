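"""Synthetic admixed cohorts with realistic homozygosity structure.

The generator emulates a Latin American case-control cohort with six
ancestry categories, each carrying a characteristic burden of runs of
homozygosity (ROH):

* **Drift / ancient inbreeding** is modelled by drawing each individual's
  two haplotypes as recombination mosaics over a finite founder-haplotype
  pool.  The pool size ``H`` sets the autozygous fraction (~1/H) and the
  mosaic switch rate sets tract lengths; small pools with high switch rates
  yield the large sums of *short* (0.3-1 Mb) ROH typical of groups with
  high indigenous American ancestry.
* **Consanguinity** is added by routing a configurable fraction of each
  group through the pedigree simulator (second cousin .. incest), which
  contributes the *long* ROH tail.

Disease outcomes are drawn from a logistic model whose default coefficients
are the published full-cohort odds ratios for gallbladder cancer (female
sex 3.48, age 1.18/yr with 0.99/yr^2, education contrasts, BMI categories,
ancestry proportions 0.97 and 1.02 per percentage point, gallstone-PRS 2.75
per doubling, F_ROH 1.07 per 1%); the model intercept is solved numerically
so the case fraction matches the target prevalence (15.3%).  A second
coefficient set adds stratum-specific F_ROH effects (stronger in males, the
young and the genetically gallstone-prone) for interaction and
stratification experiments.

Two output levels are provided: :func:`generate_cohort` draws covariates
plus per-individual ROH tract summaries (fast, scales to tens of thousands
of samples) and :func:`generate_genotypes` additionally paints biallelic
SNPs on the haplotype mosaics so the ROH caller can run on the output, with
ground-truth autozygous tracts returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import EDUCATION_LEVELS, GenotypeMatrix, validate_cohort
from .association import design_matrix
from .pedigree_sim import GenomeMap, simulate_mating

# Table-calibrated full-cohort generating coefficients (log odds ratios)
COEFFS_TABLE2: dict[str, float] = {
    "sex_female": math.log(3.48),
    "age_c": math.log(1.18),
    "age_c_sq": math.log(0.99),
    "edu_primary_informal": math.log(2.65),
    "edu_technical": math.log(0.47),
    "edu_postgraduate": math.log(0.22),
    "edu_university": math.log(0.57),
    "edu_missing": math.log(0.14),
    "bmi_overweight": math.log(1.34),
    "bmi_obesity": math.log(1.27),
    "aymara_quechua_pctpt": math.log(0.97),
    "mapuche_huilliche_pctpt": math.log(1.02),
    "log2_prs": math.log(2.75),
    "froh_pct": math.log(1.07),
}

# Variant with stratum-specific F_ROH effects (per 1% F_ROH): stronger in
# males, in individuals younger than 60 and in those above the median
# gallstone PRS; the F_ROH main effect is null in the complementary strata.
COEFFS_STRATIFIED: dict[str, float] = {
    **{k: v for k, v in COEFFS_TABLE2.items() if k != "froh_pct"},
    "froh_pct": 0.0,
    "froh_x_male": math.log(1.19),
    "froh_x_young60": math.log(1.15),
    "froh_x_highprs": math.log(1.10),
}

# Coefficient set with no homozygosity effect (type-I error experiments)
COEFFS_NULL_FROH: dict[str, float] = {**COEFFS_TABLE2, "froh_pct": 0.0}

COEFFICIENT_SETS = {
    "table2": COEFFS_TABLE2,
    "stratified": COEFFS_STRATIFIED,
    "null_froh": COEFFS_NULL_FROH,
}

#: generator-only interaction coefficient keys (not design-matrix columns)
_GENERATOR_INTERACTIONS = ("froh_x_male", "froh_x_young60", "froh_x_highprs")


@dataclass(frozen=True)
class GroupConfig:
    """Per-ancestry-group generator settings.

    ``fraction``: share of the cohort.  ``pool_size``: founder-haplotype
    pool size H (autozygous fraction ~ 1/H).  ``switch_rate_per_mb``:
    founder-label switch rate of the haplotype mosaics (per Mb); the implied
    mean autozygous tract length is 1 / (2 * rate * (1 - 1/H)) Mb.
    ``consanguinity``: mating-class -> fraction of the group routed through
    that pedigree.
    """

    fraction: float
    pool_size: int
    switch_rate_per_mb: float
    consanguinity: dict[str, float] = field(default_factory=dict)

    @property
    def autozygous_fraction(self) -> float:
        return 1.0 / self.pool_size

    @property
    def mean_tract_mb(self) -> float:
        return 1.0 / (2.0 * self.switch_rate_per_mb * (1.0 - 1.0 / self.pool_size))


# Group mix follows the published cohort composition; pool sizes and switch
# rates were calibrated once (scripts/calibrate_generator.py) against the
# published group F_ROH medians and short-ROH burdens.
DEFAULT_GROUPS: dict[str, GroupConfig] = {
    "Aymara-Quechua": GroupConfig(0.0276, 3, 2.03),
    "Aymara-Quechua-European": GroupConfig(0.0489, 5, 1.88),
    "European": GroupConfig(0.0280, 8, 1.78),
    "Mapuche-Huilliche": GroupConfig(
        0.0204, 4, 1.70,
        {"second_cousin": 0.06, "first_cousin": 0.05, "avuncular": 0.01, "incest": 0.003},
    ),
    "Mapuche-Huilliche-European": GroupConfig(
        0.4679, 6, 1.83,
        {"second_cousin": 0.04, "first_cousin": 0.015, "avuncular": 0.004},
    ),
    "Other admixture": GroupConfig(
        0.4073, 7, 1.80, {"second_cousin": 0.02, "first_cousin": 0.005}
    ),
}

#: education level probabilities of the emulated cohort
EDUCATION_PROBS = (0.127, 0.434, 0.039, 0.017, 0.132, 0.250)
SEX_MALE_PROB = 0.433
PREVALENCE_DEFAULT = 0.153
FROH_MIN_MB = 1.5


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort draw."""

    n: int = 1000
    groups: dict[str, GroupConfig] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    genome: GenomeMap = field(default_factory=GenomeMap.scaled)
    coefficients: dict[str, float] = field(default_factory=lambda: dict(COEFFS_TABLE2))
    prevalence: float = PREVALENCE_DEFAULT
    snp_spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        tot = sum(g.fraction for g in self.groups.values())
        if abs(tot - 1.0) > 1e-6:
            # normalize silently-close fractions, reject the rest
            if abs(tot - 1.0) > 0.02:
                raise ValueError(f"group fractions sum to {tot}, not 1")
            for k, g in self.groups.items():
                self.groups[k] = GroupConfig(
                    g.fraction / tot, g.pool_size, g.switch_rate_per_mb, g.consanguinity
                )
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("coefficients must be finite")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


def default_config(n: int = 1000, coefficient_set: str = "table2",
                   genome: str | GenomeMap = "scaled") -> CohortConfig:
    """Shipped default configuration.

    ``genome`` is ``"scaled"`` (6 x 100 Mb, fast) or ``"human22"`` (22
    autosomes, ~2.88 Gb); F_ROH denominators follow the chosen map.
    """
    if isinstance(genome, str):
        genome = GenomeMap.scaled() if genome == "scaled" else GenomeMap.human22()
    return CohortConfig(
        n=n, genome=genome,
        coefficients=dict(COEFFICIENT_SETS[coefficient_set]),
    )


# ---------------------------------------------------------------------------
# covariate draws
# ---------------------------------------------------------------------------


def _draw_ancestry(group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) array of (aymara_quechua, mapuche_huilliche, european) proportions
    guaranteed to fall in the named ancestry category."""
    afr = rng.uniform(0.0, 0.03, n)
    u = rng.uniform(size=n)
    if group == "European":
        eur = rng.uniform(0.705, 0.95, n)
        rem = 1 - eur - afr
        aq, mh = rem * u, rem * (1 - u)
    elif group == "Aymara-Quechua":
        aq = rng.uniform(0.705, 0.95, n)
        rem = 1 - aq - afr
        mh = rem * u * 0.5
        eur = rem - mh
    elif group == "Aymara-Quechua-European":
        aq = rng.uniform(0.35, 0.70, n)
        rem = 1 - aq - afr
        mh = rem * u * 0.4
        eur = rem - mh
    elif group == "Mapuche-Huilliche":
        mh = rng.uniform(0.705, 0.95, n)
        rem = 1 - mh - afr
        aq = rem * u * 0.3
        eur = rem - aq
    elif group == "Mapuche-Huilliche-European":
        mh = rng.uniform(0.35, 0.70, n)
        rem = 1 - mh - afr
        aq = rem * u * 0.3
        eur = rem - aq
    elif group == "Other admixture":
        s = rng.uniform(0.31, 0.58, n)  # total indigenous, keeps European <= 0.70
        w_lo = np.maximum(0.0, 1 - 0.34 / s)
        w_hi = np.minimum(1.0, 0.34 / s)
        w = w_lo + u * (w_hi - w_lo)
        aq, mh = s * w, s * (1 - w)
        eur = 1 - s - afr
    else:
        raise ValueError(f"unknown ancestry group {group!r}")
    return np.column_stack([aq, mh, eur])


def _draw_age(n: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal age mix: younger population-based participants plus older
    patients; median ~37 years with IQR ~26-58."""
    young = rng.random(n) < 0.55
    age = np.where(young, rng.normal(32.0, 9.0, n), rng.normal(58.0, 12.0, n))
    return np.clip(age, 18.0, 90.0)


def _drift_long_sroh(group: GroupConfig, n: int, genome_mb: float,
                     rng: np.random.Generator,
                     threshold_mb: float = FROH_MIN_MB) -> np.ndarray:
    """Per-individual summed length (Mb) of drift tracts longer than the
    threshold, drawn from the mosaic process analytically (compound
    Poisson: tract count ~ Poisson, lengths threshold + Exp(mean tract))."""
    f = group.autozygous_fraction
    m = group.mean_tract_mb
    lam = genome_mb * f * math.exp(-threshold_mb / m) / m
    counts = rng.poisson(lam, n)
    total = int(counts.sum())
    lengths = threshold_mb + rng.exponential(m, total)
    out = np.zeros(n)
    np.add.at(out, np.repeat(np.arange(n), counts), lengths)
    return out


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw a full synthetic cohort table.

    Returns the cohort DataFrame (validated) and a ground-truth parameter
    dictionary including the solved intercept and per-individual group
    labels.  Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    n = config.n
    names = list(config.groups)
    fracs = np.array([config.groups[g].fraction for g in names])
    group_idx = rng.choice(len(names), size=n, p=fracs / fracs.sum())

    aq = np.empty(n)
    mh = np.empty(n)
    sroh = np.zeros(n)
    mating = np.array(["none"] * n, dtype=object)
    genome_mb = config.genome.total_mb
    for gi, gname in enumerate(names):
        mask = group_idx == gi
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        props = _draw_ancestry(gname, cnt, rng)
        aq[mask], mh[mask] = props[:, 0], props[:, 1]
        sroh[mask] = _drift_long_sroh(config.groups[gname], cnt, genome_mb, rng)
        # consanguinity routing
        gcfg = config.groups[gname]
        if gcfg.consanguinity:
            idx = np.nonzero(mask)[0]
            u = rng.random(cnt)
            lo = 0.0
            for mtype, frac in gcfg.consanguinity.items():
                sel = idx[(u >= lo) & (u < lo + frac)]
                mating[sel] = mtype
                lo += frac
    # gene-drop all routed individuals, grouped by mating class
    for mtype in pd.unique(mating):
        if mtype == "none":
            continue
        sel = np.nonzero(mating == mtype)[0]
        offs = simulate_mating(mtype, config.genome, n_offspring=len(sel),
                               threshold_mb=FROH_MIN_MB, seed=rng)
        sroh[sel] += np.array([o.sroh_gt_threshold_mb for o in offs])

    froh = np.clip(sroh / genome_mb, 0.0, 1.0)

    sex = np.where(rng.random(n) < SEX_MALE_PROB, "male", "female")
    age = _draw_age(n, rng)
    education = rng.choice(EDUCATION_LEVELS, size=n,
                           p=np.array(EDUCATION_PROBS) / sum(EDUCATION_PROBS))
    bmi = np.clip(rng.normal(26.4, 4.8, n), 16.0, 55.0)
    prs = np.exp(rng.normal(math.log(0.445), 0.2466, n))

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "education": education,
            "bmi": bmi,
            "aymara_quechua_pct": aq,
            "mapuche_huilliche_pct": mh,
            "gsd_prs": prs,
            "f_roh": froh,
            "outcome": 0,
        }
    )

    # linear predictor via the same design construction the estimator uses
    X = design_matrix(cohort)
    lp = np.zeros(n)
    for key, beta in config.coefficients.items():
        if key in _GENERATOR_INTERACTIONS:
            froh_pct = X["froh_pct"].to_numpy()
            if key == "froh_x_male":
                lp += beta * froh_pct * (sex == "male")
            elif key == "froh_x_young60":
                lp += beta * froh_pct * (age < 60)
            elif key == "froh_x_highprs":
                lp += beta * froh_pct * (prs > np.median(prs))
        elif key in X.columns:
            lp += beta * X[key].to_numpy()
        else:
            raise ValueError(f"coefficient {key!r} matches no design column")

    intercept = _solve_intercept(lp, config.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    outcome = (rng.random(n) < prob).astype(int)
    if outcome.min() == outcome.max():
        raise ValueError(
            "generated outcome is single-class; adjust prevalence/intercept"
        )
    cohort["outcome"] = outcome
    validate_cohort(cohort)

    params = {
        "coefficients": dict(config.coefficients),
        "intercept": float(intercept),
        "prevalence_target": config.prevalence,
        "prevalence_realized": float(outcome.mean()),
        "genome_mb": genome_mb,
        "groups": {g: asdict(cfg) for g, cfg in config.groups.items()},
        "group_labels": [names[i] for i in group_idx],
        "mating": mating.tolist(),
    }
    return cohort, params


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept giving the target mean case probability."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(1.0 / (1.0 + np.exp(-(lp + mid)))))
        if p < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# genotype-level generation
# ---------------------------------------------------------------------------


def _mosaic(length_mb: float, rate: float, pool: int,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype founder-label mosaic: (segment ends in Mb, labels)."""
    n_b = rng.poisson(rate * length_mb)
    cuts = np.sort(rng.uniform(0.0, length_mb, n_b))
    ends = np.append(cuts, length_mb)
    labels = rng.integers(0, pool, size=len(ends))
    return ends, labels


def _paint_chromosome(
    group: GroupConfig,
    pos_mb: np.ndarray,
    founder_alleles: np.ndarray,
    rng: np.random.Generator,
    forced_ibd_mb: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One individual's genotypes on one chromosome.

    Returns (genotype row int8, boolean autozygosity mask per SNP).  Both
    haplotypes are independent founder-label mosaics; inside any
    ``forced_ibd_mb`` interval (consanguinity overlay from a pedigree
    drop) the second haplotype copies the first, making the interval
    autozygous regardless of the drift mosaics.
    """
    length_mb = float(pos_mb[-1]) + 1e-9
    n_snps = pos_mb.size
    e1, l1 = _mosaic(length_mb, group.switch_rate_per_mb, group.pool_size, rng)
    e2, l2 = _mosaic(length_mb, group.switch_rate_per_mb, group.pool_size, rng)
    lab1 = l1[np.searchsorted(e1, pos_mb, side="right").clip(max=len(l1) - 1)]
    lab2 = l2[np.searchsorted(e2, pos_mb, side="right").clip(max=len(l2) - 1)]
    for start_mb, end_mb in forced_ibd_mb or []:
        inside = (pos_mb >= start_mb) & (pos_mb <= end_mb)
        lab2[inside] = lab1[inside]
    idx = np.arange(n_snps)
    geno = founder_alleles[lab1, idx] + founder_alleles[lab2, idx]
    return geno.astype(np.int8), lab1 == lab2


def _mask_runs(same: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    if not same.any():
        return []
    d = np.diff(same.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0]
    if same[0]:
        starts = np.concatenate([[0], starts])
    if same[-1]:
        ends = np.concatenate([ends, [same.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def generate_genotypes(
    group: GroupConfig | str,
    n: int,
    genome: GenomeMap | None = None,
    snp_spacing_bp: int = 5_000,
    seed: int | None = None,
    maf_uniform: tuple[float, float] = (0.5, 0.5),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Paint SNP genotypes on founder-pool haplotype mosaics for one group.

    Returns the genotype matrix and a ground-truth tract table (sample_id,
    chrom, start_bp, end_bp) holding the maximal runs of SNPs at which the
    two haplotypes descend from the same founder haplotype -- inside these
    tracts every painted SNP is homozygous by construction.

    ``group`` may be a :class:`GroupConfig` or a default group name.
    Founder alleles are drawn per SNP with allele-B frequency uniform in
    ``maf_uniform`` (degenerate at 0.5 by default).  SNP positions sit on a
    jittered grid of mean spacing ``snp_spacing_bp``; the spacing must
    support the ROH caller's window (>= ~30 SNPs per minimum segment
    length is the caller's own density requirement, not enforced here).
    """
    if isinstance(group, str):
        group = DEFAULT_GROUPS[group]
    genome = genome or GenomeMap.human22()
    rng = np.random.default_rng(seed)
    if snp_spacing_bp <= 0:
        raise ValueError("snp_spacing_bp must be positive")

    sample_ids = [f"S{i:06d}" for i in range(n)]
    g, truth = _paint_cohort(
        sample_ids, ["_only"] * n, {"_only": group}, [None] * n, genome,
        snp_spacing_bp, maf_uniform, rng,
    )
    return g, truth


def _paint_cohort(
    sample_ids: list[str],
    group_of: list[str],
    groups: dict[str, GroupConfig],
    forced_ibd: list[dict[str, list[tuple[float, float]]] | None],
    genome: GenomeMap,
    snp_spacing_bp: int,
    maf_uniform: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Paint genotypes for a mixed-group cohort on shared SNP positions.

    ``forced_ibd[i]`` optionally maps chromosome label -> autozygous
    intervals (Mb) to overlay for sample i (consanguinity).  Each group gets
    its own founder-allele pool; allele-B frequencies per SNP are shared.
    """
    n = len(sample_ids)
    var_frames, call_blocks, truth_rows = [], [], []
    for chrom, length_bp, _ in genome.chromosomes:
        n_snps = int(length_bp // snp_spacing_bp)
        if n_snps < 2:
            raise ValueError(
                f"chromosome {chrom}: SNP spacing {snp_spacing_bp} bp leaves "
                f"{n_snps} SNPs; reduce spacing"
            )
        pos = (np.arange(n_snps) * snp_spacing_bp
               + rng.uniform(1, snp_spacing_bp / 2, n_snps)).astype(np.int64)
        pos_mb = pos / 1e6
        pfreq = rng.uniform(*maf_uniform, size=n_snps)
        founders = {
            gname: (rng.random((gcfg.pool_size, n_snps)) < pfreq).astype(np.int8)
            for gname, gcfg in groups.items()
        }
        var_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "id": [f"snp_{chrom}_{p}" for p in pos],
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
        block = np.empty((n, n_snps), dtype=np.int8)
        for i in range(n):
            gname = group_of[i]
            intervals = (forced_ibd[i] or {}).get(chrom) if forced_ibd[i] else None
            block[i], same = _paint_chromosome(
                groups[gname], pos_mb, founders[gname], rng, intervals
            )
            for s0, s1 in _mask_runs(same):
                truth_rows.append(
                    {
                        "sample_id": sample_ids[i],
                        "chrom": chrom,
                        "start_bp": int(pos[s0]),
                        "end_bp": int(pos[s1]),
                        "n_snps": int(s1 - s0 + 1),
                    }
                )
        call_blocks.append(block)
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=pd.concat(var_frames, ignore_index=True),
        calls=np.concatenate(call_blocks, axis=1),
    )
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps"])
    return g, truth


def generate_cohort_genotypes(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict, GenotypeMatrix, pd.DataFrame]:
    """Full cohort draw at genotype resolution.

    Like :func:`generate_cohort` but each individual's haplotypes are
    painted as SNP genotypes (shared variant positions across groups) and
    F_ROH is computed from the ground-truth autozygous tracts.  Routed
    consanguineous individuals get pedigree-dropped autozygous intervals
    overlaid on their drift mosaics.  Returns (cohort, params, genotypes,
    truth tracts).  Intended for moderate n; use :func:`generate_cohort`
    for large association experiments.
    """
    from .pedigree_sim import _pedigree_offspring, _autozygous_tracts

    rng = np.random.default_rng(seed)
    n = config.n
    names = list(config.groups)
    fracs = np.array([config.groups[g].fraction for g in names])
    group_idx = rng.choice(len(names), size=n, p=fracs / fracs.sum())
    group_of = [names[i] for i in group_idx]
    sample_ids = [f"S{i:06d}" for i in range(n)]

    # consanguinity routing -> forced-IBD intervals from pedigree drops
    forced: list[dict[str, list[tuple[float, float]]] | None] = [None] * n
    mating = ["none"] * n
    for i in range(n):
        gcfg = config.groups[group_of[i]]
        u, lo = rng.random(), 0.0
        for mtype, frac in gcfg.consanguinity.items():
            if lo <= u < lo + frac:
                ped = _pedigree_offspring(mtype, config.genome, rng)
                tracts = _autozygous_tracts(ped, config.genome)
                by_chrom: dict[str, list[tuple[float, float]]] = {}
                for c, s, e in tracts:
                    by_chrom.setdefault(c, []).append((s / 1e6, e / 1e6))
                forced[i] = by_chrom
                mating[i] = mtype
                break
            lo += frac

    g, truth = _paint_cohort(
        sample_ids, group_of, config.groups, forced, config.genome,
        config.snp_spacing_bp, (0.5, 0.5), rng,
    )

    # F_ROH from ground-truth tracts above the conventional threshold
    genome_mb = config.genome.total_mb
    sroh = np.zeros(n)
    if len(truth):
        t = truth.assign(length_mb=(truth.end_bp - truth.start_bp + 1) / 1e6)
        t = t[t.length_mb > FROH_MIN_MB]
        sums = t.groupby("sample_id")["length_mb"].sum()
        for sid, val in sums.items():
            sroh[sample_ids.index(sid)] = val
    froh = np.clip(sroh / genome_mb, 0.0, 1.0)

    cohort = _covariates_and_outcome(config, froh, rng, group_of=group_of)
    cohort["sample_id"] = sample_ids
    params = {
        "coefficients": dict(config.coefficients),
        "genome_mb": genome_mb,
        "group_labels": group_of,
        "mating": mating,
    }
    return cohort, params, g, truth


def _covariates_and_outcome(config: CohortConfig, froh: np.ndarray,
                            rng: np.random.Generator,
                            group_of: list[str] | None = None) -> pd.DataFrame:
    """Draw covariates and the logistic outcome for given F_ROH values.

    ``group_of`` ties ancestry proportions to the group assignment that
    produced the F_ROH values, preserving the ancestry-homozygosity
    correlation of the cohort.
    """
    n = len(froh)
    names = list(config.groups)
    if group_of is None:
        fracs = np.array([config.groups[g].fraction for g in names])
        gidx = rng.choice(len(names), size=n, p=fracs / fracs.sum())
        group_of = [names[i] for i in gidx]
    group_arr = np.asarray(group_of)
    aq, mh = np.empty(n), np.empty(n)
    for gname in names:
        mask = group_arr == gname
        if mask.any():
            props = _draw_ancestry(gname, int(mask.sum()), rng)
            aq[mask], mh[mask] = props[:, 0], props[:, 1]
    sex = np.where(rng.random(n) < SEX_MALE_PROB, "male", "female")
    age = _draw_age(n, rng)
    education = rng.choice(EDUCATION_LEVELS, size=n,
                           p=np.array(EDUCATION_PROBS) / sum(EDUCATION_PROBS))
    bmi = np.clip(rng.normal(26.4, 4.8, n), 16.0, 55.0)
    prs = np.exp(rng.normal(math.log(0.445), 0.2466, n))
    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "education": education,
            "bmi": bmi,
            "aymara_quechua_pct": aq,
            "mapuche_huilliche_pct": mh,
            "gsd_prs": prs,
            "f_roh": froh,
            "outcome": 0,
        }
    )
    X = design_matrix(cohort)
    lp = np.zeros(n)
    for key, beta in config.coefficients.items():
        if key in _GENERATOR_INTERACTIONS:
            froh_pct = X["froh_pct"].to_numpy()
            if key == "froh_x_male":
                lp += beta * froh_pct * (sex == "male")
            elif key == "froh_x_young60":
                lp += beta * froh_pct * (age < 60)
            elif key == "froh_x_highprs":
                lp += beta * froh_pct * (prs > np.median(prs))
        elif key in X.columns:
            lp += beta * X[key].to_numpy()
        else:
            raise ValueError(f"coefficient {key!r} matches no design column")
    intercept = _solve_intercept(lp, config.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    outcome = (rng.random(n) < prob).astype(int)
    if outcome.min() == outcome.max():
        raise ValueError("generated outcome is single-class; adjust prevalence")
    cohort["outcome"] = outcome
    return validate_cohort(cohort)
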