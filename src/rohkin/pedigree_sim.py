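"""Forward simulation of consanguineous matings and autozygous tracts.

Offspring of a given mating class (second cousin, first cousin, avuncular,
incest) are produced by gene-dropping founder-labelled haplotypes through the
minimal pedigree for that class.  Meiosis follows the standard no-interference
model: the crossover count per chromosome is Poisson with mean equal to the
genetic length in Morgans and breakpoints fall uniformly in genetic distance.

Because founders are unrelated, non-inbred and carry unique haplotype labels,
an offspring is autozygous exactly where its two haplotypes carry the same
founder label; tract summaries (NROH/SROH above a length threshold, total
autozygous fraction) are read directly off those label-identity tracts.  No
population or drift is simulated, so tract statistics isolate the
consanguinity signal: expected autozygous fractions are the analytic kinship
coefficients 1/4 (incest), 1/8 (avuncular / double first cousin), 1/16
(first cousin) and 1/64 (second cousin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# (label, length_bp) of the 22 human autosomes, GRCh37-scale, ~2.88 Gb total
_HUMAN_AUTOSOME_MB = (
    249.3, 243.2, 198.0, 191.2, 180.9, 171.1, 159.1, 146.4, 141.2, 135.5,
    135.0, 133.9, 115.2, 107.3, 102.5, 90.4, 81.2, 78.1, 59.1, 63.0, 48.1, 51.3,
)


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths and recombination rates.

    ``chromosomes`` is a sequence of (label, length_bp, cM_per_Mb).  The
    default human map has 22 autosomes at a uniform sex-averaged 1 cM/Mb; a
    6 x 100 Mb scaled map is available for fast simulation.
    """

    chromosomes: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome map needs at least one chromosome")
        for label, length_bp, rate in self.chromosomes:
            if length_bp <= 0:
                raise ValueError(f"chromosome {label}: length must be positive")
            if rate < 0:
                raise ValueError(f"chromosome {label}: recombination rate must be >= 0")

    @property
    def total_bp(self) -> int:
        return sum(c[1] for c in self.chromosomes)

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6

    @classmethod
    def human22(cls, cm_per_mb: float = 1.0) -> "GenomeMap":
        return cls(
            tuple(
                (str(i + 1), int(mb * 1e6), cm_per_mb)
                for i, mb in enumerate(_HUMAN_AUTOSOME_MB)
            )
        )

    @classmethod
    def scaled(cls, n_chrom: int = 6, chrom_mb: float = 100.0,
               cm_per_mb: float = 1.0) -> "GenomeMap":
        """Small genome for fast tests (default 6 chromosomes x 100 Mb)."""
        return cls(
            tuple((str(i + 1), int(chrom_mb * 1e6), cm_per_mb) for i in range(n_chrom))
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            tuple(
                (str(r.chrom), int(r.length_bp), float(r.cM_per_Mb))
                for r in df.itertuples()
            )
        )


# A haplotype on one chromosome: (ends, labels) where ends are segment end
# positions in bp (strictly increasing, last == chromosome length) and labels
# are founder-haplotype identifiers.
Haplotype = tuple[np.ndarray, np.ndarray]
# An individual: list over chromosomes of (maternal, paternal) haplotypes.
Individual = list[tuple[Haplotype, Haplotype]]

MATING_TYPES = ("second_cousin", "first_cousin", "avuncular", "incest", "unrelated")


@dataclass
class SimulatedOffspring:
    """Autozygous-tract summary for one simulated offspring."""

    mating_type: str
    autozygous_tracts: list[tuple[str, int, int]]
    nroh_gt_threshold: int
    sroh_gt_threshold_mb: float
    f_auto: float


def meiosis(
    parent_haplotypes: tuple[Haplotype, Haplotype],
    length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One recombinant gamete for one chromosome.

    Crossover count ~ Poisson(genetic length in Morgans); breakpoints uniform
    (the per-chromosome rate is uniform, so uniform in bp equals uniform in
    genetic distance); the copied parental haplotype alternates at each
    breakpoint starting from a fair coin.
    """
    morgans = (length_bp / 1e6) * cm_per_mb / 100.0
    n_x = rng.poisson(morgans) if morgans > 0 else 0
    cur = int(rng.integers(2))
    if n_x == 0:
        ends, labels = parent_haplotypes[cur]
        return ends.copy(), labels.copy()
    cuts = np.sort(rng.uniform(0, length_bp, size=n_x))
    out_ends: list[float] = []
    out_labels: list[int] = []
    start = 0.0
    bounds = np.append(cuts, length_bp)
    for end in bounds:
        if end > start:
            ends, labels = parent_haplotypes[cur]
            i0 = int(np.searchsorted(ends, start, side="right"))
            i1 = int(np.searchsorted(ends, end, side="left"))
            for k in range(i0, i1 + 1):
                seg_end = min(float(ends[k]), float(end))
                lab = int(labels[k])
                if out_labels and out_labels[-1] == lab:
                    out_ends[-1] = seg_end
                else:
                    out_ends.append(seg_end)
                    out_labels.append(lab)
        cur = 1 - cur
        start = end
    return np.asarray(out_ends), np.asarray(out_labels, dtype=np.int64)


class _LabelSource:
    def __init__(self) -> None:
        self.next = 0

    def take(self) -> int:
        self.next += 1
        return self.next - 1


def _founder(genome: GenomeMap, labels: _LabelSource) -> Individual:
    ind: Individual = []
    for _, length_bp, _ in genome.chromosomes:
        h1 = (np.array([float(length_bp)]), np.array([labels.take()], dtype=np.int64))
        h2 = (np.array([float(length_bp)]), np.array([labels.take()], dtype=np.int64))
        ind.append((h1, h2))
    return ind


def _child(mother: Individual, father: Individual, genome: GenomeMap,
           rng: np.random.Generator) -> Individual:
    out: Individual = []
    for ci, (_, length_bp, rate) in enumerate(genome.chromosomes):
        hm = meiosis(mother[ci], length_bp, rate, rng)
        hp = meiosis(father[ci], length_bp, rate, rng)
        out.append((hm, hp))
    return out


def _autozygous_tracts(ind: Individual, genome: GenomeMap) -> list[tuple[str, int, int]]:
    """Maximal intervals where the two haplotypes carry the same founder label."""
    tracts: list[tuple[str, int, int]] = []
    for ci, (label, _, _) in enumerate(genome.chromosomes):
        (e1, l1), (e2, l2) = ind[ci]
        ends = np.union1d(e1, e2)
        starts = np.concatenate([[0.0], ends[:-1]])
        mids = (starts + ends) / 2.0
        same = l1[np.searchsorted(e1, mids, side="right").clip(max=len(l1) - 1)] == \
            l2[np.searchsorted(e2, mids, side="right").clip(max=len(l2) - 1)]
        start: float | None = None
        for k in range(len(ends)):
            if same[k] and start is None:
                start = starts[k]
            if start is not None and (not same[k]):
                tracts.append((label, int(round(start)), int(round(starts[k]))))
                start = None
        if start is not None:
            tracts.append((label, int(round(start)), int(round(ends[-1]))))
    return [(c, s, e) for c, s, e in tracts if e > s]


def _pedigree_offspring(mating_type: str, genome: GenomeMap,
                        rng: np.random.Generator,
                        incest_variant: str = "parent_offspring",
                        avuncular_variant: str = "uncle_niece") -> Individual:
    labels = _LabelSource()
    F = lambda: _founder(genome, labels)  # noqa: E731
    C = lambda m, f: _child(m, f, genome, rng)  # noqa: E731
    if mating_type == "unrelated":
        return C(F(), F())
    if mating_type == "incest":
        a, b = F(), F()
        s1 = C(a, b)
        if incest_variant == "parent_offspring":
            return C(a, s1)
        s2 = C(a, b)
        return C(s1, s2)
    if mating_type == "avuncular":
        if avuncular_variant == "double_first_cousin":
            a, b, c, d = F(), F(), F(), F()
            p1 = C(C(a, b), C(c, d))
            p2 = C(C(a, b), C(c, d))
            return C(p1, p2)
        a, b = F(), F()
        s1, s2 = C(a, b), C(a, b)
        niece = C(s2, F())
        return C(s1, niece)
    if mating_type == "first_cousin":
        a, b = F(), F()
        c1 = C(C(a, b), F())
        c2 = C(C(a, b), F())
        return C(c1, c2)
    if mating_type == "second_cousin":
        a, b = F(), F()
        c1 = C(C(a, b), F())
        c2 = C(C(a, b), F())
        d1, d2 = C(c1, F()), C(c2, F())
        return C(d1, d2)
    raise ValueError(
        f"unknown mating type {mating_type!r}; valid types: {', '.join(MATING_TYPES)}"
    )


def offspring_summary(ind: Individual, genome: GenomeMap, mating_type: str,
                      threshold_mb: float = 1.5) -> SimulatedOffspring:
    tracts = _autozygous_tracts(ind, genome)
    lengths_mb = np.array([(e - s) / 1e6 for _, s, e in tracts])
    long = lengths_mb > threshold_mb
    return SimulatedOffspring(
        mating_type=mating_type,
        autozygous_tracts=tracts,
        nroh_gt_threshold=int(long.sum()),
        sroh_gt_threshold_mb=float(lengths_mb[long].sum()),
        f_auto=float(lengths_mb.sum() * 1e6 / genome.total_bp),
    )


def simulate_mating(
    mating_type: str,
    genome: GenomeMap | None = None,
    n_offspring: int = 5000,
    threshold_mb: float = 1.5,
    seed: int | np.random.Generator | None = None,
    incest_variant: str = "parent_offspring",
    avuncular_variant: str = "uncle_niece",
) -> list[SimulatedOffspring]:
    """Simulate ``n_offspring`` independent offspring of one mating class.

    Each offspring comes from a freshly gene-dropped minimal pedigree with
    unique unrelated founders, so offspring are i.i.d.  ``incest`` defaults
    to parent-offspring (``incest_variant='sibling'`` for brother-sister)
    and ``avuncular`` to uncle-niece (``avuncular_variant=
    'double_first_cousin'`` for the F = 1/8 cousin variant).
    """
    if mating_type not in MATING_TYPES:
        raise ValueError(
            f"unknown mating type {mating_type!r}; valid types: {', '.join(MATING_TYPES)}"
        )
    genome = genome or GenomeMap.human22()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_offspring):
        ind = _pedigree_offspring(mating_type, genome, rng,
                                  incest_variant, avuncular_variant)
        out.append(offspring_summary(ind, genome, mating_type, threshold_mb))
    return out


@dataclass
class Envelope:
    """Summary of one mating type's (NROH, SROH) point cloud."""

    mating_type: str
    mean: np.ndarray  # (mean NROH, mean SROH in Mb)
    cov: np.ndarray   # 2x2 covariance
    hull_points: np.ndarray = field(repr=False)  # vertices or all points if degenerate


def simulation_envelope(
    offspring_by_type: dict[str, list[SimulatedOffspring]]
) -> dict[str, Envelope]:
    """Per-type mean/covariance and convex hull of (NROH, SROH) points."""
    out: dict[str, Envelope] = {}
    for mtype, offs in offspring_by_type.items():
        if len(offs) < 2:
            raise ValueError(f"mating type {mtype}: need >= 2 offspring")
        pts = np.array([[o.nroh_gt_threshold, o.sroh_gt_threshold_mb] for o in offs])
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T, ddof=1)
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts)
            hull_pts = pts[hull.vertices]
        except Exception:  # degenerate (collinear/duplicated) clouds
            hull_pts = np.unique(pts, axis=0)
        out[mtype] = Envelope(mating_type=mtype, mean=mean, cov=np.atleast_2d(cov),
                              hull_points=hull_pts)
    return out


def offspring_to_frame(offspring: list[SimulatedOffspring]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mating_type": [o.mating_type for o in offspring],
            "nroh": [o.nroh_gt_threshold for o in offspring],
            "sroh_mb": [o.sroh_gt_threshold_mb for o in offspring],
            "f_auto": [o.f_auto for o in offspring],
        }
    )
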