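"""One-time calibration of the synthetic-cohort drift parameters.

For each candidate founder-label switch rate, generates a small synthetic
panel for the Aymara-Quechua-like group on the 22-autosome map, applies the
MAF screen, calls ROH and reports the group mean summed length of short
(0.3-1 Mb) called ROH plus the median F_ROH (> 1.5 Mb / 3 Gb).  The chosen
rate is stored in ``rohkin.synthetic_cohort.DEFAULT_GROUPS``.

Usage: python scripts/calibrate_generator.py [--n 40] [--seed 7]
"""

import argparse
import collections

import numpy as np

from rohkin.genotype_io import apply_variant_filters
from rohkin.inbreeding import class_sums
from rohkin.pedigree_sim import GenomeMap
from rohkin.roh_caller import call_roh
from rohkin.synthetic_cohort import GroupConfig, generate_genotypes


def evaluate(pool: int, rate: float, n: int, seed: int,
             spacing: int = 5_000) -> tuple[float, float]:
    grp = GroupConfig(1.0, pool, rate)
    g, _ = generate_genotypes(grp, n=n, genome=GenomeMap.human22(),
                              snp_spacing_bp=spacing, seed=seed)
    gq = apply_variant_filters(g, maf_min=0.01, hwe_p_min=None)
    segs = call_roh(gq)
    by = collections.defaultdict(list)
    for s in segs:
        by[s.sample_id].append(s)
    shorts, frohs = [], []
    for sid in g.sample_ids:
        cs = class_sums(by.get(sid, []))
        shorts.append(cs[0] + cs[1])
        frohs.append(sum(s.length_mb for s in by.get(sid, []) if s.length_mb > 1.5) / 3000.0)
    return float(np.mean(shorts)), float(np.median(frohs))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=40)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--pool", type=int, default=3)
    ap.add_argument("--rates", type=float, nargs="+",
                    default=[1.8, 1.9, 2.0, 2.1, 2.2, 2.3])
    args = ap.parse_args()
    print("rate\tmean_short_sum_Mb\tmedian_F_ROH")
    for rate in args.rates:
        short, froh = evaluate(args.pool, rate, args.n, args.seed)
        print(f"{rate}\t{short:.1f}\t{froh:.4f}")


if __name__ == "__main__":
    main()
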