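"""Literal brute-force reference implementation of the ROH scan.

Written independently of the vectorized caller: every window is enumerated
explicitly and the five steps (window homozygosity, per-SNP hit rate,
candidate runs with gap splitting, threshold screening, boundary trimming)
are applied one by one with plain Python loops.  Used only as a test oracle.
"""

from rohkin.genotype_io import MISSING, GenotypeMatrix
from rohkin.roh_caller import ROHParams, ROHSegment


def call_roh_bruteforce(g: GenotypeMatrix, params: ROHParams) -> list[ROHSegment]:
    out = []
    chrom_order = list(dict.fromkeys(g.variants["chrom"].tolist()))
    for si, sid in enumerate(g.sample_ids):
        for chrom in chrom_order:
            idx = [j for j in range(g.n_variants) if g.variants["chrom"][j] == chrom]
            pos = [int(g.variants["pos"][j]) for j in idx]
            geno = [int(g.calls[si, j]) for j in idx]
            out.extend(_one(sid, chrom, pos, geno, params))
    return out


def _one(sid, chrom, pos, geno, p: ROHParams):
    s = len(geno)
    w = p.window_snps
    if s < w:
        return []
    # step (i): classify every full window
    hom_window = []
    for start in range(s - w + 1):
        window = geno[start : start + w]
        n_het = sum(1 for x in window if x == 1)
        n_mis = sum(1 for x in window if x == MISSING)
        hom_window.append(n_het <= p.window_het_max and n_mis <= p.window_missing_max)
    # step (ii): per-SNP hit rate over the windows containing it
    flagged = []
    for j in range(s):
        covering = [
            hom_window[start]
            for start in range(s - w + 1)
            if start <= j <= start + w - 1
        ]
        rate = sum(covering) / len(covering)
        flagged.append(rate >= p.window_hit_threshold)
    # step (iii): maximal flagged runs, split at large gaps
    runs = []
    cur = []
    for j in range(s):
        if not flagged[j]:
            if cur:
                runs.append(cur)
                cur = []
            continue
        if cur and pos[j] - pos[cur[-1]] > p.max_gap_kb * 1000:
            runs.append(cur)
            cur = []
        cur.append(j)
    if cur:
        runs.append(cur)
    # steps (iv)-(v): trim to homozygous non-missing boundaries, then screen
    segs = []
    for run in runs:
        a, b = run[0], run[-1]
        while a <= b and geno[a] not in (0, 2):
            a += 1
        while b >= a and geno[b] not in (0, 2):
            b -= 1
        if a > b:
            continue
        n_snps = b - a + 1
        length_bp = pos[b] - pos[a] + 1
        if n_snps < p.min_snps:
            continue
        if length_bp < p.min_length_kb * 1000:
            continue
        if length_bp / 1000.0 > n_snps * p.density_kb_per_snp:
            continue
        segs.append(
            ROHSegment(sample_id=sid, chromosome=str(chrom),
                       start_bp=pos[a], end_bp=pos[b], n_snps=n_snps)
        )
    return segs
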