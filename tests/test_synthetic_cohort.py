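import numpy as np
import pandas as pd
import pytest

from rohkin.association import ancestry_category, fit_gbc_model
from rohkin.genotype_io import MISSING, validate_cohort
from rohkin.pedigree_sim import GenomeMap
from rohkin.roh_caller import ROHParams, call_roh
from rohkin.synthetic_cohort import (
    COEFFS_TABLE2,
    CohortConfig,
    GroupConfig,
    default_config,
    generate_cohort,
    generate_cohort_genotypes,
    generate_genotypes,
)

SMALL_GM = GenomeMap.scaled(n_chrom=3, chrom_mb=60.0)


class TestCohortGeneration:
    def test_same_seed_identical_output(self):
        cfg = default_config(n=500)
        a, pa = generate_cohort(cfg, seed=21)
        b, pb = generate_cohort(cfg, seed=21)
        assert a.equals(b)
        assert pa["intercept"] == pb["intercept"]

    def test_validates_against_cohort_schema(self):
        cohort, _ = generate_cohort(default_config(n=300), seed=1)
        validate_cohort(cohort)  # raises on violation

    def test_intercept_only_model_hits_target_prevalence(self):
        cfg = default_config(n=20_000)
        cfg.coefficients = {k: 0.0 for k in COEFFS_TABLE2}
        cfg.prevalence = 0.15
        cohort, _ = generate_cohort(cfg, seed=2)
        assert cohort["outcome"].mean() == pytest.approx(0.15, abs=0.01)

    def test_group_labels_consistent_with_ancestry_rules(self):
        cohort, params = generate_cohort(default_config(n=2000), seed=3)
        eur = 1.0 - cohort.aymara_quechua_pct - cohort.mapuche_huilliche_pct
        for i in range(0, 2000, 37):
            cat = ancestry_category(
                cohort.aymara_quechua_pct[i], cohort.mapuche_huilliche_pct[i],
                min(eur[i], 1.0),
            )
            # the generator reserves part of the residue for a small African
            # component, so European proportion here is an upper bound; the
            # only category this can flip is European vs Other admixture
            assert params["group_labels"][i] in (cat, "Other admixture", "European")

    def test_group_froh_ordering_matches_design(self):
        """Groups with small founder pools carry more homozygosity."""
        cohort, params = generate_cohort(default_config(n=8000), seed=4)
        lab = pd.Series(params["group_labels"])
        med = cohort.groupby(lab.values)["f_roh"].median()
        assert med["Aymara-Quechua"] > med["Mapuche-Huilliche-European"]
        assert med["Mapuche-Huilliche"] > med["Other admixture"]

    def test_consanguinity_routing_fattens_upper_tail(self):
        cfg = default_config(n=4000)
        cohort, params = generate_cohort(cfg, seed=5)
        mating = np.array(params["mating"])
        routed = cohort.f_roh[mating != "none"]
        unrouted = cohort.f_roh[mating == "none"]
        assert routed.mean() > unrouted.mean()


class TestGenotypeGeneration:
    def test_degenerate_pool_gives_near_total_homozygosity(self):
        grp = GroupConfig(1.0, 2, 0.05)  # two founders, very long tracts
        g, truth = generate_genotypes(grp, n=4, genome=SMALL_GM,
                                      snp_spacing_bp=20_000, seed=6)
        het_rate = (g.calls == 1).mean()
        assert het_rate < 0.3
        covered = truth.assign(mb=(truth.end_bp - truth.start_bp) / 1e6) \
            .groupby("sample_id").mb.sum().mean()
        assert covered > 0.25 * SMALL_GM.total_mb  # autozygous fraction ~1/2

    def test_large_pool_outbred_limit(self):
        grp = GroupConfig(1.0, 500, 2.0)
        g, truth = generate_genotypes(grp, n=5, genome=SMALL_GM,
                                      snp_spacing_bp=20_000, seed=7)
        if len(truth):
            long_mb = (truth.end_bp - truth.start_bp).max() / 1e6
            assert long_mb < 1.5  # no long autozygous tract
    def test_truth_tracts_are_homozygous_at_every_snp(self):
        grp = GroupConfig(1.0, 3, 2.0)
        g, truth = generate_genotypes(grp, n=3, genome=SMALL_GM,
                                      snp_spacing_bp=10_000, seed=8)
        pos = g.variants["pos"].to_numpy()
        chroms = g.variants["chrom"].to_numpy()
        for row in truth.itertuples():
            si = g.sample_ids.index(row.sample_id)
            inside = (chroms == row.chrom) & (pos >= row.start_bp) & (pos <= row.end_bp)
            calls = g.calls[si, inside]
            assert np.isin(calls[calls != MISSING], (0, 2)).all()

    def test_called_roh_overlap_truth_jaccard(self):
        """Caller recovers the generator's long autozygous tracts."""
        from rohkin.synthetic_cohort import DEFAULT_GROUPS

        grp = DEFAULT_GROUPS["Aymara-Quechua"]
        g, truth = generate_genotypes(grp, n=6, genome=SMALL_GM,
                                      snp_spacing_bp=10_000, seed=9)
        segs = call_roh(g, ROHParams())
        truth = truth.assign(mb=(truth.end_bp - truth.start_bp + 1) / 1e6)
        truth_long = truth[truth.mb > 1.5]
        # base-pair Jaccard between called and true tracts > 1.5 Mb
        def intervals(df_or_segs, sid):
            if isinstance(df_or_segs, pd.DataFrame):
                sub = df_or_segs[df_or_segs.sample_id == sid]
                return [(r.chrom, r.start_bp, r.end_bp) for r in sub.itertuples()]
            return [(s.chromosome, s.start_bp, s.end_bp) for s in df_or_segs
                    if s.sample_id == sid and s.length_mb > 1.5]

        inter = union = 0
        for sid in g.sample_ids:
            t = intervals(truth_long, sid)
            c = intervals(segs, sid)
            for chrom in {x[0] for x in t} | {x[0] for x in c}:
                tt = [(s, e) for ch, s, e in t if ch == chrom]
                cc = [(s, e) for ch, s, e in c if ch == chrom]
                grid = np.zeros(SMALL_GM.total_bp // 10_000 + 2, dtype=np.int8)
                for s, e in tt:
                    grid[s // 10_000: e // 10_000 + 1] |= 1
                for s, e in cc:
                    grid[s // 10_000: e // 10_000 + 1] |= 2
                inter += int(np.sum(grid == 3))
                union += int(np.sum(grid > 0))
        assert union > 0
        assert inter / union > 0.8

    def test_too_sparse_spacing_rejected(self):
        grp = GroupConfig(1.0, 3, 2.0)
        with pytest.raises(ValueError, match="spacing"):
            generate_genotypes(grp, n=1, genome=SMALL_GM, snp_spacing_bp=10**9)


class TestGenotypeCohort:
    def test_cohort_genotypes_consistent(self):
        cfg = CohortConfig(n=12, genome=SMALL_GM, snp_spacing_bp=20_000)
        cohort, params, g, truth = generate_cohort_genotypes(cfg, seed=10)
        assert g.n_samples == 12
        assert len(cohort) == 12
        validate_cohort(cohort)
        # F_ROH in the table equals the truth-tract fraction
        t = truth.assign(mb=(truth.end_bp - truth.start_bp + 1) / 1e6)
        t = t[t.mb > 1.5].groupby("sample_id").mb.sum()
        for sid, val in t.items():
            got = float(cohort.set_index("sample_id").loc[sid, "f_roh"])
            assert got == pytest.approx(val / SMALL_GM.total_mb, rel=1e-9)


class TestRecoveryClosure:
    def test_generating_coefficients_recovered(self):
        """Estimator closure: the association layer recovers what the
        generator planted (checked loosely here on a mid-size cohort)."""
        cohort, _ = generate_cohort(default_config(n=20_000), seed=11)
        res = fit_gbc_model(cohort)
        for term, target in [("sex_female", 3.48), ("mapuche_huilliche_pctpt", 1.02)]:
            d = res.term(term)
            assert d["ci_low"] < target < d["ci_high"] or abs(np.log(d["or"]) - np.log(target)) < 0.15
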