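import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import make_matrix
from rohkin.genotype_io import (
    MISSING,
    GenotypeFormatError,
    apply_variant_filters,
    hwe_exact_pvalue,
    read_plink,
    write_plink,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided HWE p-value by full enumeration with rationals."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (n_a - h) // 2
        bb = (2 * n - n_a - h) // 2
        probs[h] = (
            Fraction(2) ** h
            * Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb))
        )
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHWEExact:
    def test_most_probable_het_count_gives_p_one(self):
        assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_total_het_deficit_is_extreme(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-20

    def test_monomorphic_is_uninformative(self):
        assert hwe_exact_pvalue(10, 0, 0) == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (3, 5, 2), (40, 20, 40), (0, 7, 93),
        (12, 1, 3), (60, 75, 65), (1, 1, 1), (10, 30, 5),
    ])
    def test_matches_rational_enumeration(self, counts):
        got = hwe_exact_pvalue(*counts)
        want = hwe_enumeration_oracle(*counts)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_enumeration_on_random_counts(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 67, size=3)
            if counts.sum() == 0:
                continue
            got = hwe_exact_pvalue(*counts)
            want = hwe_enumeration_oracle(*(int(c) for c in counts))
            assert got == pytest.approx(want, abs=1e-12)


class TestPlinkRoundTrip:
    def test_roundtrip_preserves_every_code(self, tmp_path, rng):
        calls = rng.choice([0, 1, 2, MISSING], size=(3, 4)).astype(np.int8)
        g = make_matrix(calls)
        paths = [tmp_path / f"x.{ext}" for ext in ("bed", "bim", "fam")]
        write_plink(g, *paths)
        g2 = read_plink(*paths)
        assert g2.calls.shape == (3, 4)
        assert np.array_equal(g2.calls, calls)
        assert g2.sample_ids == g.sample_ids
        assert list(g2.variants["pos"]) == list(g.variants["pos"])

    def test_single_missing_call_round_trips(self, tmp_path):
        calls = np.zeros((3, 4), dtype=np.int8)
        calls[1, 2] = MISSING
        g = make_matrix(calls)
        paths = [tmp_path / f"m.{ext}" for ext in ("bed", "bim", "fam")]
        write_plink(g, *paths)
        g2 = read_plink(*paths)
        assert (g2.calls == MISSING).sum() == 1
        assert g2.calls[1, 2] == MISSING

    def test_truncated_bed_raises_format_error(self, tmp_path):
        g = make_matrix(np.zeros((3, 4), dtype=np.int8))
        paths = [tmp_path / f"t.{ext}" for ext in ("bed", "bim", "fam")]
        write_plink(g, *paths)
        raw = paths[0].read_bytes()
        paths[0].write_bytes(raw[:-1])
        with pytest.raises(GenotypeFormatError, match="bed"):
            read_plink(*paths)

    def test_bad_magic_raises_format_error(self, tmp_path):
        g = make_matrix(np.zeros((2, 2), dtype=np.int8))
        paths = [tmp_path / f"b.{ext}" for ext in ("bed", "bim", "fam")]
        write_plink(g, *paths)
        raw = bytearray(paths[0].read_bytes())
        raw[0] ^= 0xFF
        paths[0].write_bytes(bytes(raw))
        with pytest.raises(GenotypeFormatError, match="magic"):
            read_plink(*paths)

    def test_non_autosomes_dropped_on_load(self, tmp_path):
        g = make_matrix(
            np.zeros((2, 3), dtype=np.int8),
            positions=[100, 200, 100],
            chroms=["1", "1", "23"],
        )
        paths = [tmp_path / f"c.{ext}" for ext in ("bed", "bim", "fam")]
        write_plink(g, *paths)
        g2 = read_plink(*paths)
        assert g2.n_variants == 2
        assert set(g2.variants["chrom"]) == {"1"}


class TestVariantFilters:
    def _fixture(self):
        # 100 samples x 10 SNPs; SNP 3 has MAF 0.005, SNP 7 has counts (50,0,50)
        rng = np.random.default_rng(7)
        calls = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(100, 10)).astype(np.int8)
        calls[:, 3] = 0
        calls[0, 3] = 1  # one het in 100 -> MAF 0.005
        calls[:50, 7] = 0
        calls[50:, 7] = 2  # (50, 0, 50): HWE p ~ 1e-30
        return make_matrix(calls)

    def test_maf_and_hwe_failures_removed(self):
        g = self._fixture()
        gq = apply_variant_filters(g, maf_min=0.01, hwe_p_min=0.001)
        assert gq.n_variants == 8
        kept = set(gq.variants["id"])
        assert "snp3" not in kept and "snp7" not in kept

    def test_monomorphic_removed(self):
        calls = np.zeros((20, 2), dtype=np.int8)
        # snp1 in Hardy-Weinberg proportions (5 AA, 10 AB, 5 BB); snp0 monomorphic
        calls[:5, 1] = 0
        calls[5:15, 1] = 1
        calls[15:, 1] = 2
        g = make_matrix(calls)
        gq = apply_variant_filters(g, maf_min=0.01, hwe_p_min=0.001)
        assert list(gq.variants["id"]) == ["snp1"]

    def test_maf_exactly_at_threshold_retained(self):
        # 100 samples, one het among 100 diploids at SNP 0 -> MAF exactly 0.01
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[0, 0] = 1
        calls[1, 0] = 1
        calls[:50, 1] = 1  # companion polymorphic SNP
        g = make_matrix(calls)
        assert g.maf()[0] == pytest.approx(0.01)
        gq = apply_variant_filters(g, maf_min=0.01, hwe_p_min=None)
        assert "snp0" in set(gq.variants["id"])

    def test_idempotent(self):
        g = self._fixture()
        once = apply_variant_filters(g)
        twice = apply_variant_filters(once)
        assert twice.n_variants == once.n_variants
        assert np.array_equal(once.calls, twice.calls)

    def test_all_removed_raises(self):
        calls = np.zeros((10, 2), dtype=np.int8)  # all monomorphic
        with pytest.raises(ValueError, match="every SNP"):
            apply_variant_filters(make_matrix(calls))
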