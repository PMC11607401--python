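import math

import numpy as np
import pandas as pd
import pytest

from ygeneflow import popstats
from ygeneflow.popstats import (
    ABBACounts,
    GenotypeMatrix,
    abba_baba_counts,
    apply_site_filters,
    block_jackknife_z,
    coalescence_time_from_dxy,
    d_statistic,
    dxy_windows,
    f_d_windows,
    read_popmap,
    read_vcf,
    write_vcf,
)


def make_matrix(dosage, samples, pops, ploidy=2, chrom="chr1", locus_length=None,
                **kwargs):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        chrom=np.array([chrom] * dosage.shape[0], dtype=object),
        pos=np.arange(1, dosage.shape[0] + 1, dtype=np.int64),
        dosage=dosage,
        samples=list(samples),
        populations=dict(zip(samples, pops)),
        ploidy=ploidy,
        locus_length=locus_length,
        **kwargs,
    )


QUARTET = ("p1", "p2", "p3", "og")


def quartet_matrix(freq_rows, ploidy=1, **kwargs):
    """One haploid sample per population: dosages are frequencies 0/1."""
    return make_matrix(
        freq_rows, ["a", "b", "c", "d"], list(QUARTET), ploidy=ploidy, **kwargs
    )


class TestSiteFilters:
    def base(self):
        dosage = [[1, 1], [1, 2], [0, 1]]
        depth = np.full((3, 2), 30.0)
        minor = np.full((3, 2), 0.5)
        return make_matrix(
            dosage,
            ["s1", "s2"],
            ["x", "y"],
            depth=depth,
            minor_fraction=minor,
        )

    def test_low_allele_balance_het_masked(self):
        m = self.base()
        m.minor_fraction[0, 0] = 0.20
        out, report = apply_site_filters(m, {"s1": 30, "s2": 30})
        assert np.isnan(out.dosage[0, 0])
        assert report["masked_allele_balance"] == 1

    def test_balance_boundary_inclusive(self):
        m = self.base()
        m.minor_fraction[0, 0] = 0.25
        out, _ = apply_site_filters(m, {"s1": 30, "s2": 30})
        assert out.dosage[0, 0] == 1

    def test_depth_boundaries(self):
        m = self.base()
        m.depth[0, 0] = 75.0  # 2.5x mean -> masked
        m.depth[1, 0] = 60.0  # exactly 2.0x -> retained
        m.depth[2, 0] = 15.0  # exactly 0.5x -> retained
        out, report = apply_site_filters(m, {"s1": 30, "s2": 30})
        assert np.isnan(out.dosage[0, 0])
        assert out.dosage[1, 0] == 1
        assert out.dosage[2, 0] == 0
        assert report["masked_depth"] == 1

    def test_y_het_site_dropped_for_all_samples(self):
        m = self.base()
        out, report = apply_site_filters(
            m, {"s1": 30, "s2": 30}, y_chroms=("chr1",)
        )
        # sites 1 and 2 contain a heterozygote (dosage 1) somewhere
        assert report["dropped_y_het_sites"] == 3
        assert out.n_sites == 0

    def test_missing_metadata_named(self):
        m = make_matrix([[0, 1]], ["s1", "s2"], ["x", "y"])
        with pytest.raises(ValueError, match="depth"):
            apply_site_filters(m, {"s1": 30, "s2": 30})
        m2 = make_matrix(
            [[0, 1]], ["s1", "s2"], ["x", "y"], depth=np.full((1, 2), 30.0)
        )
        with pytest.raises(ValueError, match="minor_fraction"):
            apply_site_filters(m2, {"s1": 30, "s2": 30})


class TestAbbaBaba:
    def test_canonical_abba_site(self):
        m = quartet_matrix([[0, 1, 1, 0]])
        counts = abba_baba_counts(m, QUARTET)
        assert counts.abba == pytest.approx(1.0)
        assert counts.baba == pytest.approx(0.0)

    def test_p1_equals_p2_gives_symmetry(self, rng):
        rows = rng.integers(0, 2, size=(40, 4))
        rows[:, 1] = rows[:, 0]  # P2 == P1 at every site
        rows[:, 3] = 0
        m = quartet_matrix(rows)
        counts = abba_baba_counts(m, QUARTET)
        assert counts.abba == pytest.approx(counts.baba)

    def test_matches_per_site_brute_force(self, rng):
        """Frequency-weighted counts equal an independent per-site loop."""
        rows = rng.integers(0, 3, size=(50, 4)).astype(float)
        m = make_matrix(rows, ["a", "b", "c", "d"], list(QUARTET), ploidy=2)
        counts = abba_baba_counts(m, QUARTET)
        abba = baba = 0.0
        for r in rows:
            p = r / 2.0
            if p[3] not in (0.0, 1.0):
                continue
            if p[3] == 1.0:
                p = 1.0 - p
            abba += (1 - p[0]) * p[1] * p[2]
            baba += p[0] * (1 - p[1]) * p[2]
        assert counts.abba == pytest.approx(abba)
        assert counts.baba == pytest.approx(baba)
        assert counts.block_abba.sum() == pytest.approx(counts.abba)

    def test_polymorphic_outgroup_sites_skipped(self):
        m = make_matrix(
            [[0, 2, 2, 1]], ["a", "b", "c", "d"], list(QUARTET), ploidy=2
        )
        counts = abba_baba_counts(m, QUARTET)
        assert counts.abba == 0.0 and counts.n_sites_used == 0


class TestDStatistic:
    def test_arithmetic(self):
        c = ABBACounts(60.0, 40.0, np.array([60.0]), np.array([40.0]))
        assert d_statistic(c) == pytest.approx(0.2)

    def test_balanced_counts_give_zero(self):
        c = ABBACounts(10.0, 10.0, np.array([10.0]), np.array([10.0]))
        assert d_statistic(c) == 0.0

    def test_zero_denominator_flagged_not_zero(self):
        c = ABBACounts(0.0, 0.0, np.array([0.0]), np.array([0.0]))
        assert math.isnan(d_statistic(c))


class TestBlockJackknife:
    def test_matches_independent_jackknife(self, rng):
        """SE equals a from-scratch delete-one implementation."""
        ab = rng.uniform(5, 15, 20)
        bb = rng.uniform(5, 15, 20)
        counts = ABBACounts(ab.sum(), bb.sum(), ab, bb)
        se, z = block_jackknife_z(counts)
        n = 20
        d_loo = []
        for i in range(n):
            a = ab.sum() - ab[i]
            b = bb.sum() - bb[i]
            d_loo.append((a - b) / (a + b))
        d_loo = np.array(d_loo)
        se_ref = math.sqrt((n - 1) / n * ((d_loo - d_loo.mean()) ** 2).sum())
        assert se == pytest.approx(se_ref)
        assert z == pytest.approx(d_statistic(counts) / se_ref)

    def test_identical_blocks_degenerate(self):
        ab = np.full(20, 3.0)
        bb = np.full(20, 1.0)
        counts = ABBACounts(ab.sum(), bb.sum(), ab, bb)
        se, z = block_jackknife_z(counts)
        assert se == 0.0 and math.isinf(z)

    def test_zero_d_gives_zero_z(self, rng):
        ab = rng.uniform(1, 5, 20)
        counts = ABBACounts(ab.sum(), ab.sum(), ab, ab.copy())
        se, z = block_jackknife_z(counts)
        assert z == 0.0

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError):
            block_jackknife_z(ABBACounts(1.0, 1.0, np.array([1.0]), np.array([1.0])))

    def test_se_shrinks_with_block_count(self, rng):
        """On iid blocks the jackknife SE scales like 1/sqrt(blocks)."""
        ses = []
        for n in (10, 40, 160):
            ab = rng.uniform(5, 15, n)
            bb = rng.uniform(5, 15, n)
            se, _ = block_jackknife_z(ABBACounts(ab.sum(), bb.sum(), ab, bb))
            ses.append(se)
        assert ses[0] > ses[1] > ses[2]


class TestFdWindows:
    def test_p2_equals_p3_gives_one(self):
        rows = np.array([[0, 1, 1, 0], [0, 1, 1, 0], [1, 1, 1, 0]], dtype=float)
        m = quartet_matrix(rows, locus_length=100)
        t = f_d_windows(m, QUARTET, 100)
        assert t["f_d"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        rows = rng.integers(0, 2, size=(30, 4)).astype(float)
        rows[:, 3] = 0
        m = quartet_matrix(rows, locus_length=100)
        t = f_d_windows(m, QUARTET, 100)
        num = den = 0.0
        for p1, p2, p3, po in rows:
            pdn = max(p2, p3)
            num += (1 - p1) * p2 * p3 - p1 * (1 - p2) * p3
            den += (1 - p1) * pdn * pdn - p1 * (1 - pdn) * pdn
        expected = 0.0 if num <= 0 else num / den
        assert t["f_d"].iloc[0] == pytest.approx(expected)

    def test_zero_denominator_missing(self):
        rows = np.zeros((5, 4))
        m = quartet_matrix(rows, locus_length=100)
        t = f_d_windows(m, QUARTET, 100)
        assert np.isnan(t["f_d"].iloc[0])


class TestDxy:
    def test_identical_haploids_zero(self):
        rows = np.zeros((100, 4))
        m = quartet_matrix(rows, locus_length=100, includes_invariant=True)
        t = dxy_windows(m, "p1", "p2", window_bp=100, min_sites=10)
        assert t["dxy"].iloc[0] == 0.0

    def test_one_difference_in_hundred(self):
        rows = np.zeros((100, 4))
        rows[0, 1] = 1  # one derived allele in p2's haplotype
        m = quartet_matrix(rows, locus_length=100, includes_invariant=True)
        t = dxy_windows(m, "p1", "p2", window_bp=100, min_sites=10)
        assert t["dxy"].iloc[0] == pytest.approx(0.01)

    def test_diploid_matches_allele_pair_brute_force(self, rng):
        dosage = rng.integers(0, 3, size=(60, 4)).astype(float)
        dosage[rng.random(dosage.shape) < 0.1] = np.nan
        m = make_matrix(
            dosage,
            ["a1", "a2", "b1", "b2"],
            ["A", "A", "B", "B"],
            ploidy=2,
            locus_length=60,
            includes_invariant=True,
        )
        t = dxy_windows(m, "A", "B", window_bp=60, min_sites=1)
        diffs = comps = 0.0
        for row in dosage:
            a_alleles = []
            for d in row[:2]:
                if not np.isnan(d):
                    a_alleles += [1] * int(d) + [0] * (2 - int(d))
            b_alleles = []
            for d in row[2:]:
                if not np.isnan(d):
                    b_alleles += [1] * int(d) + [0] * (2 - int(d))
            if not a_alleles or not b_alleles:
                continue
            for x in a_alleles:
                for y in b_alleles:
                    diffs += x != y
                    comps += 1
        assert t["dxy"].iloc[0] == pytest.approx(diffs / comps)

    def test_symmetric_in_populations(self, rng):
        dosage = rng.integers(0, 3, size=(40, 4)).astype(float)
        m = make_matrix(
            dosage,
            ["a1", "a2", "b1", "b2"],
            ["A", "A", "B", "B"],
            locus_length=40,
            includes_invariant=True,
        )
        ab = dxy_windows(m, "A", "B", window_bp=40, min_sites=1)["dxy"]
        ba = dxy_windows(m, "B", "A", window_bp=40, min_sites=1)["dxy"]
        assert np.allclose(ab, ba)

    def test_requires_invariant_sites(self):
        m = quartet_matrix(np.ones((5, 4)))
        with pytest.raises(ValueError, match="invariant"):
            dxy_windows(m, "p1", "p2")

    def test_sparse_window_reported_missing(self):
        rows = np.zeros((10, 4))
        m = quartet_matrix(rows, locus_length=1000, includes_invariant=True)
        t = dxy_windows(m, "p1", "p2", window_bp=1000, min_sites=100)
        assert np.isnan(t["dxy"].iloc[0])


class TestCoalescenceScaling:
    def test_known_value(self):
        assert coalescence_time_from_dxy(9.64e-4, 4.82e-9, 10) == pytest.approx(1e6)

    def test_zero_divergence(self):
        assert coalescence_time_from_dxy(0.0, 4.82e-9, 10) == 0.0

    def test_round_trip(self):
        t = 123_456.0
        mu, g = 4.82e-9, 10.0
        dxy = 2 * mu * (t / g)
        assert coalescence_time_from_dxy(dxy, mu, g) == pytest.approx(t)

    def test_validation(self):
        with pytest.raises(ValueError):
            coalescence_time_from_dxy(-0.1, 1e-8, 10)
        with pytest.raises(ValueError):
            coalescence_time_from_dxy(0.1, 0.0, 10)


class TestVcfRoundTrip:
    def test_diploid_round_trip_with_missing(self, tmp_path, rng):
        dosage = rng.integers(0, 3, size=(30, 3)).astype(float)
        dosage[rng.random(dosage.shape) < 0.15] = np.nan
        dosage[5, :] = 0.0  # an invariant row
        m = make_matrix(
            dosage, ["s1", "s2", "s3"], ["A", "A", "B"], locus_length=50
        )
        path = tmp_path / "test.vcf"
        write_vcf(m, str(path))
        back = read_vcf(str(path), m.populations)
        assert back.samples == m.samples
        assert np.array_equal(back.pos, m.pos)
        assert np.array_equal(
            np.nan_to_num(back.dosage, nan=-1), np.nan_to_num(m.dosage, nan=-1)
        )
        assert back.includes_invariant

    def test_haploid_round_trip(self, tmp_path):
        dosage = np.array([[0, 1], [1, 0], [np.nan, 1]])
        m = make_matrix(
            dosage, ["s1", "s2"], ["A", "B"], ploidy=1, locus_length=10
        )
        path = tmp_path / "hap.vcf"
        write_vcf(m, str(path))
        back = read_vcf(str(path), m.populations, ploidy=1)
        assert np.array_equal(
            np.nan_to_num(back.dosage, nan=-1), np.nan_to_num(m.dosage, nan=-1)
        )

    def test_popmap_round_trip(self, tmp_path):
        p = tmp_path / "popmap.tsv"
        p.write_text("s1\tA\ns2\tB\n")
        assert read_popmap(str(p)) == {"s1": "A", "s2": "B"}


class TestDPermutationInvariance:
    def test_site_order_does_not_change_d(self, rng):
        rows = rng.integers(0, 2, size=(50, 4)).astype(float)
        m = quartet_matrix(rows, locus_length=50)
        d1 = d_statistic(abba_baba_counts(m, QUARTET))
        perm = rng.permutation(50)
        m2 = quartet_matrix(rows[perm], locus_length=50)
        d2 = d_statistic(abba_baba_counts(m2, QUARTET))
        assert d1 == pytest.approx(d2)
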