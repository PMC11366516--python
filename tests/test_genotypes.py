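from fractions import Fraction
from math import comb

import numpy as np
import pytest

from singlestep.genotypes import (
    MarkerData,
    QcConfig,
    apply_qc,
    gene_content_centered,
    hwe_exact_p,
    parentage_conflict_rate,
    read_matrix_tsv,
    read_plink_text,
)


def _write_plink(tmp_path, ped_lines, map_lines):
    (tmp_path / "g.ped").write_text("\n".join(ped_lines) + "\n")
    (tmp_path / "g.map").write_text("\n".join(map_lines) + "\n")
    return tmp_path / "g.ped", tmp_path / "g.map"


class TestPlinkText:
    def test_counted_allele_encoding(self, tmp_path):
        ped, mp = _write_plink(
            tmp_path,
            ["F s1 0 0 0 -9 A A", "F s2 0 0 0 -9 A G"],
            ["1 m1 0 1000"],
        )
        md = read_plink_text(ped, mp)
        assert md.calls[:, 0].tolist() == [2.0, 1.0]
        assert md.alleles[0] == ("A", "G")

    def test_missing_genotype(self, tmp_path):
        ped, mp = _write_plink(
            tmp_path,
            ["F s1 0 0 0 -9 0 0", "F s2 0 0 0 -9 G G"],
            ["1 m1 0 1000"],
        )
        md = read_plink_text(ped, mp)
        assert np.isnan(md.calls[0, 0]) and md.calls[1, 0] == 2.0

    def test_sex_chromosome_kept_at_read_time(self, tmp_path):
        ped, mp = _write_plink(
            tmp_path,
            ["F s1 0 0 0 -9 A A C C"],
            ["X mx 0 500", "1 m1 0 900"],
        )
        md = read_plink_text(ped, mp)
        assert md.n_markers == 2 and "X" in set(md.chrom)

    def test_ragged_line_rejected(self, tmp_path):
        ped, mp = _write_plink(
            tmp_path, ["F s1 0 0 0 -9 A A G"], ["1 m1 0 1", "1 m2 0 2"]
        )
        with pytest.raises(ValueError, match="expected"):
            read_plink_text(ped, mp)


class TestMatrixTsv:
    def _write(self, tmp_path, body):
        g = tmp_path / "g.tsv"
        m = tmp_path / "m.tsv"
        g.write_text(body)
        m.write_text("marker\tchrom\tpos\nm1\t1\t100\nm2\t1\t200\n")
        return g, m

    def test_clean_read_and_na(self, tmp_path):
        g, m = self._write(tmp_path, "\tm1\tm2\ns1\t0\t2\ns2\tNA\t1\n")
        md = read_matrix_tsv(g, m)
        assert md.calls[0].tolist() == [0.0, 2.0]
        assert np.isnan(md.calls[1, 0]) and md.calls[1, 1] == 1.0

    def test_bad_value_rejected(self, tmp_path):
        g, m = self._write(tmp_path, "\tm1\tm2\ns1\t0\t3\n")
        with pytest.raises(ValueError, match="invalid genotype"):
            read_matrix_tsv(g, m)


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Exact-rational two-sided HWE p: enumerate the conditional
    distribution of heterozygote counts with Fraction arithmetic."""
    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n_common = 2 * n - n_rare

    def prob(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        num = Fraction(2**h) * Fraction(
            comb(n, h) * comb(n - h, rare_hom)
        )
        den = Fraction(comb(2 * n, n_rare))
        # multinomial over genotypes / binomial over alleles
        return num * Fraction(
            comb(n - h - rare_hom, common_hom)
        ) / den

    hs = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {h: prob(h) for h in hs}
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(50, 0, 0) == 1.0

    def test_extreme_departure_below_threshold(self):
        assert hwe_exact_p(30, 0, 30) < 1e-6
        assert hwe_exact_p(30, 0, 30) == pytest.approx(
            hwe_enumeration_oracle(30, 0, 30), abs=1e-12
        )

    def test_mode_table_sums_to_one(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n = int(rng.integers(2, 200))
            h1 = int(rng.integers(0, n + 1))
            het = int(rng.integers(0, n - h1 + 1))
            h2 = n - h1 - het
            assert hwe_exact_p(h1, het, h2) == pytest.approx(
                hwe_enumeration_oracle(h1, het, h2), abs=1e-10
            )


def _toy_markerdata():
    """10 markers: 2 unknown position, 1 X-linked, 2 low call rate,
    1 rare (MAF below 0.01 via monomorphism); 4 clean survivors."""
    rng = np.random.default_rng(0)
    n = 40
    calls = rng.binomial(2, 0.4, size=(n, 10)).astype(float)
    calls[: n - 2, 3] = np.nan  # call rate 0.05
    calls[: n - 3, 4] = np.nan  # call rate 0.075
    calls[:, 5] = 0.0           # monomorphic -> MAF 0
    pos = np.array([100, 200, 300, 400, 500, 600, 700, -1, -1, 800], dtype=np.int64)
    chrom = np.array(["1", "1", "X", "2", "2", "2", "3", "3", "4", "4"], dtype=object)
    return MarkerData(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        marker_ids=tuple(f"m{i}" for i in range(10)),
        chrom=chrom, pos=pos, calls=calls,
    )


class TestApplyQc:
    def test_itemized_counts_and_survivors(self):
        md, report = apply_qc(_toy_markerdata())
        assert report.removed_unknown_position == 2
        assert report.removed_sex_chromosome == 1
        assert report.removed_call_rate == 2
        assert report.removed_maf == 1
        assert md.n_markers == 4
        assert report.n_markers_in - report.n_removed == report.n_markers_out

    def test_idempotent(self):
        md1, _ = apply_qc(_toy_markerdata())
        md2, rep2 = apply_qc(md1)
        assert rep2.n_removed == 0
        assert np.array_equal(md1.calls, md2.calls, equal_nan=True)

    def test_disabled_filters_are_identity(self):
        cfg = QcConfig(min_call_rate=0.0, min_maf=0.0, hwe_p_min=0.0,
                       drop_sex_chromosomes=False, drop_unknown_position=False)
        md0 = _toy_markerdata()
        md, report = apply_qc(md0, cfg)
        assert md.n_markers == md0.n_markers and report.n_removed == 0

    def test_low_maf_removed(self):
        rng = np.random.default_rng(1)
        calls = np.zeros((200, 1))
        calls[0, 0] = 1.0  # MAF 0.0025
        md = MarkerData(
            sample_ids=tuple(f"s{i}" for i in range(200)),
            marker_ids=("m",), chrom=np.array(["1"], dtype=object),
            pos=np.array([10], dtype=np.int64), calls=calls,
        )
        _, report = apply_qc(md)
        assert report.removed_maf == 1


class TestParentageConflicts:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0], dtype=float)
        assert parentage_conflict_rate(g, g) == 0.0

    def test_fully_opposing(self):
        assert parentage_conflict_rate(np.zeros(100), np.full(100, 2.0)) == 1.0

    def test_hand_counted_rate(self):
        parent = np.full(20, 1.0)
        child = np.full(20, 1.0)
        parent[:3], child[:3] = 0.0, 2.0       # 3 opposing
        parent[15:] = np.nan                   # 5 not jointly called
        assert parentage_conflict_rate(parent, child) == pytest.approx(3 / 15)
        assert 3 / 15 > QcConfig().parentage_conflict_max

    def test_no_joint_markers_rejected(self):
        with pytest.raises(ValueError):
            parentage_conflict_rate(np.array([np.nan]), np.array([1.0]))


class TestGeneContent:
    def test_hand_example(self):
        md = MarkerData(
            sample_ids=("a", "b", "c"), marker_ids=("m",),
            chrom=np.array(["1"], dtype=object), pos=np.array([5], dtype=np.int64),
            calls=np.array([[0.0], [1.0], [2.0]]),
        )
        Z, lam, p = gene_content_centered(md)
        assert np.allclose(Z[:, 0], [-1, 0, 1])
        assert lam == pytest.approx(2.0)
        assert p[0] == pytest.approx(0.5)

    def test_all_het_column_is_zero(self):
        md = MarkerData(
            sample_ids=("a", "b"), marker_ids=("m",),
            chrom=np.array(["1"], dtype=object), pos=np.array([5], dtype=np.int64),
            calls=np.ones((2, 1)),
        )
        Z, _, _ = gene_content_centered(md)
        assert np.allclose(Z, 0.0)

    def test_columns_centered(self, qtl_bundle):
        Z, _, _ = gene_content_centered(qtl_bundle.markers_genotyped)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12

    def test_monomorphic_rejected(self):
        md = MarkerData(
            sample_ids=("a", "b"), marker_ids=("m",),
            chrom=np.array(["1"], dtype=object), pos=np.array([5], dtype=np.int64),
            calls=np.zeros((2, 1)),
        )
        with pytest.raises(ValueError, match="monomorphic"):
            gene_content_centered(md)
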