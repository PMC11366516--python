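import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la

from singlestep.genotypes import MarkerData
from singlestep.kinship import SnpWeights
from singlestep.reml import TraitDataset
from singlestep.wssgwas import (
    SnpEffectSet,
    WssgwasConfig,
    annotate_windows,
    backsolve_snp_effects,
    genotype_class_means,
    normalize_weights,
    run_wssgwas,
    significant_windows,
    update_weights,
    window_scan,
)


class TestBacksolve:
    def test_zero_gebv_zero_effects(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        eff = backsolve_snp_effects(np.zeros(2), Z, np.ones(2), np.eye(2), 1.0)
        assert np.allclose(eff.u_hat, 0.0)

    def test_dense_hand_calculation(self):
        """2-sample, 2-marker system small enough to invert by hand."""
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        d = np.array([1.0, 2.0])
        lam = 0.5
        G = (Z * d) @ Z.T * lam          # diag(0.5, 1.0)
        Ginv = np.diag([2.0, 1.0])
        a_g = np.array([0.3, -0.4])
        eff = backsolve_snp_effects(a_g, Z, SnpWeights(d=d), Ginv, lam)
        # u = lam * d * Z' Ginv a = (0.5*1*2*0.3, 0.5*2*1*(-0.4))
        assert np.allclose(eff.u_hat, [0.3, -0.4])
        assert np.allclose(Z @ eff.u_hat, a_g)
        assert np.allclose(G @ Ginv, np.eye(2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            backsolve_snp_effects(np.zeros(3), np.zeros((2, 2)), np.ones(2),
                                  np.eye(2), 1.0)


class TestWeights:
    def test_update_hand_values(self):
        d = update_weights(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        assert np.allclose(d, [0.5, 0.5])

    def test_zero_effect_zero_weight(self):
        assert update_weights(np.array([0.0]), np.array([0.3]))[0] == 0.0

    def test_quadratic_in_effects(self):
        u = np.array([0.2, -1.1, 0.7])
        p = np.array([0.1, 0.3, 0.5])
        assert np.allclose(update_weights(3 * u, p), 9 * update_weights(u, p))

    def test_normalize_hand_values(self):
        w = normalize_weights(np.array([0.5, 0.5]), trace_target=2)
        assert np.allclose(w.d, [1.0, 1.0])
        w = normalize_weights(np.array([3.0, 1.0]), trace_target=2)
        assert np.allclose(w.d, [1.5, 0.5])

    def test_normalize_identity_when_trace_matches(self):
        d = np.array([0.5, 1.5])
        assert np.allclose(normalize_weights(d, trace_target=2).d, d)

    def test_all_zero_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero"):
            w = normalize_weights(np.zeros(4), trace_target=4)
        assert np.allclose(w.d, 1.0)


class TestRunWssgwas:
    def test_reconstruction_and_trace_every_iteration(self, qtl_bundle, litter_vc):
        b = qtl_bundle
        res = run_wssgwas(b.data, b.markers_genotyped, b.ped, litter_vc,
                          WssgwasConfig(n_iterations=3))
        M = b.markers_genotyped.n_markers
        for it in res.iterations:
            a_g = it.effects.gebv_g
            centered = a_g - a_g.mean()
            rel = la.norm(res.Z @ it.effects.u_hat - centered) / la.norm(centered)
            assert rel < 1e-6
            assert it.weights.d.sum() == pytest.approx(M, abs=1e-6)

    def test_qtl_rank_improves_with_weighting(self, qtl_bundle, litter_vc):
        b = qtl_bundle
        res = run_wssgwas(b.data, b.markers_genotyped, b.ped, litter_vc,
                          WssgwasConfig(n_iterations=3))
        qtl_marker = b.truth.qtl.iloc[0]["marker"]
        j = res.md.marker_ids.index(qtl_marker)

        def rank(it):
            order = np.argsort(-np.abs(it.effects.u_hat))
            return int(np.where(order == j)[0][0])

        assert rank(res.iterations[-1]) <= rank(res.iterations[0])


def _scan_fixture():
    """4 individuals, 3 SNPs on one chromosome, hand-checkable."""
    Z = np.array([
        [-1.0, 0.0, 1.0],
        [0.0, 1.0, -1.0],
        [1.0, -1.0, 0.0],
        [0.0, 0.0, 0.0],
    ])
    chrom = np.array(["1", "1", "1"], dtype=object)
    pos = np.array([100_000, 300_000, 900_000], dtype=np.int64)
    return Z, chrom, pos


class TestWindowScan:
    def test_zero_effects_zero_scan(self):
        Z, chrom, pos = _scan_fixture()
        wv = window_scan(np.zeros(3), Z, chrom, pos, sigma_a2=1.0)
        assert (wv.windows["pct_var"] == 0).all()

    def test_whole_genome_single_window_identity(self):
        Z, chrom, pos = _scan_fixture()
        u = np.array([0.5, -0.2, 0.1])
        wv = window_scan(u, Z, chrom, pos, sigma_a2=1.0, window_bp=10_000_000)
        direct = np.var(Z @ u) * 100
        first = wv.windows.iloc[0]
        assert first["n_snp"] == 3
        assert first["pct_var"] == pytest.approx(direct)

    def test_hand_computed_window(self):
        Z, chrom, pos = _scan_fixture()
        u = np.array([1.0, 2.0, 0.0])
        # 520 kb window anchored at SNP1 covers SNPs 1-2 only
        wv = window_scan(u, Z, chrom, pos, sigma_a2=2.0, window_bp=520_000)
        a_w = Z[:, :2] @ u[:2]
        assert wv.windows.iloc[0]["pct_var"] == pytest.approx(
            np.var(a_w) / 2.0 * 100)
        assert wv.windows.iloc[0]["n_snp"] == 2

    def test_allele_flip_invariance(self):
        Z, chrom, pos = _scan_fixture()
        u = np.array([0.7, -0.3, 0.2])
        wv1 = window_scan(u, Z, chrom, pos, sigma_a2=1.0)
        Zf = Z.copy()
        Zf[:, 1] *= -1
        uf = u.copy()
        uf[1] *= -1
        wv2 = window_scan(uf, Zf, chrom, pos, sigma_a2=1.0)
        assert np.allclose(wv1.windows["pct_var"], wv2.windows["pct_var"])

    def test_unsorted_map_rejected(self):
        Z, chrom, _ = _scan_fixture()
        bad = np.array([500, 100, 900], dtype=np.int64)
        with pytest.raises(ValueError, match="sorted"):
            window_scan(np.zeros(3), Z, chrom, bad, sigma_a2=1.0)


class TestSignificantWindows:
    def _wv(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "anchor",
                                         "n_snp", "pct_var", "first_idx", "last_idx"])
        from singlestep.wssgwas import WindowVariance
        return WindowVariance(windows=df, sigma_a2=1.0, window_bp=520_000)

    def test_nothing_significant(self):
        wv = self._wv([("1", 100, 600, 0, 2, 0.5, 0, 1)])
        assert len(significant_windows(wv)) == 0

    def test_overlapping_windows_merge(self):
        wv = self._wv([
            ("1", 100, 600, 0, 2, 2.0, 0, 1),
            ("1", 400, 900, 1, 2, 1.8, 1, 2),
        ])
        out = significant_windows(wv)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (100, 900)
        assert row["max_pct"] == pytest.approx(2.0)
        assert row["n_snp"] == 3

    def test_disjoint_regions_counted(self):
        wv = self._wv([
            ("1", 100, 600, 0, 2, 2.0, 0, 1),
            ("1", 5_000, 5_400, 1, 1, 1.0, 2, 2),
            ("2", 900, 1_300, 0, 2, 1.6, 3, 4),
        ])
        out = significant_windows(wv, threshold_pct=1.56)
        assert len(out) == 2


class TestGenotypeClassMeans:
    def _fixture(self):
        md = MarkerData(
            sample_ids=tuple("abcdef"),
            marker_ids=("m1",),
            chrom=np.array(["1"], dtype=object),
            pos=np.array([100], dtype=np.int64),
            calls=np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0]]),
        )
        data = TraitDataset(records=pd.DataFrame({
            "animal_id": list("abcdef"),
            "parity": 1, "year_season": "y",
            "value": [8.0, 9.0, 10.0, 11.0, 12.0, 14.0],
        }))
        return md, data

    def test_hand_computed_means(self):
        md, data = self._fixture()
        df = genotype_class_means(data, md, "m1")
        means = dict(zip(df["genotype"], df["mean"]))
        assert means == {0: 8.5, 1: 10.5, 2: 13.0}
        assert df.attrs["hom_difference"] == pytest.approx(4.5)

    def test_single_class_is_overall_mean(self):
        md, data = self._fixture()
        md1 = MarkerData(
            sample_ids=md.sample_ids, marker_ids=md.marker_ids,
            chrom=md.chrom, pos=md.pos, calls=np.ones((6, 1)),
        )
        df = genotype_class_means(data, md1, "m1")
        assert len(df) == 1
        assert df["mean"].iloc[0] == pytest.approx(
            data.records["value"].mean())

    def test_empty_class_omitted_not_zero(self):
        md, data = self._fixture()
        calls = md.calls.copy()
        calls[calls == 1.0] = 0.0  # no heterozygotes left
        md2 = MarkerData(sample_ids=md.sample_ids, marker_ids=md.marker_ids,
                         chrom=md.chrom, pos=md.pos, calls=calls)
        df = genotype_class_means(data, md2, "m1")
        assert set(df["genotype"]) == {0, 2}

    def test_missing_marker(self):
        md, data = self._fixture()
        with pytest.raises(KeyError):
            genotype_class_means(data, md, "nope")


class TestAnnotateWindows:
    def _regions(self):
        return pd.DataFrame({
            "chrom": ["1", "18"],
            "start_bp": [1_000, 11_250_000],
            "end_bp": [5_000, 11_720_000],
            "max_pct": [2.0, 1.57],
            "n_snp": [4, 10],
        })

    def test_gff3_overlap(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t500\t1500\t.\t+\t.\tID=g1;Name=GENE1\n"
            "1\tsrc\tgene\t4000\t4500\t.\t-\t.\tID=g2;Name=GENE2\n"
            "1\tsrc\tgene\t9000\t9500\t.\t+\t.\tID=g3;Name=GENE3\n"
        )
        out = annotate_windows(self._regions(), gff)
        assert out.iloc[0]["genes"] == "GENE1, GENE2"
        assert out.iloc[1]["genes"] == "-"

    def test_bed_and_abutting_exclusion(self, tmp_path):
        bed = tmp_path / "genes.bed"
        # 0-based half-open: second gene starts exactly at region end (5000)
        bed.write_text("1\t2000\t3000\tinG\n1\t4999\t6000\tabutting\n")
        out = annotate_windows(self._regions(), bed)
        assert out.iloc[0]["genes"] == "inG"

    def test_chromosome_mismatch_reported(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tg\n")
        out = annotate_windows(self._regions(), bed)
        assert set(out.attrs["unmatched_chroms"]) == {"1", "18"}
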