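"""Weighted correlation/clustering, signature recovery, bins, turnover fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from aneuprot import signatures as sg, synthetic_data as sd
from aneuprot.io_tables import QuantMatrix


def matrix_of(array, genes=None, strains=None, layer="protein"):
    n, m = np.asarray(array).shape
    genes = genes or [f"g{i}" for i in range(n)]
    strains = strains or [f"disome{j+1:02d}" for j in range(m)]
    return QuantMatrix(
        pd.DataFrame(np.asarray(array, float), index=pd.Index(genes, name="gene"),
                     columns=strains),
        layer,
    )


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = sg.weighted_pearson(x, y, np.ones(50))
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_affine_relation_gives_one(self):
        x = np.linspace(0, 1, 20)
        w = np.random.default_rng(1).uniform(0.1, 1, 20)
        assert sg.weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)

    def test_zero_weight_equals_removal(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        x[5], y[5] = 50.0, -50.0  # planted outlier pair
        w = np.ones(30)
        w[5] = 0.0
        keep = np.arange(30) != 5
        expected = stats.pearsonr(x[keep], y[keep])[0]
        assert sg.weighted_pearson(x, y, w) == pytest.approx(expected, abs=1e-12)

    def test_needs_three_effective_points(self):
        with pytest.raises(ValueError):
            sg.weighted_pearson([1, 2, 3], [1, 2, 3], [1, 1, 0])


class TestWeightedHcluster:
    def make_blocks(self, seed=3, n_per=20, m=10, rho=0.9):
        rng = np.random.default_rng(seed)
        shared_a = rng.normal(size=m)
        shared_b = rng.normal(size=m)
        rows = []
        for _ in range(n_per):
            rows.append(np.sqrt(rho) * shared_a + np.sqrt(1 - rho) * rng.normal(size=m))
        for _ in range(n_per):
            rows.append(np.sqrt(rho) * shared_b + np.sqrt(1 - rho) * rng.normal(size=m))
        return matrix_of(np.array(rows))

    def test_planted_blocks_recovered_at_k2(self):
        m = self.make_blocks()
        Z, genes = sg.weighted_hcluster(m)
        labels = hierarchy.fcluster(Z, 2, criterion="maxclust")
        first = labels[:20]
        second = labels[20:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_duplicate_rows_merge_first_at_distance_zero(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=8)
        rows = [base, base, rng.normal(size=8), rng.normal(size=8)]
        Z, _ = sg.weighted_hcluster(matrix_of(np.array(rows)))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_row_permutation_invariance(self):
        m = self.make_blocks(seed=5)
        perm = np.random.default_rng(6).permutation(m.data.shape[0])
        shuffled = QuantMatrix(m.data.iloc[perm], "protein")
        Z1, genes1 = sg.weighted_hcluster(m)
        Z2, genes2 = sg.weighted_hcluster(shuffled)
        lab1 = dict(zip(genes1, hierarchy.fcluster(Z1, 2, criterion="maxclust")))
        lab2 = dict(zip(genes2, hierarchy.fcluster(Z2, 2, criterion="maxclust")))
        # same bipartition up to label swap
        pairs = {(lab1[g], lab2[g]) for g in genes1}
        assert len(pairs) == 2

    def test_downweighting_removes_own_chromosome_cluster(self, small_genome):
        """Unweighted clustering of disomes groups duplicated genes by their
        shared twofold jump; zero-weighting those cells removes the effect."""
        strains = []
        chroms = ["chr01", "chr02", "chr03", "chr04"]
        cols = {}
        rng = np.random.default_rng(7)
        for chrom in chroms:
            truth = sd.DisomeTruth(chrom, set(), noise_sd=0.2)
            col = sd.generate_disome_matrix(small_genome, truth, "protein",
                                            seed=int(chrom[3:]))
            cols[col.strains[0]] = col.data.iloc[:, 0]
        m = QuantMatrix(pd.DataFrame(cols), "protein")
        genes = small_genome.genes_on("chr01")[:15] + small_genome.genes_on("chr02")[:15]
        sub = QuantMatrix(m.data.loc[genes], "protein")
        Zu, _ = sg.weighted_hcluster(sub)
        labels = hierarchy.fcluster(Zu, 2, criterion="maxclust")
        agree = (labels[:15] == labels[0]).all() and (labels[15:] == labels[15]).all()
        assert agree and labels[0] != labels[15]  # trivial own-chromosome clusters
        w = sg.WeightTable.downweight_duplicated(sub, small_genome.annotation)
        Zw, _ = sg.weighted_hcluster(sub, w)
        labels_w = hierarchy.fcluster(Zw, 2, criterion="maxclust")
        assert not ((labels_w[:15] == labels_w[0]).all()
                    and (labels_w[15:] == labels_w[15]).all())


class TestSignatureExtraction:
    def test_planted_aps_recovered(self, study):
        """92 planted signature genes: recall >= 0.9, precision >= 0.8."""
        weights = sg.WeightTable.downweight_duplicated(
            study.protein, study.annotation, study.duplicated_map()
        )
        sig = sg.extract_consistent_up_signature(study.protein, weights)
        aps = study.aps_genes()
        hit = set(sig.genes) & aps
        assert len(hit) / len(aps) >= 0.9
        assert len(hit) / len(sig.genes) >= 0.8

    def test_null_expected_false_genes_below_closed_form(self, genome):
        """Without a planted signature the threshold method keeps ~no genes:
        closed form n * P(N(0,sigma) > t)^12 with the mean-floor cut."""
        null = sd.null_study(genome=genome, seed=21)
        weights = sg.WeightTable.downweight_duplicated(
            null.protein, null.annotation, null.duplicated_map()
        )
        with pytest.warns(UserWarning):
            sig = sg.extract_consistent_up_signature(
                null.protein, weights, min_log2=0.2
            )
        # at min_log2=0.2, sigma=0.2: (1-Phi(1))^12 * 4800 << 1
        assert len(sig.genes) == 0

    def test_single_strain_positive_values(self):
        m = matrix_of([[0.5], [-0.1], [0.3]], strains=["disome01"])
        sig = sg.extract_consistent_up_signature(
            m, min_strains=1, min_log2=0.0, mean_floor=-np.inf
        )
        assert sig.genes == ["g0", "g2"]

    def test_cluster_method_finds_planted_block(self):
        """Planted signature genes share a strain profile (shift grows with
        the strain, as a chromosome-size-coupled signature does), which is
        what makes them a coherent cluster under a correlation metric.

        Within-block correlation: var(shift)/(var(shift)+noise^2)
        = 0.076/(0.076+0.0225) ~ 0.77 over 12 strains.
        """
        rng = np.random.default_rng(8)
        background = rng.normal(0, 0.15, (200, 12))
        strain_shift = np.linspace(0.3, 1.2, 12)
        planted = strain_shift + rng.normal(0, 0.15, (20, 12))
        m = matrix_of(np.vstack([planted, background]))
        sig = sg.extract_consistent_up_signature(m, method="cluster",
                                                 min_cluster_size=10)
        planted_names = {f"g{i}" for i in range(20)}
        hit = set(sig.genes) & planted_names
        assert len(hit) / 20 >= 0.8
        assert len(hit) / max(len(sig.genes), 1) >= 0.8


class TestProjection:
    def test_single_gene_projection_is_its_row(self, tiny_matrix):
        sig = sg.signature_projection(tiny_matrix, ["g1"])
        assert sig.intensity["disome01"] == 1.0
        assert sig.intensity["disome02"] == 0.1

    def test_linearity(self):
        rng = np.random.default_rng(9)
        a = matrix_of(rng.normal(size=(30, 5)))
        b = matrix_of(rng.normal(size=(30, 5)))
        both = QuantMatrix(a.data + b.data, "protein")
        genes = [f"g{i}" for i in range(10)]
        pa = sg.signature_projection(a, genes).intensity
        pb = sg.signature_projection(b, genes).intensity
        pab = sg.signature_projection(both, genes).intensity
        assert np.allclose(pab, pa + pb, atol=1e-12)

    def test_esr_projection_scales_with_esr_scale(self, genome):
        """Planted stress-response shift scales linearly across studies."""
        lo = sd.generate_study(genome=genome, esr_scale=0.3, seed=3)
        hi = sd.generate_study(genome=genome, esr_scale=0.9, seed=3)
        dup_all = {g for t in lo.truths.values()
                   for g in genome.genes_on(t.duplicated_chromosome)}
        down = sorted(genome.esr_down - dup_all)  # avoid dosage offsets
        p_lo = sg.signature_projection(lo.protein, down).intensity.mean()
        p_hi = sg.signature_projection(hi.protein, down).intensity.mean()
        assert p_hi / p_lo == pytest.approx(3.0, abs=0.5)
        assert p_lo < 0

    def test_all_zero_matrix_projects_zero(self):
        m = matrix_of(np.zeros((10, 4)))
        assert (sg.signature_projection(m, ["g0", "g3"]).intensity == 0).all()


class TestIntensitySizeCorrelation:
    def test_exact_proportionality_r_one(self):
        intensity = pd.Series([0.2, 0.4, 0.8], index=["disome01", "disome02", "disome03"])
        sig = sg.SignatureSet("s", ["g"], intensity, intensity * 0)
        sizes = {"disome01": 100, "disome02": 200, "disome03": 400}
        out = sg.intensity_size_correlation(sig, sizes)
        assert out["r"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_permuted_sizes_destroy_correlation(self, study):
        weights = sg.WeightTable.downweight_duplicated(
            study.protein, study.annotation, study.duplicated_map()
        )
        sig = sg.extract_consistent_up_signature(study.protein, weights)
        sizes = study.annotation.chromosome_sizes()
        strain_sizes = {s: sizes[c] for s, c in study.duplicated_map().items()}
        r_true = sg.intensity_size_correlation(sig, strain_sizes)["r"]
        rng = np.random.default_rng(10)
        permuted = dict(zip(strain_sizes,
                            rng.permutation(list(strain_sizes.values()))))
        r_perm = sg.intensity_size_correlation(sig, permuted)["r"]
        assert r_true >= 0.9
        assert abs(r_perm) < r_true


class TestBinAndCompare:
    def test_identical_matrices(self):
        rng = np.random.default_rng(11)
        m = matrix_of(rng.normal(0, 0.6, (300, 2)))
        out = sg.bin_and_compare(m, m)
        measured = out.dropna(subset=["paired_t_p"])
        assert (measured["paired_t_p"] == 1.0).all()
        assert np.allclose(measured["mean_a"], measured["mean_b"])

    def test_uniform_attenuation_shrinks_both_tails(self):
        rng = np.random.default_rng(12)
        a = matrix_of(rng.normal(0, 0.8, (1000, 1)), strains=["disome01"])
        b = QuantMatrix(a.data * 0.7, "protein")
        out = sg.bin_and_compare(a, b).set_index("bin")
        up, down = out.loc["up"], out.loc["down"]
        assert up["mean_b"] < up["mean_a"]
        assert down["mean_b"] > down["mean_a"]
        assert up["paired_t_p"] < 1e-3 and down["paired_t_p"] < 1e-3
        assert up["n"] >= 100 and down["n"] >= 100

    def test_empty_bin_reported_without_test(self):
        a = matrix_of(np.full((10, 1), 1.0), strains=["disome01"])
        b = matrix_of(np.full((10, 1), 0.5), strains=["disome01"])
        out = sg.bin_and_compare(a, b).set_index("bin")
        assert out.loc["down", "n"] == 0
        assert np.isnan(out.loc["down", "paired_t_p"])
        assert out.loc["up", "n"] == 10


class TestTurnoverSlopes:
    def test_closed_form_three_points(self):
        m = matrix_of(np.array([[0.0, 0.072, 0.24]]), strains=["t0", "t90", "t300"])
        slope = sg.fit_turnover_slope(m, (0, 90, 300)).iloc[0]
        t = np.array([0, 90, 300.0])
        y = np.array([0, 0.072, 0.24])
        expected = np.polyfit(t, y, 1)[0]
        assert slope == pytest.approx(expected, abs=1e-12)
        # by hand: sum((t-130)(y-0.104)) / sum((t-130)^2) = 37.92/47400
        assert slope == pytest.approx(8.0e-4, abs=1e-7)

    def test_flat_timecourse_zero_slope(self):
        m = matrix_of(np.ones((5, 3)), strains=["t0", "t90", "t300"])
        assert (sg.fit_turnover_slope(m, (0, 90, 300)) == 0).all()

    def test_planted_slopes_recovered_within_3se(self, small_genome):
        chrom = "chr05"
        att = set(small_genome.genes_on(chrom)[:20])
        truth = sd.DisomeTruth(chrom, att, noise_sd=0.0)
        slopes_t = sd.default_turnover_slopes(small_genome, truth)
        tc = sd.generate_turnover_truth(small_genome, truth, slopes_t,
                                        seed=13, noise_sd=0.1)
        fit = sg.fit_turnover_slope(tc)
        se = 0.1 / np.sqrt(np.sum((np.array([0, 90, 300]) - 130.0) ** 2))
        planted = np.array([slopes_t[g] for g in fit.index])
        within = np.abs(fit.to_numpy() - planted) <= 3 * se
        assert within.mean() >= 0.99

    def test_group_contrast_attenuated_positive(self, small_genome):
        chrom = "chr05"
        att = set(small_genome.genes_on(chrom)[:30])
        truth = sd.DisomeTruth(chrom, att, noise_sd=0.0)
        slopes_t = sd.default_turnover_slopes(small_genome, truth)
        tc = sd.generate_turnover_truth(small_genome, truth, slopes_t,
                                        seed=14, noise_sd=0.1)
        fit = sg.fit_turnover_slope(tc)
        out = sg.turnover_group_contrast(fit, att, set(small_genome.genes_on(chrom)))
        assert out["welch_p"] < 1e-3
        assert out["mean_attenuated"] > out["mean_not_attenuated"]

    def test_per_chromosome_means(self, small_genome):
        chrom = "chr05"
        att = set(small_genome.genes_on(chrom))
        truth = sd.DisomeTruth(chrom, att, noise_sd=0.0)
        slopes_t = sd.default_turnover_slopes(small_genome, truth, slope=4.8e-4)
        tc = sd.generate_turnover_truth(small_genome, truth, slopes_t,
                                        seed=15, noise_sd=0.0)
        per_chrom = sg.turnover_chromosome_means(
            sg.fit_turnover_slope(tc), small_genome.annotation
        )
        assert per_chrom[chrom] == pytest.approx(4.8e-4, abs=1e-10)
        assert per_chrom.drop(chrom).abs().max() < 1e-10
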