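import json

import numpy as np
import pytest
from scipy import stats

from patternreg.synthetic import (
    DEFAULT_SCALE_SPECS,
    CohortConfig,
    GroupParams,
    ScaleSpec,
    _calibrate_truncnorm,
    _component_targets,
    cohort_to_table,
    draw_scores,
    generate_atlas,
    generate_cohort,
    write_cohort,
)

SPEC_BY_NAME = {s.name: s for s in DEFAULT_SCALE_SPECS}


class TestDrawScores:
    def test_distressed_stai_t_moments(self, rng):
        x = draw_scores(SPEC_BY_NAME["STAI-T"], "distressed", 10000, rng)
        assert abs(x.mean() - 54.9) < 0.5
        assert abs(x.std() - 11.0) < 0.5

    def test_degenerate_variance(self, rng):
        spec = ScaleSpec("STAI-T", GroupParams(50, 1e-6, 0, 100), GroupParams(50, 1e-6, 0, 100))
        x = draw_scores(spec, "distressed", 5, rng)
        assert np.allclose(x, 50.0, atol=1e-4)

    def test_healthy_hama_zero_fraction(self, rng):
        x = draw_scores(SPEC_BY_NAME["HAM-A"], "healthy", 7200, rng)
        assert abs(np.mean(x == 0) - 47 / 72) < 0.02

    def test_unknown_scale_name(self):
        with pytest.raises(ValueError, match="unknown scale"):
            ScaleSpec("BOGUS", GroupParams(1, 1, 0, 2), GroupParams(1, 1, 0, 2))

    def test_inverted_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            GroupParams(mean=5, sd=1, minimum=10, maximum=0)

    def test_n_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            draw_scores(SPEC_BY_NAME["STAI-T"], "distressed", 0, rng)

    def test_values_respect_bounds(self, rng):
        for spec in DEFAULT_SCALE_SPECS:
            for group in ("distressed", "healthy"):
                x = draw_scores(spec, group, 2000, rng)
                params = spec.group_params(group)
                assert x.min() >= params.minimum - 1e-9
                assert x.max() <= params.maximum + 1e-9


class TestCalibration:
    def test_calibration_matches_analytic_moments(self):
        mu, sigma = _calibrate_truncnorm(54.9, 11.0, 25.0, 75.0)
        a, b = (25 - mu) / sigma, (75 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert abs(m - 54.9) < 1e-6
        assert abs(np.sqrt(v) - 11.0) < 1e-4

    def test_mean_always_exact_even_when_sd_capped(self):
        # healthy MASQ-D asks for more spread than a truncated normal on
        # [12, 24] can deliver; the mean must still be matched exactly
        mu, sigma = _calibrate_truncnorm(15.3, 3.5, 12.0, 24.0)
        a, b = (12 - mu) / sigma, (24 - mu) / sigma
        m = stats.truncnorm.mean(a, b, loc=mu, scale=sigma)
        assert abs(m - 15.3) < 1e-5


class TestGenerateCohort:
    def test_determinism(self):
        config = CohortConfig(
            n_distressed=6, n_healthy=6, grid_shape=(4, 4, 4), n_signal_voxels=5,
            scanner_split={"distressed": (4, 2), "healthy": (4, 2)}, seed=11,
            dropout_fraction=0.25,
        )
        recs1, truth1 = generate_cohort(config)
        recs2, truth2 = generate_cohort(config)
        for r1, r2 in zip(recs1, recs2):
            np.testing.assert_array_equal(r1.volume, r2.volume)
            assert r1.scores == r2.scores
            assert (r1.gender, r1.scanner, r1.age) == (r2.gender, r2.scanner, r2.age)
        np.testing.assert_array_equal(
            truth1.true_weight_volume, truth2.true_weight_volume
        )

    def test_study_size(self):
        config = CohortConfig(grid_shape=(2, 2, 2), n_signal_voxels=1, seed=0)
        records, _ = generate_cohort(config)
        assert len(records) == 154
        assert sum(r.group == "distressed" for r in records) == 82
        assert sum(r.group == "healthy" for r in records) == 72

    def test_null_cohort_voxel_correlations(self):
        """With snr=0 no voxel correlates with the score beyond chance.

        Oracle: Monte-Carlo null distribution of the max |r| over the same
        number of independent noise voxels.
        """
        config = CohortConfig(
            n_distressed=40, n_healthy=40, grid_shape=(10, 10, 5),
            signal_snr=0.0, n_signal_voxels=1, scanner_offset_sd=0.0,
            scanner_split={"distressed": (30, 10), "healthy": (30, 10)}, seed=5,
        )
        records, _ = generate_cohort(config)
        n = len(records)
        scores = np.array([r.scores["STAI-T"] for r in records])
        X = np.vstack([r.volume.ravel(order="F") for r in records])[:, :500]
        zs = (scores - scores.mean()) / scores.std()
        zx = (X - X.mean(0)) / X.std(0)
        observed_max = np.max(np.abs(zs @ zx / n))
        # brute-force null oracle
        oracle_rng = np.random.default_rng(123)
        null_max = np.empty(300)
        for i in range(300):
            noise = oracle_rng.standard_normal((n, 500))
            zn = (noise - noise.mean(0)) / noise.std(0)
            null_max[i] = np.max(np.abs(zs @ zn / n))
        assert observed_max < np.quantile(null_max, 0.997)

    def test_signal_planting_ols_oracle(self):
        config = CohortConfig(grid_shape=(8, 8, 8), signal_snr=0.3,
                              n_signal_voxels=40, seed=2)
        records, truth = generate_cohort(config)
        scores = np.array([r.scores["STAI-T"] for r in records])
        flat = np.vstack([r.volume.ravel(order="F") for r in records])
        mean_signal = flat[:, truth.signal_voxel_indices].mean(axis=1)
        res = stats.linregress(mean_signal, scores)
        assert res.slope > 0
        assert res.pvalue < 0.01

    def test_truth_nonzero_exactly_at_signal_voxels(self, small_cohort):
        _, _, truth = small_cohort
        flat = truth.true_weight_volume.ravel(order="F")
        np.testing.assert_array_equal(
            np.sort(np.flatnonzero(flat)), truth.signal_voxel_indices
        )

    def test_nan_placement(self):
        config = CohortConfig(
            n_distressed=10, n_healthy=10, grid_shape=(8, 8, 8),
            n_signal_voxels=4, dropout_fraction=0.3, dropout_extent=0.07,
            scanner_split={"distressed": (6, 4), "healthy": (6, 4)}, seed=1,
        )
        records, _ = generate_cohort(config)
        n_vox = 8**3
        nan_counts = [int(np.isnan(r.volume).sum()) for r in records]
        affected = [c for c in nan_counts if c > 0]
        assert len(affected) == round(0.3 * 20)
        target = round(0.07 * n_vox)
        assert all(abs(c - target) <= 1 for c in affected)

    def test_scanner_split_honoured(self, small_cohort):
        _, records, _ = small_cohort
        for group, (n_a, n_b) in (("distressed", (6, 4)), ("healthy", (6, 4))):
            in_group = [r for r in records if r.group == group]
            assert sum(r.scanner == "A" for r in in_group) == n_a
            assert sum(r.scanner == "B" for r in in_group) == n_b

    def test_impossible_scanner_split(self):
        with pytest.raises(ValueError, match="scanner_split"):
            CohortConfig(n_distressed=10, n_healthy=10,
                         scanner_split={"distressed": (5, 4), "healthy": (6, 4)})

    def test_moment_recovery(self):
        """Empirical per-scale moments within 3 SE of the calibrated
        analytic moments at n=5000 per group."""
        config = CohortConfig(
            n_distressed=5000, n_healthy=5000, grid_shape=(2, 2, 2),
            n_signal_voxels=1, signal_snr=0.0,
            scanner_split={"distressed": (4000, 1000), "healthy": (4000, 1000)},
            gender_shift_sd=0.0, seed=9,
        )
        records, _ = generate_cohort(config)
        table = cohort_to_table(records)
        for spec in DEFAULT_SCALE_SPECS:
            col = {"STAI-T": "stai_t", "STAI-S": "stai_s", "MASQ-D": "masq_d",
                   "HAM-A": "ham_a", "HDRS": "hdrs"}[spec.name]
            for group, n in (("distressed", 5000), ("healthy", 5000)):
                vals = table.loc[table["group"] == group, col].to_numpy()
                params = spec.group_params(group)
                cm, cs, p0 = _component_targets(spec, group)
                mu, sigma = _calibrate_truncnorm(
                    cm, cs, params.minimum, params.maximum
                )
                a, b = (params.minimum - mu) / sigma, (params.maximum - mu) / sigma
                m_c, v_c = stats.truncnorm.stats(a, b, loc=mu, scale=sigma,
                                                 moments="mv")
                # analytic mixture moments of the calibrated model
                mean_target = (1 - p0) * float(m_c)
                var_target = (1 - p0) * (float(v_c) + float(m_c) ** 2) - mean_target**2
                sd_target = np.sqrt(var_target)
                assert abs(vals.mean() - mean_target) < 3 * sd_target / np.sqrt(n)
                assert abs(vals.std() - sd_target) < 3 * sd_target / np.sqrt(2 * n)
                # model mean equals the published mean by calibration
                assert abs(mean_target - params.mean) < 1e-4

    def test_gender_shift_preserves_group_mean(self):
        base = dict(n_distressed=4000, n_healthy=4000, grid_shape=(2, 2, 2),
                    n_signal_voxels=1, signal_snr=0.0,
                    scanner_split={"distressed": (3000, 1000),
                                   "healthy": (3000, 1000)}, seed=4)
        with_shift = cohort_to_table(
            generate_cohort(CohortConfig(**base, gender_shift_sd=0.25))[0]
        )
        dist = with_shift[with_shift["group"] == "distressed"]
        f = dist[dist["gender"] == "F"]["stai_t"].mean()
        m = dist[dist["gender"] == "M"]["stai_t"].mean()
        assert f > m  # females shifted up
        assert abs(dist["stai_t"].mean() - 54.9) < 0.6  # mean preserved


class TestWriteCohort:
    def test_file_counts_and_roundtrip(self, tmp_path):
        import nibabel as nib

        config = CohortConfig(
            n_distressed=2, n_healthy=1, grid_shape=(4, 4, 4), n_signal_voxels=3,
            scanner_split={"distressed": (1, 1), "healthy": (1, 0)}, seed=0,
        )
        records, truth = generate_cohort(config)
        manifest = write_cohort(records, truth, tmp_path)
        niftis = sorted(tmp_path.glob("sub-*.nii.gz"))
        assert len(niftis) == 3
        assert (tmp_path / "cohort.csv").exists()
        assert (tmp_path / "truth.nii.gz").exists()
        assert (tmp_path / "manifest.json").exists()
        back = np.asarray(nib.load(niftis[0]).get_fdata())
        assert np.nanmax(np.abs(back - records[0].volume)) <= 1e-6
        assert manifest["n_subjects"] == 3

    def test_csv_row_count(self, tmp_path):
        config = CohortConfig(
            n_distressed=3, n_healthy=2, grid_shape=(3, 3, 3), n_signal_voxels=2,
            scanner_split={"distressed": (2, 1), "healthy": (1, 1)}, seed=0,
        )
        records, truth = generate_cohort(config)
        write_cohort(records, truth, tmp_path)
        lines = (tmp_path / "cohort.csv").read_text().strip().splitlines()
        assert len(lines) == 5 + 1

    def test_manifest_determinism(self, tmp_path):
        config = CohortConfig(
            n_distressed=2, n_healthy=2, grid_shape=(3, 3, 3), n_signal_voxels=2,
            scanner_split={"distressed": (1, 1), "healthy": (1, 1)}, seed=5,
        )
        m1 = write_cohort(*generate_cohort(config), tmp_path / "a")
        m2 = write_cohort(*generate_cohort(config), tmp_path / "b")
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)


class TestGenerateAtlas:
    def test_octants(self):
        atlas = generate_atlas((6, 6, 6), 8)
        sizes = np.bincount(atlas.ravel())[1:]
        assert len(sizes) == 8
        assert (sizes == 27).all()
        # corner blocks carry distinct labels
        assert atlas[0, 0, 0] != atlas[5, 5, 5]

    def test_single_region(self):
        atlas = generate_atlas((4, 4, 4), 1)
        assert (atlas == 1).all()

    def test_partition(self):
        atlas = generate_atlas((6, 6, 6), 8)
        assert np.bincount(atlas.ravel())[1:].sum() == 216
        assert atlas.min() == 1

    def test_prime_region_count_fallback(self):
        atlas = generate_atlas((6, 6, 6), 7)
        labels = np.unique(atlas)
        np.testing.assert_array_equal(labels, np.arange(1, 8))

    def test_too_many_regions(self):
        with pytest.raises(ValueError, match="n_regions"):
            generate_atlas((2, 2, 2), 9)
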