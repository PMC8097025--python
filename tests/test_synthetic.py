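"""The synthetic cohort generator: invariants, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from scndev.errors import InvalidConfigError
from scndev.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_parcellation,
    region_columns,
)


class TestParcellation:
    def test_minimal_parcellation(self):
        p = generate_parcellation(n_regions=4, n_modules=2, seed=1)
        assert (p.hemisphere == "L").sum() == 2
        assert (p.hemisphere == "R").sum() == 2
        assert set(p.modules) <= {1, 2}
        for d in p.distance.values():
            np.testing.assert_allclose(np.diagonal(d), 0.0)

    def test_every_module_populated(self, parcellation60):
        assert set(parcellation60.modules) == set(range(1, 8))

    def test_distance_matrices_valid(self, parcellation60):
        for hemi in ("L", "R"):
            d = parcellation60.distance[hemi]
            np.testing.assert_allclose(d, d.T)
            off = d[~np.eye(d.shape[0], dtype=bool)]
            assert (off > 0).all()
            assert (off <= np.pi + 1e-12).all()

    def test_antipodal_points_at_distance_pi(self):
        p = generate_parcellation(n_regions=4, n_modules=2, seed=1)
        p.coords[0] = [0.0, 0.0, 1.0]
        p.coords[1] = [0.0, 0.0, -1.0]
        from scndev.synthetic import _great_circle

        d = _great_circle(p.coords[:2])
        assert d[0, 1] == pytest.approx(np.pi)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_parcellation(n_regions=61, n_modules=7)
        with pytest.raises(InvalidConfigError):
            generate_parcellation(n_regions=10, n_modules=7)


class TestGenerateDataset:
    def test_seed_reproducibility(self, parcellation60):
        cfg = SyntheticConfig(seed=21)
        t1, _ = generate_dataset(cfg, parcellation60)
        t2, _ = generate_dataset(SyntheticConfig(seed=21), parcellation60)
        pd.testing.assert_frame_equal(t1, t2)

    def test_cohort_invariants(self, default_dataset):
        _, table, _ = default_dataset
        cfg = SyntheticConfig()
        assert table["age"].between(cfg.age_min, cfg.age_max).all()
        counts = table.groupby("participant_id").size()
        assert counts.between(1, 3).all()
        for _, grp in table.groupby("participant_id"):
            ages = grp.sort_values("scan_id")["age"].to_numpy()
            assert (np.diff(ages) > 0).all()
        assert (table[region_columns(table)].to_numpy() > 0).all()
        assert not table.duplicated(["participant_id", "scan_id"]).any()

    def test_scan_count_near_target(self, default_dataset):
        cfg, table, _ = default_dataset
        assert abs(len(table) - cfg.target_scans) <= 0.05 * cfg.target_scans
        assert table["participant_id"].nunique() == cfg.n_participants

    def test_noiseless_linear_thinning(self, parcellation60):
        cfg = SyntheticConfig(
            seed=1,
            noise_sd=0.0,
            subject_sd=0.0,
            loading_base=0.0,
            thinning_slope_mean=-0.05,
            thinning_slope_sd=0.0,
            region_mu_sd=0.0,
            scanner_effect=0.0,  # the upgrade step would break pure linearity
        )
        table, truth = generate_dataset(cfg, parcellation60)
        np.testing.assert_allclose(truth.slope, -0.05)
        regions = region_columns(table)
        for _, grp in table.groupby("participant_id"):
            if len(grp) < 2:
                continue
            grp = grp.sort_values("age")
            d_age = np.diff(grp["age"].to_numpy())
            d_th = np.diff(grp[regions].to_numpy(), axis=0)
            expected = np.broadcast_to(-0.05 * d_age[:, None], d_th.shape)
            np.testing.assert_allclose(d_th, expected, atol=1e-10)

    def test_zero_loadings_leave_no_residual_correlation(self, parcellation60):
        # residualize each region on covariates AND age with no subject
        # offset: off-diagonal correlations should center on 0
        cfg = SyntheticConfig(seed=3, loading_base=0.0, subject_sd=0.0)
        table, _ = generate_dataset(cfg, parcellation60)
        regions = region_columns(table)
        X = np.column_stack(
            [
                np.ones(len(table)),
                table["sex"],
                table["cohort"],
                table["scanner"],
                table["age"],
            ]
        ).astype(float)
        Y = table[regions].to_numpy()
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        r = np.corrcoef(resid, rowvar=False)
        off = r[np.triu_indices(len(regions), k=1)]
        assert abs(off.mean()) < 0.02

    def test_covariance_higher_near_peak_age(self, parcellation60):
        # oracle on the generator itself: sample correlation of per-region
        # detrended thickness at scans near vs far from the peak age
        cfg = SyntheticConfig(seed=11)
        table, truth = generate_dataset(cfg, parcellation60)
        regions = region_columns(table)
        X = np.column_stack(
            [np.ones(len(table)), table["sex"], table["cohort"],
             table["scanner"], table["age"]]
        ).astype(float)
        Y = table[regions].to_numpy()
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        near = np.abs(table["age"] - truth.peak_age) < 0.5
        far = np.abs(table["age"] - truth.peak_age) > 2.0
        assert near.sum() > 10 and far.sum() > 10

        def mean_abs_corr(mask):
            r = np.corrcoef(resid[mask.to_numpy()], rowvar=False)
            return np.abs(r[np.triu_indices(len(regions), k=1)]).mean()

        assert mean_abs_corr(near) > mean_abs_corr(far)

    def test_planted_coupling_in_ground_truth(self, default_dataset):
        cfg, _, truth = default_dataset
        r = np.corrcoef(truth.slope, truth.loading)[0, 1]
        assert r == pytest.approx(cfg.thinning_degree_coupling, abs=0.15)

    def test_scanner_only_at_fast_cohort_final_wave(self, default_dataset):
        _, table, _ = default_dataset
        upgraded = table[table["scanner"] == 1]
        assert (upgraded["cohort"] == 1).all()
        assert upgraded["scan_id"].str.endswith("w3").all()
        assert (table[table["cohort"] == 0]["scanner"] == 0).all()

    def test_invalid_configs_rejected(self, parcellation60):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(noise_sd=-0.1).validate()
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(target_scans=10_000).validate()
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(target_scans=100).validate()  # below n_participants
        with pytest.raises(InvalidConfigError):
            generate_dataset(
                SyntheticConfig(n_regions=30), parcellation60
            )
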