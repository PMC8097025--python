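"""Residualization, per-bin correlation, and bootstrap edge thresholding."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from scndev.errors import InvalidConfigError, InvalidInputError
from scndev.networks import (
    BootstrapSpec,
    bootstrap_threshold,
    correlation_matrix,
    mean_correlation,
    residualize,
)
from scndev.windows import AgeBin


def _table(values, covariates=None, region_names=None):
    """Build a minimal scan table from a (n_scans x n_regions) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "scan_id": [f"S{i}" for i in range(n)],
            "age": np.linspace(9, 13, n),
            "sex": (covariates or {}).get("sex", [0] * n),
            "cohort": (covariates or {}).get("cohort", [0] * n),
            "scanner": (covariates or {}).get("scanner", [0] * n),
        }
    )
    names = region_names or [f"R{j}" for j in range(values.shape[1])]
    for j, name in enumerate(names):
        df[name] = values[:, j]
    return df


def _bin_of(df):
    return AgeBin(
        0,
        tuple(df["scan_id"]),
        tuple(df["participant_id"]),
        tuple(df["age"]),
        float(np.median(df["age"])),
    )


class TestResidualize:
    def test_intercept_only_standardized_residuals(self):
        # values (1,2,3): residuals (-1,0,1), sigma=1, leverage 1/3
        # -> standardized (-1.2247, 0, 1.2247)
        df = _table(np.array([[1.0], [2.0], [3.0]]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant covariates dropped
            out = residualize(df)
        expected = np.array([-1, 0, 1]) / np.sqrt(1 - 1 / 3)
        np.testing.assert_allclose(out["R0"].to_numpy(), expected, atol=1e-12)

    def test_perfect_fit_returns_zeros(self):
        cov = {"sex": [0, 0, 1, 1]}
        df = _table(np.array([[1.0], [1.0], [2.0], [2.0]]), covariates=cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = residualize(df, covariates=("sex",))
        np.testing.assert_allclose(out["R0"].to_numpy(), 0.0)

    def test_residuals_centered_and_orthogonal_to_design(self, default_dataset):
        _, table, _ = default_dataset
        out = residualize(table)
        regions = [c for c in out.columns if c.startswith(("L", "R"))]
        R = out[regions].to_numpy()
        # studentization reweights by leverage, so the mean is only
        # approximately zero; near-orthogonality to the design is retained
        assert np.abs(R.mean(axis=0)).max() < 1e-3
        X = table[["sex", "cohort", "scanner"]].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        corr = Xc.T @ R / len(R)
        assert np.abs(corr).max() < 1e-3

    def test_idempotence_up_to_rescaling(self, default_dataset):
        _, table, _ = default_dataset
        once = residualize(table)
        twice = residualize(once)
        regions = [c for c in once.columns if c.startswith(("L", "R"))]
        a = once[regions].to_numpy()
        b = twice[regions].to_numpy()
        # raw residuals are exactly invariant; the leverage reweighting of
        # studentization perturbs orthogonality slightly, so the second
        # pass changes direction only at the ~leverage-variation scale
        for j in range(a.shape[1]):
            ra = a[:, j] / np.linalg.norm(a[:, j])
            rb = b[:, j] / np.linalg.norm(b[:, j])
            np.testing.assert_allclose(ra, rb, atol=5e-3)

    def test_constant_covariate_dropped_with_warning(self):
        df = _table(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.warns(UserWarning, match="constant"):
            residualize(df)

    def test_too_few_scans_rejected(self):
        df = _table(np.array([[1.0], [2.0]]), covariates={"sex": [0, 1]})
        with pytest.raises(InvalidInputError):
            residualize(df, covariates=("sex",))


class TestCorrelation:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_pairwise_pearson(self, a, b, expected):
        df = _table(np.column_stack([a, b]))
        net = correlation_matrix(df, _bin_of(df))
        assert net.r[0, 1] == pytest.approx(expected)
        assert net.r[0, 0] == 1.0

    def test_zero_variance_region_flagged(self):
        df = _table(np.column_stack([[1, 2, 3, 4], [2, 2, 2, 2]]))
        net = correlation_matrix(df, _bin_of(df))
        assert net.r[0, 1] == 0.0
        assert net.diagnostics["zero_variance_regions"] == 1

    def test_small_bin_rejected(self):
        df = _table(np.ones((2, 2)))
        with pytest.raises(InvalidInputError):
            correlation_matrix(df, _bin_of(df))


class TestMeanCorrelation:
    def _net(self, upper):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = upper[0]
        r[0, 2] = r[2, 0] = upper[1]
        r[1, 2] = r[2, 1] = upper[2]
        df = _table(np.random.default_rng(0).normal(size=(5, 3)))
        net = correlation_matrix(df, _bin_of(df))
        return dataclasses.replace(net, r=r)

    def test_positive_mode(self):
        assert mean_correlation(self._net([0.5, -0.2, 0.3])) == pytest.approx(0.4)

    def test_all_mode(self):
        net = self._net([0.5, -0.2, 0.3])
        assert mean_correlation(net, mode="all") == pytest.approx(0.2)

    def test_identity_matrix_gives_zero(self):
        net = self._net([0.0, 0.0, 0.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mean_correlation(net) == 0.0
        assert mean_correlation(net, mode="all") == 0.0


class TestBootstrapThreshold:
    def test_duplicate_regions_always_retained(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        df = _table(np.column_stack([x, x, rng.normal(size=80)]))
        net = bootstrap_threshold(df, _bin_of(df), BootstrapSpec(B=200, seed=0))
        assert net.retained[0, 1] == 1

    def test_null_retains_few_edges(self):
        # 20 independent regions: BH under the complete null retains < 5%
        rng = np.random.default_rng(3)
        df = _table(rng.normal(size=(80, 20)))
        net = bootstrap_threshold(df, _bin_of(df), BootstrapSpec(B=200, seed=3))
        frac = net.retained.sum() / (20 * 19)
        assert frac < 0.05

    def test_retained_implies_positive_point_estimate(self, small_dataset):
        _, table, _ = small_dataset
        resid = residualize(table)
        from scndev.windows import dedup_bin

        bin_ = dedup_bin(resid.iloc[:60])
        net = bootstrap_threshold(resid, bin_, BootstrapSpec(B=100, seed=2))
        iu = np.triu_indices(net.n_regions, k=1)
        mask = net.retained[iu] > 0
        assert (net.r[iu][mask] > 0).all()
        # symmetric 0/1 with zero diagonal
        assert np.array_equal(net.retained, net.retained.T)
        assert set(np.unique(net.retained)) <= {0, 1}
        assert not np.diagonal(net.retained).any()

    def test_retention_monotone_in_true_correlation(self):
        # equicorrelated data: higher rho never reduces expected retention
        fracs = []
        for rho in (0.0, 0.3, 0.6):
            rng = np.random.default_rng(7)
            shared = rng.normal(size=(80, 1))
            noise = rng.normal(size=(80, 12))
            X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            df = _table(X)
            net = bootstrap_threshold(df, _bin_of(df), BootstrapSpec(B=150, seed=5))
            fracs.append(net.retained.sum())
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidConfigError):
            BootstrapSpec(B=0)
        with pytest.raises(InvalidConfigError):
            BootstrapSpec(alpha=1.5)
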