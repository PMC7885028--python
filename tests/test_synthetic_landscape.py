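import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import COVARIATES, confounded_config, null_config
from paimpact.balance import balance_table
from paimpact.forest_change import compute_loss
from paimpact.matching import nearest_neighbor_match  # noqa: F401  (import check)
from paimpact.synthetic_landscape import (
    CovariateSpec,
    SimulationConfig,
    gaussian_random_field,
    generate_landscape,
    inject_missing,
)


class TestConfigValidation:
    def test_pa_fraction_bounds(self):
        with pytest.raises(ValueError, match="pa_fraction"):
            SimulationConfig(pa_fraction=0.0)
        with pytest.raises(ValueError, match="pa_fraction"):
            SimulationConfig(pa_fraction=1.0)

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="4 cells"):
            SimulationConfig(grid_nx=1, grid_ny=3)

    def test_nonpositive_range(self):
        with pytest.raises(ValueError, match="range_km"):
            SimulationConfig(covariate_specs=[CovariateSpec("a", -1.0, 1.0)])

    def test_json_roundtrip(self, tmp_path):
        cfg = confounded_config(seed=3)
        cfg.to_json(tmp_path / "c.json")
        back = SimulationConfig.from_json(tmp_path / "c.json")
        assert back == cfg


class TestGaussianRandomField:
    coords = np.column_stack(
        [np.repeat(np.arange(10.0), 10) + 0.5, np.tile(np.arange(10.0), 10) + 0.5]
    )

    def test_zero_variance_gives_zero_surface(self):
        z = gaussian_random_field(self.coords, 5.0, 0.0, seed=1)
        assert np.all(z == 0.0)

    def test_deterministic_for_fixed_seed(self):
        a = gaussian_random_field(self.coords, 5.0, 1.0, seed=42)
        b = gaussian_random_field(self.coords, 5.0, 1.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            gaussian_random_field(self.coords, 0.0, 1.0, seed=1)

    @pytest.mark.parametrize("method", ["cholesky", "spectral"])
    def test_correlation_decays_with_distance(self, method):
        # 30x30 grid, range 10: near-pair correlation must exceed far-pair
        # correlation when averaged over 20 seeds
        ix, iy = np.meshgrid(np.arange(30.0), np.arange(30.0), indexing="ij")
        coords = np.column_stack([ix.ravel(), iy.ravel()])
        d = squareform(pdist(coords))
        near = d < 2.0
        np.fill_diagonal(near, False)
        far = d > 25.0
        near_acc = far_acc = 0.0
        for seed in range(20):
            z = gaussian_random_field(coords, 10.0, 1.0, seed=seed, method=method)
            zc = z - z.mean()
            prod = np.outer(zc, zc) / zc.var()
            near_acc += prod[near].mean()
            far_acc += prod[far].mean()
        assert near_acc / 20 > 0.5
        assert near_acc / 20 > far_acc / 20 + 0.3


class TestGenerateLandscape:
    def test_determinism_bitwise_on_csv(self):
        cfg = confounded_config(seed=11, grid=15)
        a, b = io.StringIO(), io.StringIO()
        generate_landscape(cfg)[0].cells.to_csv(a, index=False)
        generate_landscape(cfg)[0].cells.to_csv(b, index=False)
        assert a.getvalue() == b.getvalue()

    def test_invariants(self, confounded_landscape):
        landscape, truth = confounded_landscape
        cells = landscape.cells
        assert cells["cell_id"].is_unique
        for y in landscape.years:
            f = cells[f"forest_{y}"].dropna()
            assert ((f >= 0) & (f <= 1)).all()
        prot = cells["protected"]
        assert cells.loc[prot, "pa_id"].notna().all()
        assert (cells.loc[prot, "iucn_cat"] != "").all()
        assert len(truth.expected_loss) == len(cells)

    def test_regions_contiguous(self, confounded_landscape):
        # every region is one connected component on the grid
        from scipy import ndimage

        landscape, _ = confounded_landscape
        nx = landscape.cells["x"].nunique()
        grid = landscape.cells["region_id"].to_numpy().reshape(nx, -1)
        for reg in np.unique(grid):
            _, num = ndimage.label(grid == reg)
            assert num == 1

    def test_no_confounding_means_balanced_covariates(self):
        diffs = []
        for seed in range(5):
            cfg = null_config(seed=seed, grid=25)
            landscape, _ = generate_landscape(cfg)
            c = landscape.cells
            t = c[c.protected]["cov_elevation"]
            u = c[~c.protected]["cov_elevation"]
            diffs.append(t.mean() - u.mean())
        pooled_sd = landscape.cells["cov_elevation"].std()
        assert abs(np.mean(diffs)) < 0.5 * pooled_sd

    def test_null_effect_null_difference(self):
        # zero siting coefs, zero effect: naive loss difference averages ~0
        diffs = []
        for seed in range(20):
            landscape, _ = generate_landscape(null_config(seed=seed))
            loss = compute_loss(landscape)
            prot = landscape.cells.set_index("cell_id")["protected"]
            diffs.append(loss.loss[prot].mean() - loss.loss[~prot].mean())
        assert abs(np.mean(diffs)) < 0.005

    def test_confounded_siting_produces_imbalance(self):
        # siting on elevation: pre-matching |ND| for elevation exceeds 25%
        from paimpact.balance import normalized_difference

        nds = []
        for seed in range(5):
            landscape, _ = generate_landscape(confounded_config(seed=seed))
            c = landscape.cells
            nds.append(
                normalized_difference(
                    c[c.protected]["cov_elevation"], c[~c.protected]["cov_elevation"]
                )
            )
        assert np.mean(nds) > 25.0

    def test_confounding_dial_monotone(self):
        # pre-matching |ND| of elevation is monotone in its siting coefficient
        from paimpact.balance import normalized_difference

        means = []
        for coef in (0.0, 0.8, 2.0):
            nds = []
            for seed in range(5):
                cfg = confounded_config(
                    seed=seed, pa_siting_coefs={"elevation": coef}, pa_clumping_sd=0.0
                )
                landscape, _ = generate_landscape(cfg)
                c = landscape.cells
                nds.append(
                    abs(
                        normalized_difference(
                            c[c.protected]["cov_elevation"],
                            c[~c.protected]["cov_elevation"],
                        )
                    )
                )
            means.append(np.mean(nds))
        assert means[0] <= means[1] <= means[2]

    def test_quantile_fallback_on_extreme_coefs(self):
        cfg = confounded_config(
            seed=0, grid=12, pa_siting_coefs={"elevation": 500.0}, pa_clumping_sd=0.0
        )
        with pytest.warns(RuntimeWarning, match="quantile"):
            landscape, _ = generate_landscape(cfg)
        frac = landscape.cells["protected"].mean()
        assert frac == pytest.approx(cfg.pa_fraction, abs=0.05)

    def test_regional_effect_shift(self):
        cfg = confounded_config(
            seed=1, true_protection_effect=-0.04, regional_effect_shift={1: 0.08}
        )
        _, truth = generate_landscape(cfg)
        assert truth.true_protection_effect == -0.04


class TestInjectMissing:
    def test_rate_zero_is_identity(self, confounded_landscape):
        landscape, _ = confounded_landscape
        out = inject_missing(landscape, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.cells, landscape.cells)

    def test_exact_count(self):
        landscape, _ = generate_landscape(
            null_config(grid=25, years=(2000, 2008, 2015))
        )
        assert len(landscape.cells) == 625
        out = inject_missing(landscape, 0.058, seed=3)
        n_missing = sum(out.cells[f"forest_{y}"].isna().sum() for y in out.years)
        assert n_missing == round(0.058 * 625 * 3)

    def test_deterministic_mask(self, confounded_landscape):
        landscape, _ = confounded_landscape
        a = inject_missing(landscape, 0.1, seed=5)
        b = inject_missing(landscape, 0.1, seed=5)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_rate_one_rejected(self, confounded_landscape):
        landscape, _ = confounded_landscape
        with pytest.raises(ValueError):
            inject_missing(landscape, 1.0, seed=1)
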