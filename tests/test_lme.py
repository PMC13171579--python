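import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dbslfp.design import make_design
from dbslfp.errors import ValidationError
from dbslfp.lme import (
    ModelSpec,
    VarianceDecomposition,
    bootstrap_predictions,
    fdr_adjust,
    fit_lme,
    marginal_grid,
    marginal_predictions,
    percentile_pvalues,
    variance_decomposition,
)
from dbslfp.synth import plant_effects, simulate_power_table


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def test_bh_worked_example():
    assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert fdr_adjust([0.2])[0] == pytest.approx(0.2)


def test_bh_all_ones_saturate():
    assert np.allclose(fdr_adjust([1.0] * 5), 1.0)


def test_bh_matches_brute_force_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = rng.integers(1, 21)
        p = rng.uniform(0, 1, size=m)
        assert np.allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_dominates_raw_p_and_matches_oracle(p):
    q = fdr_adjust(p)
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1.0).all()
    assert np.allclose(q, bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        fdr_adjust([0.5, 1.5])
    with pytest.raises(ValidationError):
        fdr_adjust([-0.1])


# ---------------------------------------------------------------------------
# variance decomposition arithmetic
# ---------------------------------------------------------------------------


def test_variance_share_worked_example():
    vd = VarianceDecomposition.from_sds(0.232, 0.561, 3.18)
    assert vd.share_subject_dataset_trial == pytest.approx(0.00514, abs=2e-4)
    assert round(100 * vd.share_subject_dataset_trial, 1) == 0.5


def test_variance_share_single_component():
    vd = VarianceDecomposition.from_sds(1.0, 0.0, 0.0)
    assert vd.share_subject_dataset_trial == 1.0


def test_variance_share_symmetry():
    vd = VarianceDecomposition.from_sds(1.0, 1.0, 1.0)
    assert vd.share_subject_dataset_trial == pytest.approx(1 / 3)
    assert vd.share_channel == pytest.approx(1 / 3)
    assert vd.share_residual == pytest.approx(1 / 3)
    assert vd.total_variance == pytest.approx(
        vd.sd_subject_dataset_trial**2 + vd.sd_channel**2 + vd.sd_residual**2
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def two_roi_design():
    return make_design(
        {"subjects": 1, "datasets_per_subject": 1, "trials_per_condition": 10,
         "channels_per_roi": 6, "rois": ("lOFC", "rOFC")}
    )


def test_zero_variance_data_gives_boundary_estimates(two_roi_design):
    effects, _ = plant_effects(
        two_roi_design, "null", sd_trial=0.0, sd_channel=0.0, sd_residual=0.3
    )
    table = simulate_power_table(two_roi_design, effects, seed=2)
    fit = fit_lme(table, ModelSpec(rois=two_roi_design.rois))
    vd = variance_decomposition(fit)
    assert vd.sd_subject_dataset_trial <= 0.05
    assert vd.sd_channel <= 0.05
    assert vd.sd_residual == pytest.approx(0.3, rel=0.1)


def test_planted_variance_components_recovered():
    """sd_channel=0.5, sd_residual=1 recovered within 25% (50 channels)."""
    d = make_design(
        {"subjects": 1, "datasets_per_subject": 1, "trials_per_condition": 15,
         "channels_per_roi": 26, "rois": ("lOFC", "rOFC")}
    )
    effects, _ = plant_effects(d, "null", sd_trial=0.0, sd_channel=0.5, sd_residual=1.0)
    table = simulate_power_table(d, effects, seed=7)
    table = table[table["band"] == "theta"]  # one band: 105 epochs x 50 channels
    fit = fit_lme(table, ModelSpec(rois=d.rois, bands=("theta",)))
    vd = variance_decomposition(fit)
    assert vd.sd_channel == pytest.approx(0.5, rel=0.25)
    assert vd.sd_residual == pytest.approx(1.0, rel=0.25)


def test_missing_condition_levels_named_in_error(mixed_tables):
    table, _, _ = mixed_tables
    sub = table[table["condition"] == "rSCC"]
    spec = ModelSpec(conditions=("rSCC", "lSCC", "bSCC"))
    with pytest.raises(ValidationError) as err:
        fit_lme(sub, spec)
    assert "lSCC" in str(err.value) and "bSCC" in str(err.value)


def test_marginal_grid_covers_full_cross_and_null_estimates(default_design):
    effects, _ = plant_effects(default_design, "null")
    table = simulate_power_table(default_design, effects, seed=3)
    spec = ModelSpec()
    fit = fit_lme(table, spec)
    est = marginal_predictions(fit)
    assert len(est) == 7 * 12 * 4 == 336
    # balanced null: estimates within 3 SEs of zero
    se = np.sqrt(
        (0.25**2 + 0.018**2) / 60 + 0.045**2 / 3
    )  # residual+trial over 60 rows, channel over 3 clusters
    assert (est["estimate"].abs() < 3 * se).mean() > 0.98
    assert est["estimate"].abs().max() < 5 * se


def test_marginal_predictions_reject_unseen_cells(two_roi_design):
    effects, _ = plant_effects(two_roi_design, "null")
    table = simulate_power_table(two_roi_design, effects, seed=1)
    fit = fit_lme(table, ModelSpec(rois=two_roi_design.rois))
    with pytest.raises(ValidationError, match="unseen"):
        marginal_predictions(fit, grid=["rSCC|lACC|theta"])


def test_lme_estimates_agree_with_balanced_cell_means(two_roi_design):
    """Saturated fixed effects + balanced design: GLS == cell means."""
    effects, _ = plant_effects(two_roi_design, "mixed")
    table = simulate_power_table(two_roi_design, effects, seed=4)
    fit = fit_lme(table, ModelSpec(rois=two_roi_design.rois))
    est = marginal_predictions(fit).set_index(["condition", "roi", "band"])["estimate"]
    means = table.groupby(["condition", "roi", "band"])["delta_p"].mean()
    assert np.allclose(est.sort_index(), means.sort_index(), atol=1e-6)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_minimum_attainable_p_is_one_over_nboot_plus_one():
    d = make_design({"subjects": 2, "datasets_per_subject": 1,
                     "trials_per_condition": 5, "channels_per_roi": 2})
    effects, _ = plant_effects(
        d, "all_additive",
        unilateral_amps={"rSCC": 1.0, "lSCC": 1.0, "rVCVS": 1.0, "lVCVS": 1.0},
        sd_trial=1e-3, sd_channel=1e-3, sd_residual=1e-2,
    )
    table = simulate_power_table(d, effects, seed=5)
    pframe, _ = bootstrap_predictions(table, ModelSpec(), n_boot=999, seed=1)
    assert pframe["p"].min() == pytest.approx(1 / 1000)


def test_bootstrap_is_deterministic_given_seed(two_roi_design):
    effects, _ = plant_effects(two_roi_design, "mixed")
    table = simulate_power_table(two_roi_design, effects, seed=6)
    spec = ModelSpec(rois=two_roi_design.rois)
    p1, b1 = bootstrap_predictions(table, spec, n_boot=59, seed=42)
    p2, b2 = bootstrap_predictions(table, spec, n_boot=59, seed=42)
    assert p1.equals(p2)
    assert np.array_equal(b1, b2)
    p3, _ = bootstrap_predictions(table, spec, n_boot=59, seed=43)
    assert not p1["p"].equals(p3["p"])


def test_null_pvalues_approximately_uniform(default_design):
    """Pooled fraction of p<0.05 over null grids lands in [0.02, 0.09]."""
    effects, _ = plant_effects(default_design, "null")
    hits, total = 0, 0
    for seed in (0, 1, 2):
        table = simulate_power_table(default_design, effects, seed=seed)
        pframe, _ = bootstrap_predictions(table, ModelSpec(), n_boot=199, seed=seed)
        hits += (pframe["p"] < 0.05).sum()
        total += len(pframe)
    assert 0.02 <= hits / total <= 0.09


def test_add_one_percentile_formula():
    boot = np.column_stack(
        [
            [0.5, 0.5, 0.5],    # no mass at/below 0  -> p = 1/4
            [0.5, -0.5, 0.5],   # one tail count      -> p = 3/4
            [0.5, -0.5, -0.5],  # min tail = 1        -> p = 3/4
            [0.0, -0.5, 0.5],   # ties count both ways -> capped at 1
        ]
    )
    assert np.allclose(percentile_pvalues(boot), [0.25, 0.75, 0.75, 1.0])


def test_full_lme_refit_bootstrap_smoke(two_roi_design):
    """The mixed-model refit path agrees in location with the fast refit."""
    d = make_design({"subjects": 1, "datasets_per_subject": 1,
                     "trials_per_condition": 4, "channels_per_roi": 2,
                     "rois": ("lOFC",)})
    effects, _ = plant_effects(d, "null", sd_residual=0.1)
    table = simulate_power_table(d, effects, seed=9)
    spec = ModelSpec(rois=("lOFC",))
    _, fast = bootstrap_predictions(table, spec, n_boot=5, seed=3, refit="cellmeans")
    _, slow = bootstrap_predictions(table, spec, n_boot=5, seed=3, refit="lme")
    assert slow.shape[1] == fast.shape[1]
    assert abs(np.nanmean(slow) - np.nanmean(fast)) < 0.2


def test_marginal_grid_output_contract(two_roi_design):
    effects, _ = plant_effects(two_roi_design, "mixed")
    table = simulate_power_table(two_roi_design, effects, seed=10)
    grid = marginal_grid(table, ModelSpec(rois=two_roi_design.rois), n_boot=99, seed=0)
    assert list(grid.columns) == ["condition", "roi", "band", "estimate", "p", "q", "significant"]
    assert len(grid) == 7 * 2 * 4
    assert (grid["q"] >= grid["p"] - 1e-12).all()
    assert grid["significant"].equals(grid["q"] < 0.05)
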