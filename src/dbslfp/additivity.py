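"""Additive-scale interaction analysis of combined stimulation conditions.

For each combination pair (bilateral SCC, bilateral VC/VS, multi-target)
the data are restricted to the pair's three conditions and a separate
mixed model is fit.  The interaction statistic on the additive scale is

    Interaction = delta_P_AB - (delta_P_A + delta_P_B)

evaluated per (ROI, band) cell from the model's marginal predictions.  A
cluster bootstrap yields the median interaction, a 95% percentile
interval and an add-one two-sided p-value per cell; Benjamini-Hochberg
correction is applied across the (ROI x band) family of each pair.  A
cell is *super-additive* when q < alpha and the median interaction has
the same sign as the expected additive effect delta_P_A + delta_P_B,
*sub-additive* when q < alpha with the opposite sign, and *additive*
when q >= alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .design import PAIRS, ROIS
from .errors import ValidationError
from .lme import (
    CELL_SEP,
    ModelSpec,
    _BootPlan,
    fdr_adjust,
    fit_lme,
    marginal_predictions,
    percentile_pvalues,
)
from .spectral import BAND_NAMES

log = logging.getLogger(__name__)

#: Below this magnitude the expected additive effect is treated as zero;
#: a significant interaction with zero expected effect is reported as
#: super-additive (an effect emerging where none was expected exceeds
#: the additive prediction in magnitude) and flagged in the report.
ZERO_EXPECTED_TOL = 1e-9

CLASS_MARKERS = {"super-additive": "+*", "sub-additive": "-*", "additive": "o"}

RESULT_COLUMNS = (
    "pair", "roi", "band", "median_interaction", "ci_lo", "ci_hi",
    "expected_sum", "p", "q", "class",
)


def partition_subsets(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split the power table into the three interaction subsets.

    Each subset holds exactly the rows of its pair's three conditions
    (A, B, AB); conditions shared between pairs appear in several
    subsets.  Raises when a required condition is absent.
    """
    present = set(table["condition"].unique())
    out = {}
    for pair, conds in PAIRS.items():
        missing = sorted(set(conds) - present)
        if missing:
            raise ValidationError(f"pair '{pair}' missing condition(s): {missing}")
        out[pair] = table[table["condition"].isin(conds)].reset_index(drop=True)
    return out


def interaction_statistic(dp_ab, dp_a, dp_b):
    """Additive-scale interaction: dp_ab - (dp_a + dp_b). Vectorized."""
    return np.asarray(dp_ab) - (np.asarray(dp_a) + np.asarray(dp_b))


def classify_interaction(median, expected_sum, q, alpha: float = 0.05):
    """Interaction class from the significance/sign rule.  Vectorized.

    Additive when q >= alpha; otherwise super-additive when the median
    interaction and the expected additive effect share a sign (or the
    expected effect is numerically zero), sub-additive when they oppose.
    """
    median = np.atleast_1d(np.asarray(median, dtype=float))
    expected = np.atleast_1d(np.asarray(expected_sum, dtype=float))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    zero_exp = np.abs(expected) < ZERO_EXPECTED_TOL
    prod = np.sign(median) * np.sign(expected)
    out = np.where(
        q >= alpha,
        "additive",
        np.where(zero_exp | (prod > 0), "super-additive", "sub-additive"),
    )
    return out if out.size > 1 else out.item()


def bootstrap_interaction(
    subset_table: pd.DataFrame,
    pair: str,
    n_boot: int = 999,
    seed: int = 0,
    rois: tuple[str, ...] = ROIS,
    bands: tuple[str, ...] = BAND_NAMES,
    refit: str = "cellmeans",
) -> pd.DataFrame:
    """Bootstrap distribution of the interaction per (ROI, band).

    Point estimates of delta_P_A, delta_P_B and delta_P_AB come from the
    REML fit's marginal predictions; the bootstrap resamples trial and
    channel clusters, recomputes the per-condition cell estimates and
    the interaction contrast per replicate, and summarizes with the
    median, the 2.5/97.5 percentile interval and the add-one two-sided
    p-value.  Identical seeds give identical output.
    """
    a, b, ab = PAIRS[pair]
    spec = ModelSpec(conditions=(a, b, ab), rois=tuple(rois), bands=tuple(bands))
    spec.validate_table(subset_table)

    fit = fit_lme(subset_table, spec)
    est = marginal_predictions(fit).set_index(["condition", "roi", "band"])["estimate"]

    rng = default_rng(seed)
    plan = _BootPlan(subset_table, spec)
    cells = np.array(plan.cells)  # order: condition-major, then roi, band
    cond_of = np.array([c.split(CELL_SEP)[0] for c in cells])
    idx_a, idx_b, idx_ab = (np.where(cond_of == c)[0] for c in (a, b, ab))
    boot_inter = np.empty((n_boot, len(idx_a)))
    for r in range(n_boot):
        cell_est = plan.cell_estimates(plan.weights(rng))
        boot_inter[r] = interaction_statistic(cell_est[idx_ab], cell_est[idx_a], cell_est[idx_b])

    rows = []
    med = np.median(boot_inter, axis=0)
    lo, hi = np.percentile(boot_inter, [2.5, 97.5], axis=0)
    p = percentile_pvalues(boot_inter)
    for j, cell in enumerate(cells[idx_a]):
        _, roi, band = cell.split(CELL_SEP)
        dp_a = est.loc[(a, roi, band)]
        dp_b = est.loc[(b, roi, band)]
        dp_ab = est.loc[(ab, roi, band)]
        rows.append(
            (
                pair, roi, band, med[j], lo[j], hi[j],
                dp_a + dp_b, p[j],
                dp_a, dp_b, dp_ab,
                interaction_statistic(dp_ab, dp_a, dp_b).item(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "roi", "band", "median_interaction", "ci_lo", "ci_hi",
            "expected_sum", "p", "dp_a", "dp_b", "dp_ab", "interaction_estimate",
        ],
    )


def analyze_additivity(
    table: pd.DataFrame,
    n_boot: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    rois: tuple[str, ...] = ROIS,
    bands: tuple[str, ...] = BAND_NAMES,
) -> pd.DataFrame:
    """Full interaction analysis over the three pairs.

    FDR correction is applied within each pair's (ROI x band) family.
    Returns one row per (pair, roi, band) with the bootstrap summary,
    q-value and interaction class.
    """
    subsets = partition_subsets(table)
    frames = []
    for i, (pair, sub) in enumerate(subsets.items()):
        pair_seed = SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        res = bootstrap_interaction(
            sub, pair, n_boot=n_boot, seed=int(pair_seed), rois=rois, bands=bands
        )
        res["q"] = fdr_adjust(res["p"].to_numpy())
        res["class"] = classify_interaction(
            res["median_interaction"], res["expected_sum"], res["q"], alpha
        )
        res["zero_expected_flag"] = np.abs(res["expected_sum"]) < ZERO_EXPECTED_TOL
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def additivity_report(results: pd.DataFrame) -> dict:
    """Heatmap-shaped tables and per-pair class tallies.

    For each pair: a ROI x band grid of median interactions and a grid
    of class markers (+* super-additive, -* sub-additive, o additive,
    with '!' appended where the expected additive effect was numerically
    zero).  Also returns class counts per pair.
    """
    heatmaps, markers = {}, {}
    for pair, grp in results.groupby("pair", sort=False):
        heatmaps[pair] = grp.pivot(index="band", columns="roi", values="median_interaction")
        mk = grp.copy()
        mk["marker"] = mk["class"].map(CLASS_MARKERS)
        if "zero_expected_flag" in mk:
            mk.loc[mk["zero_expected_flag"] & (mk["class"] != "additive"), "marker"] += "!"
        markers[pair] = mk.pivot(index="band", columns="roi", values="marker")
    tally = (
        results.groupby(["pair", "class"]).size().rename("n").reset_index()
    )
    return {"median": heatmaps, "markers": markers, "tally": tally}
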