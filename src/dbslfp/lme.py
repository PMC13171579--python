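"""Hierarchical inference on relative band-power change.

The response ``delta_p`` is modelled with a linear mixed-effects model:
fixed effects for stimulation condition, ROI and frequency band with all
two- and three-way interactions (a saturated cell-mean structure over
the condition x ROI x band grid), and random intercepts for recording
channel (nested in ROI) and for trial nested in dataset nested in
subject.  Fitting uses REML.  Population-level ("marginal") predictions
are the fixed-effects-only predictions per grid cell.

Uncertainty comes from a cluster bootstrap rather than parametric
standard errors: whole trial clusters are resampled with replacement
within (subject, dataset, condition) strata, and whole channel clusters
within ROI strata, so the resampling respects the dependence the random
effects encode.  Because the fixed-effect structure is saturated and the
design balanced, the refitted fixed-effect estimate for a cell reduces
to the weighted cell mean of the resampled data, which each replicate
recomputes directly; a full mixed-model refit per replicate is available
via ``refit='lme'``.  Two-sided percentile p-values use the add-one rule

    p = (2 * min(#{est_b <= 0}, #{est_b >= 0}) + 1) / (n_boot + 1)

capped at 1, and are corrected across a model's grid with the
Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from numpy.random import Generator, default_rng
from statsmodels.stats.multitest import multipletests

from .design import CONDITIONS, ROIS
from .errors import ValidationError
from .spectral import BAND_NAMES

log = logging.getLogger(__name__)

CELL_SEP = "|"


@dataclass(frozen=True)
class ModelSpec:
    """Factor levels and response for one mixed model."""

    conditions: tuple[str, ...] = CONDITIONS
    rois: tuple[str, ...] = ROIS
    bands: tuple[str, ...] = BAND_NAMES
    response: str = "delta_p"

    @property
    def cells(self) -> list[str]:
        return [
            CELL_SEP.join(key)
            for key in product(self.conditions, self.rois, self.bands)
        ]

    def validate_table(self, table: pd.DataFrame) -> None:
        required = {self.response, "condition", "roi", "band", "subject", "dataset", "trial", "channel"}
        missing_cols = required - set(table.columns)
        if missing_cols:
            raise ValidationError(f"table missing columns: {sorted(missing_cols)}")
        if len(table) == 0:
            raise ValidationError("table is empty")
        for col, levels in (
            ("condition", self.conditions),
            ("roi", self.rois),
            ("band", self.bands),
        ):
            missing = sorted(set(levels) - set(table[col].unique()))
            if missing:
                raise ValidationError(f"table missing {col} levels: {missing}")


def _cell_key(table: pd.DataFrame) -> pd.Series:
    return table["condition"] + CELL_SEP + table["roi"] + CELL_SEP + table["band"]


@dataclass
class LMEFit:
    """A fitted mixed model plus the cell bookkeeping needed downstream."""

    result: object  # statsmodels MixedLMResults
    spec: ModelSpec
    cells: list[str]  # observed cells, in spec order

    @property
    def converged(self) -> bool:
        return bool(getattr(self.result, "converged", True))


def fit_lme(table: pd.DataFrame, spec: ModelSpec) -> LMEFit:
    """REML fit of the saturated mixed model.

    Random structure: variance components for trial (nested in dataset
    nested in subject; grouped by subject) and recording channel.  Grid
    cells without observations are dropped from the grid with a warning.
    Raises on non-convergence with the optimizer diagnostics attached.
    """
    spec.validate_table(table)
    df = table.copy()
    df["cell"] = _cell_key(df)
    observed = set(df["cell"])
    cells = [c for c in spec.cells if c in observed]
    dropped = len(spec.cells) - len(cells)
    if dropped:
        log.warning("dropping %d grid cells with no observations", dropped)
    df["cell"] = pd.Categorical(df["cell"], categories=cells)
    df["sdt"] = df["dataset"].astype(str) + ":" + df["trial"].astype(str)
    model = smf.mixedlm(
        f"{spec.response} ~ 0 + C(cell)",
        data=df,
        groups=df["subject"],
        re_formula="0",
        vc_formula={"trial": "0 + C(sdt)", "channel": "0 + C(channel)"},
    )
    start = _moment_start(df, model, spec.response)
    # Variance components near zero put REML on the parameter boundary,
    # where a single optimizer can stall; fall through a short chain.
    result = None
    for method in ("bfgs", "cg", "powell"):
        result = model.fit(reml=True, method=method, maxiter=500, start_params=start)
        if result.converged:
            break
        start = None  # retry from statsmodels defaults
    if result is None or not result.converged:
        raise ValidationError(
            f"mixed model failed to converge: {getattr(result, 'mle_retvals', None)!r}"
        )
    return LMEFit(result=result, spec=spec, cells=cells)


def _moment_start(df: pd.DataFrame, model, response: str):
    """Method-of-moments starting values for the REML optimizer.

    Cell means are swept out; the variance of trial- and channel-level
    residual means seeds the two variance components (as ratios to the
    residual variance, the profiled parameterization statsmodels uses).
    """
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    r = df[response] - df.groupby("cell", observed=True)[response].transform("mean")
    v_e = float(r.var())
    if not np.isfinite(v_e) or v_e <= 0:
        return None
    by = {
        "trial": ["subject", "sdt"],
        "channel": ["channel"],
    }
    ratios = {}
    for name, cols in by.items():
        v = float(df.assign(_r=r).groupby(cols, observed=True)["_r"].mean().var())
        ratios[name] = max(v, 1e-8) / v_e
    ordered = [ratios[n] for n in model.exog_vc.names]
    return MixedLMParams.from_components(vcomp=np.asarray(ordered))


def _split_cell(cell: str) -> tuple[str, str, str]:
    cond, roi, band = cell.split(CELL_SEP)
    return cond, roi, band


def marginal_predictions(fit: LMEFit, grid: list[str] | None = None) -> pd.DataFrame:
    """Fixed-effects-only predictions per (condition, roi, band) cell."""
    params = fit.result.fe_params
    by_cell = {}
    for name, value in params.items():
        if "[" in name:
            by_cell[name[name.index("[") + 1:-1]] = float(value)
    grid = fit.cells if grid is None else list(grid)
    unseen = sorted(set(grid) - set(by_cell))
    if unseen:
        raise ValidationError(f"grid cells unseen in training: {unseen}")
    rows = [(*_split_cell(c), by_cell[c]) for c in grid]
    return pd.DataFrame(rows, columns=["condition", "roi", "band", "estimate"])


@dataclass(frozen=True)
class VarianceDecomposition:
    """Random-effect and residual standard deviations with variance shares."""

    sd_subject_dataset_trial: float
    sd_channel: float
    sd_residual: float

    @property
    def total_variance(self) -> float:
        return (
            self.sd_subject_dataset_trial ** 2
            + self.sd_channel ** 2
            + self.sd_residual ** 2
        )

    @property
    def share_subject_dataset_trial(self) -> float:
        return self.sd_subject_dataset_trial ** 2 / self.total_variance

    @property
    def share_channel(self) -> float:
        return self.sd_channel ** 2 / self.total_variance

    @property
    def share_residual(self) -> float:
        return self.sd_residual ** 2 / self.total_variance

    @classmethod
    def from_sds(cls, sd_subject_dataset_trial: float, sd_channel: float, sd_residual: float):
        return cls(sd_subject_dataset_trial, sd_channel, sd_residual)

    def as_dict(self) -> dict:
        return {
            "sd_subject_dataset_trial": self.sd_subject_dataset_trial,
            "sd_channel": self.sd_channel,
            "sd_residual": self.sd_residual,
            "share_subject_dataset_trial": self.share_subject_dataset_trial,
            "share_channel": self.share_channel,
            "share_residual": self.share_residual,
        }


def variance_decomposition(fit: LMEFit) -> VarianceDecomposition:
    """Standard deviations and variance shares from a fitted model."""
    names = list(fit.result.model.exog_vc.names)
    vcomp = np.asarray(fit.result.vcomp)
    comp = dict(zip(names, vcomp))
    return VarianceDecomposition(
        sd_subject_dataset_trial=float(np.sqrt(max(comp.get("trial", 0.0), 0.0))),
        sd_channel=float(np.sqrt(max(comp.get("channel", 0.0), 0.0))),
        sd_residual=float(np.sqrt(fit.result.scale)),
    )


# ---------------------------------------------------------------------------
# cluster bootstrap
# ---------------------------------------------------------------------------


class _BootPlan:
    """Precomputed integer codes for fast weighted-cell-mean replicates."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        self.cells = spec.cells
        codes = pd.Categorical(_cell_key(table), categories=self.cells).codes
        if (codes < 0).any():
            raise ValidationError("table contains cells outside the model grid")
        self.cell_code = np.asarray(codes)
        self.n_cells = len(self.cells)
        self.dp = table[spec.response].to_numpy(dtype=float)

        trial_key = (
            table["subject"].astype(str) + "/" + table["dataset"].astype(str)
            + "/" + table["trial"].astype(str)
        )
        self.t_code, t_uniques = pd.factorize(trial_key)
        stratum_key = (
            table["subject"].astype(str) + "/" + table["dataset"].astype(str)
            + "/" + table["condition"].astype(str)
        )
        per_trial = pd.DataFrame({"t": self.t_code, "s": stratum_key}).drop_duplicates("t")
        self.trial_strata = [grp["t"].to_numpy() for _, grp in per_trial.groupby("s", sort=True)]
        self.n_trials = len(t_uniques)

        self.c_code, c_uniques = pd.factorize(table["channel"])
        per_chan = pd.DataFrame({"c": self.c_code, "roi": table["roi"]}).drop_duplicates("c")
        self.chan_strata = [grp["c"].to_numpy() for _, grp in per_chan.groupby("roi", sort=True)]
        self.n_channels = len(c_uniques)

    def weights(self, rng: Generator) -> np.ndarray:
        tw = np.zeros(self.n_trials)
        for arr in self.trial_strata:
            k = len(arr)
            tw[arr] = rng.multinomial(k, np.full(k, 1.0 / k))
        cw = np.zeros(self.n_channels)
        for arr in self.chan_strata:
            k = len(arr)
            cw[arr] = rng.multinomial(k, np.full(k, 1.0 / k))
        return tw[self.t_code] * cw[self.c_code]

    def cell_estimates(self, w: np.ndarray) -> np.ndarray:
        num = np.bincount(self.cell_code, weights=w * self.dp, minlength=self.n_cells)
        den = np.bincount(self.cell_code, weights=w, minlength=self.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)


def percentile_pvalues(boot: np.ndarray) -> np.ndarray:
    """Add-one two-sided percentile p-values per column of ``boot``."""
    finite = np.isfinite(boot)
    n = finite.sum(axis=0)
    n_le = ((boot <= 0) & finite).sum(axis=0)
    n_ge = ((boot >= 0) & finite).sum(axis=0)
    p = (2.0 * np.minimum(n_le, n_ge) + 1.0) / (n + 1.0)
    return np.minimum(p, 1.0)


def bootstrap_predictions(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 999,
    seed: int = 0,
    refit: str = "cellmeans",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-bootstrap distribution of the marginal prediction per cell.

    Returns a frame (condition, roi, band, p) in grid order and the
    (n_boot, n_cells) matrix of replicate estimates.  ``refit`` selects
    the per-replicate estimator: ``'cellmeans'`` (weighted saturated-model
    refit; the default) or ``'lme'`` (full mixed-model refit; replicates
    that fail to converge are dropped, aborting if more than 5% fail).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    spec.validate_table(table)
    rng = default_rng(seed)
    plan = _BootPlan(table, spec)
    if refit == "cellmeans":
        boot = np.empty((n_boot, plan.n_cells))
        for b in range(n_boot):
            boot[b] = plan.cell_estimates(plan.weights(rng))
    elif refit == "lme":
        boot = _bootstrap_lme(table, spec, n_boot, rng)
    else:
        raise ValidationError(f"unknown refit mode '{refit}'")
    p = percentile_pvalues(boot)
    rows = [(*_split_cell(c), p[i]) for i, c in enumerate(plan.cells)]
    return pd.DataFrame(rows, columns=["condition", "roi", "band", "p"]), boot


def _bootstrap_lme(table: pd.DataFrame, spec: ModelSpec, n_boot: int, rng: Generator) -> np.ndarray:
    """Full mixed-model refit per replicate (slow; for cross-checks)."""
    cells = spec.cells
    trial_key = (
        table["subject"].astype(str) + "/" + table["dataset"].astype(str)
        + "/" + table["trial"].astype(str)
    )
    groups = {k: idx.to_numpy() for k, idx in table.groupby(trial_key, sort=True).groups.items()}
    strata: dict[str, list[str]] = {}
    per_trial = table.assign(tk=trial_key).drop_duplicates("tk")
    for r in per_trial.itertuples():
        strata.setdefault(f"{r.subject}/{r.dataset}/{r.condition}", []).append(r.tk)
    boot = np.full((n_boot, len(cells)), np.nan)
    n_fail = 0
    for b in range(n_boot):
        blocks: list[pd.DataFrame] = []
        for _, tks in sorted(strata.items()):
            take = rng.integers(0, len(tks), size=len(tks))
            for i, j in enumerate(take):
                block = table.loc[groups[tks[j]]].copy()
                # fresh cluster label: a trial drawn twice is two clusters
                block["trial"] = block["trial"].astype(str) + f"_b{i}"
                blocks.append(block)
        sample = pd.concat(blocks, ignore_index=True)
        try:
            fit = fit_lme(sample, spec)
            est = marginal_predictions(fit).set_index(["condition", "roi", "band"])["estimate"]
            boot[b] = [est.get(_split_cell(c), np.nan) for c in cells]
        except Exception:  # non-convergence or degenerate resample
            n_fail += 1
            if n_fail > 0.05 * n_boot + 1:
                raise ValidationError(f"{n_fail} bootstrap replicates failed to converge")
    if n_fail == n_boot:
        raise ValidationError("all bootstrap replicates failed")
    if n_fail:
        log.warning("dropped %d non-converged bootstrap replicates", n_fail)
    return boot[~np.isnan(boot).all(axis=1)]


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marginal_grid(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    refit: str = "cellmeans",
) -> pd.DataFrame:
    """Full inference grid: LME estimate, bootstrap p, BH q, significance.

    The FDR family is the complete condition x ROI x band grid of the
    model.  Returns columns condition, roi, band, estimate, p, q,
    significant.
    """
    fit = fit_lme(table, spec)
    est = marginal_predictions(fit)
    pframe, _ = bootstrap_predictions(table, spec, n_boot=n_boot, seed=seed, refit=refit)
    out = est.merge(pframe, on=["condition", "roi", "band"], how="left")
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
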