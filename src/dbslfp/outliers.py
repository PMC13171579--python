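"""Deterministic screening of stimulation-edge artifacts.

Epochs contaminated by transient deflections at stimulation onset or
offset show excess broadband wavelet power concentrated in the 100 ms
windows flanking the stimulation period.  The screen scores each epoch
by the ratio of mean broadband power in those edge windows to the mean
broadband power over the remaining pre + post interior, and removes all
records from epochs whose ratio exceeds a threshold.  A clean stationary
epoch scores close to 1; the default threshold of 5 keeps the
false-positive rate on clean data well below 1% while catching strong
edge artifacts essentially always.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectral import edge_interior_masks

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 5.0


@dataclass(frozen=True)
class OutlierReport:
    """Per-epoch edge scores, flags and summary counts."""

    threshold: float
    per_epoch: pd.DataFrame  # epoch_id, score, flag
    n_total: int
    n_flagged: int

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else 0.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_flagged": self.n_flagged,
            "fraction_flagged": self.fraction_flagged,
            "per_epoch": [
                {"epoch_id": r.epoch_id, "score": None if np.isinf(r.score) else float(r.score),
                 "flag": bool(r.flag)}
                for r in self.per_epoch.itertuples()
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def edge_artifact_score(
    power_matrix: np.ndarray,
    fs: float,
    epoch_layout: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Edge-to-interior broadband power ratio for one epoch.

    ``power_matrix`` is (freq, time) or (channel, freq, time) covering
    the full epoch; multi-channel input is averaged across channels.
    Returns ``inf`` when the interior power is exactly zero (degenerate
    epoch, always flagged).
    """
    p = np.asarray(power_matrix, dtype=float)
    if p.ndim == 3:
        p = p.mean(axis=0)
    if p.ndim != 2:
        raise ValidationError("power matrix must be (freq, time) or (channel, freq, time)")
    pre_s, stim_s, post_s = epoch_layout
    edge, interior = edge_interior_masks(p.shape[-1], fs, pre_s, stim_s, post_s)
    interior_power = p[:, interior].mean()
    edge_power = p[:, edge].mean()
    if interior_power == 0.0:
        return np.inf
    return float(edge_power / interior_power)


def flag_outliers(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop all records belonging to epochs whose edge score exceeds the threshold.

    ``scores`` carries one row per epoch (columns epoch_id, score).
    Returns the filtered power table and an :class:`OutlierReport`.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    per_epoch = scores.copy()
    per_epoch["flag"] = per_epoch["score"] > threshold
    flagged = set(per_epoch.loc[per_epoch["flag"], "epoch_id"])
    kept = table[~table["epoch_id"].isin(flagged)].reset_index(drop=True)
    report = OutlierReport(
        threshold=threshold,
        per_epoch=per_epoch,
        n_total=len(per_epoch),
        n_flagged=int(per_epoch["flag"].sum()),
    )
    if report.n_flagged:
        log.info("flagged %d/%d epochs as edge-artifact outliers", report.n_flagged, report.n_total)
    return kept, report
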