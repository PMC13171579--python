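"""Synthetic multi-site stimulation recordings with planted effect structure.

Two generators share one planted-effect specification:

* :func:`synthesize_session` builds raw monopolar voltage traces.  Each
  contact carries a sum of four band-limited Gaussian noise streams
  (4th-order Butterworth band-passed white noise) whose amplitude from
  stimulation onset to the end of the epoch is scaled by
  ``sqrt(1 + delta_p_effective)``, so the planted value is exactly the
  relative band-power change the analysis estimates.  A common-mode
  stream shared by all contacts of a lead is added on top, giving
  bipolar re-referencing real work to do.
* :func:`simulate_power_table` draws the post-spectral band-power table
  directly from the hierarchical model the inference stage assumes
  (planted cell effect + trial and channel random intercepts + residual),
  which is cheap enough for repeated calibration runs.

``delta_p_effective`` for one record is::

    delta_p_true(condition, roi, band)
      + b_trial(subject, dataset, trial)      ~ N(0, sd_trial^2)
      + b_channel(subject, channel)           ~ N(0, sd_channel^2)
      + eps                                   ~ N(0, sd_residual^2)

For every combined condition AB the planted effects satisfy the additive
identity ``delta_p_true(AB) = delta_p_true(A) + delta_p_true(B) +
interaction_true(A, B)`` exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.signal import butter, sosfiltfilt, windows

from .design import (
    CONDITIONS,
    PAIRS,
    PULSE_METADATA,
    UNILATERAL_CONDITIONS,
    StudyDesign,
    hemisphere_of,
)
from .errors import ConfigurationError, ValidationError
from .preprocess import RecordingSession
from .spectral import BANDS, BAND_NAMES

log = logging.getLogger(__name__)

SCENARIOS = ("null", "all_additive", "all_sub", "all_super", "mixed")

#: Default per-condition unilateral effect amplitudes (theta-band value;
#: other bands are scaled by DEFAULT_BAND_FACTORS).
DEFAULT_UNILATERAL_AMPS = {"rSCC": 0.3, "lSCC": 0.2, "rVCVS": 0.25, "lVCVS": 0.2}

#: Band scaling of the planted effects: low-frequency modulation dominates.
DEFAULT_BAND_FACTORS = {"theta": 1.0, "alpha": 0.8, "beta": 0.5, "gamma": 0.4}

#: Baseline band power (variance of the band-limited component, a.u.),
#: decreasing with frequency like a coarse 1/f spectrum.
DEFAULT_BASE_POWER = {"theta": 4.0, "alpha": 2.0, "beta": 1.0, "gamma": 0.5}

#: Random-intercept and residual scales on the delta-p scale.  The ratios
#: trial : channel : residual follow the variance structure this kind of
#: stimulation data shows (trial and channel dispersion small relative to
#: the single-record residual); the absolute residual is set so a single
#: record's delta_p standard deviation is about 0.3.
DEFAULT_SD_TRIAL = 0.018
DEFAULT_SD_CHANNEL = 0.045
DEFAULT_SD_RESIDUAL = 0.25

#: Common-mode amplitude relative to a contact's private signal.
DEFAULT_CM_SCALE = 2.0

DEFAULT_INTERACTION_MAGNITUDE = 0.3

#: Physical floor on 1 + delta_p_effective in signal synthesis: power
#: saturates here instead of going negative on rare Gaussian-tail draws.
GAIN_FLOOR = 0.02


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects and noise scales for one synthetic study.

    ``delta_p_true`` is indexed by (condition, roi, band),
    ``interaction_true`` by (pair, roi, band) and ``base_power`` by
    (roi, band); all are pandas Series.
    """

    delta_p_true: pd.Series
    interaction_true: pd.Series
    base_power: pd.Series
    sd_trial: float = DEFAULT_SD_TRIAL
    sd_channel: float = DEFAULT_SD_CHANNEL
    sd_residual: float = DEFAULT_SD_RESIDUAL
    cm_scale: float = DEFAULT_CM_SCALE

    def __post_init__(self):
        for name, sd in (
            ("sd_trial", self.sd_trial),
            ("sd_channel", self.sd_channel),
            ("sd_residual", self.sd_residual),
        ):
            if sd < 0:
                raise ValidationError(f"{name} must be >= 0, got {sd}")
        if (self.base_power <= 0).any():
            raise ValidationError("base_power must be positive everywhere")
        # Additive identity: delta(AB) = delta(A) + delta(B) + interaction.
        for pair, (a, b, ab) in PAIRS.items():
            lhs = self.delta_p_true.loc[ab]
            rhs = self.delta_p_true.loc[a] + self.delta_p_true.loc[b] + self.interaction_true.loc[pair]
            if not np.allclose(lhs.values, rhs.values, rtol=0, atol=1e-12):
                raise ValidationError(f"additive identity violated for pair '{pair}'")

    def expected_sum(self, pair: str) -> pd.Series:
        """delta_p_true(A) + delta_p_true(B) per (roi, band)."""
        a, b, _ = PAIRS[pair]
        return self.delta_p_true.loc[a] + self.delta_p_true.loc[b]


def build_ground_truth(effects: EffectSpec) -> pd.DataFrame:
    """Derive the true interaction class per (pair, roi, band).

    A cell is *additive* iff its planted interaction is exactly zero;
    otherwise it is *super-additive* when the interaction has the same
    (non-zero) sign as the expected additive effect delta_A + delta_B and
    *sub-additive* in every other non-zero case.
    """
    rows = []
    for pair in PAIRS:
        inter = effects.interaction_true.loc[pair]
        exp = effects.expected_sum(pair)
        for (roi, band), i_val in inter.items():
            e_val = exp.loc[(roi, band)]
            if i_val == 0:
                cls = "additive"
            elif np.sign(i_val) == np.sign(e_val) and np.sign(e_val) != 0:
                cls = "super-additive"
            else:
                cls = "sub-additive"
            rows.append((pair, roi, band, i_val, cls, e_val))
    return pd.DataFrame(
        rows,
        columns=["pair", "roi", "band", "interaction_true", "class_true", "expected_sum"],
    )


def _mixed_pattern(n_rois: int, n_bands: int) -> np.ndarray:
    """Deterministic class pattern over the (roi, band) grid of one pair.

    Cell classes cycle so that roughly 2/3 are additive, ~1/4
    sub-additive and a handful super-additive, echoing the class balance
    combinatorial stimulation data tends to show.  The stride is coprime
    to the band count so every class lands in every band (spectral
    estimation noise is band-dependent and no class should be confined
    to the noisiest bands).  Returns +1 (super), -1 (sub) or 0
    (additive) per flattened (roi-major) cell.
    """
    idx = np.arange(n_rois * n_bands)
    out = np.zeros_like(idx)
    out[idx % 13 % 4 == 1] = -1
    out[idx % 13 == 0] = +1
    return out


def plant_effects(
    design: StudyDesign,
    scenario: str = "mixed",
    seed: int = 0,
    *,
    unilateral_amps: dict[str, float] | None = None,
    band_factors: dict[str, float] | None = None,
    interaction_magnitude: float = DEFAULT_INTERACTION_MAGNITUDE,
    base_power: dict[str, float] | None = None,
    sd_trial: float = DEFAULT_SD_TRIAL,
    sd_channel: float = DEFAULT_SD_CHANNEL,
    sd_residual: float = DEFAULT_SD_RESIDUAL,
    cm_scale: float = DEFAULT_CM_SCALE,
) -> tuple[EffectSpec, pd.DataFrame]:
    """Plant per-cell effects for a named scenario and derive ground truth.

    Scenarios
    ---------
    ``null``
        Every effect and interaction is zero.
    ``all_additive``
        Non-zero unilateral effects, zero interactions everywhere.
    ``all_sub`` / ``all_super``
        Interactions of magnitude ``interaction_magnitude`` whose sign
        opposes / matches the expected additive effect in every cell.
    ``mixed``
        A deterministic blend of the three classes (the default study
        condition); interactions are 0 or +/- ``interaction_magnitude``.

    Returns the :class:`EffectSpec` and the ground-truth table.  The
    construction is deterministic; ``seed`` is accepted for interface
    symmetry only.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario '{scenario}'; valid scenarios: {', '.join(SCENARIOS)}"
        )
    amps = dict(DEFAULT_UNILATERAL_AMPS, **(unilateral_amps or {}))
    bf = dict(DEFAULT_BAND_FACTORS, **(band_factors or {}))
    bp = dict(DEFAULT_BASE_POWER, **(base_power or {}))
    if not np.isfinite(interaction_magnitude):
        raise ValidationError("interaction_magnitude must be finite")

    rois, bands = list(design.rois), list(BAND_NAMES)
    cell_index = pd.MultiIndex.from_product([rois, bands], names=["roi", "band"])
    n_cells = len(cell_index)
    band_vec = np.array([bf[b] for _, b in cell_index])

    delta: dict[str, np.ndarray] = {}
    for cond in UNILATERAL_CONDITIONS:
        amp = 0.0 if scenario == "null" else amps[cond]
        delta[cond] = amp * band_vec

    inter: dict[str, np.ndarray] = {}
    # Pairs are resolved in schedule order so that combined conditions
    # (bSCC, bVCVS) exist before the multi-target pair consumes them.
    for pair, (a, b, _ab) in PAIRS.items():
        exp = delta[a] + delta[b]
        sgn = np.sign(exp)
        if scenario in ("null", "all_additive"):
            ivals = np.zeros(n_cells)
        elif scenario == "all_sub":
            ivals = -interaction_magnitude * np.where(sgn == 0, 1.0, sgn)
        elif scenario == "all_super":
            ivals = interaction_magnitude * np.where(sgn == 0, 1.0, sgn)
        else:  # mixed
            pat = _mixed_pattern(len(rois), len(bands))
            ivals = interaction_magnitude * pat * np.where(sgn == 0, 1.0, sgn)
        inter[pair] = ivals
        delta[_ab] = exp + ivals

    delta_p_true = pd.concat(
        {c: pd.Series(delta[c], index=cell_index) for c in CONDITIONS},
        names=["condition"],
    )
    interaction_true = pd.concat(
        {p: pd.Series(inter[p], index=cell_index) for p in PAIRS},
        names=["pair"],
    )
    base = pd.Series([bp[b] for _, b in cell_index], index=cell_index)
    effects = EffectSpec(
        delta_p_true=delta_p_true,
        interaction_true=interaction_true,
        base_power=base,
        sd_trial=sd_trial,
        sd_channel=sd_channel,
        sd_residual=sd_residual,
        cm_scale=cm_scale,
    )
    return effects, build_ground_truth(effects)


# ---------------------------------------------------------------------------
# signal-level synthesis
# ---------------------------------------------------------------------------


def _contact_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for roi in design.rois:
        for k in range(design.channels_per_roi):
            rows.append((f"{roi}{k + 1}", roi, hemisphere_of(roi), roi, k + 1))
    return pd.DataFrame(rows, columns=["name", "roi", "hemisphere", "lead", "contact"])


def _schedule(design: StudyDesign, rng) -> pd.DataFrame:
    """Randomly ordered condition schedule with epoch onset times."""
    slots = [
        (cond, rep)
        for cond in design.conditions
        for rep in range(design.trials_per_condition)
    ]
    order = rng.permutation(len(slots))
    period = design.epoch_s + design.gap_s
    rows = []
    for i, j in enumerate(order):
        cond, _rep = slots[j]
        onset = design.gap_s + i * period + design.pre_s  # stimulation onset
        rows.append((onset, cond, f"t{i:03d}"))
    return pd.DataFrame(rows, columns=["onset_s", "condition", "trial"])


def _band_sos(fs: float):
    return {b.name: butter(4, [b.lo, b.hi], btype="bandpass", fs=fs, output="sos") for b in BANDS}


def _channel_intercepts(design: StudyDesign, effects: EffectSpec, seed: int, subject_idx: int) -> np.ndarray:
    """Per-contact random intercepts, shared across a subject's datasets."""
    rng = default_rng(SeedSequence([seed, 2, subject_idx]))
    n = len(design.rois) * design.channels_per_roi
    return rng.standard_normal(n) * effects.sd_channel


def synthesize_session(
    design: StudyDesign,
    effects: EffectSpec,
    subject: str,
    dataset: str,
    seed: int = 0,
) -> RecordingSession:
    """Synthesize one (subject, dataset) recording session.

    Bit-identical for identical arguments.  Raises
    :class:`ValidationError` if any effective relative power change drops
    to or below -1 (power cannot be negative) or if the effect
    specification does not cover the design's ROIs.
    """
    missing = set(design.rois) - set(effects.base_power.index.get_level_values("roi"))
    if missing:
        raise ValidationError(f"effect spec missing ROIs: {sorted(missing)}")
    si = design.subjects.index(subject)
    di = int(dataset.lstrip("d"))
    fs = design.sampling_rate
    rng_sched = default_rng(SeedSequence([seed, 0, si, di]))
    rng_sig = default_rng(SeedSequence([seed, 1, si, di]))
    rng_eff = default_rng(SeedSequence([seed, 3, si, di]))

    events = _schedule(design, rng_sched)
    n_epochs = len(events)
    period = design.epoch_s + design.gap_s
    total_s = design.gap_s + n_epochs * period
    n = int(round(total_s * fs))
    contacts = _contact_table(design)
    n_contacts = len(contacts)

    b_chan = _channel_intercepts(design, effects, seed, si)
    b_trial = rng_eff.standard_normal(n_epochs) * effects.sd_trial
    eps = rng_eff.standard_normal((n_epochs, n_contacts, len(BANDS))) * effects.sd_residual

    # Sample ranges over which the post-onset gain applies (stim + post).
    starts = np.round((events["onset_s"].values) * fs).astype(int)
    ends = np.round((events["onset_s"].values + design.stim_s + design.post_s) * fs).astype(int)

    sos = _band_sos(fs)
    signals = np.zeros((n_contacts, n), dtype=np.float64)
    n_clipped = 0
    for r, roi in enumerate(design.rois):
        rows = np.where(contacts["roi"] == roi)[0]
        # One white-noise stream per contact plus one common-mode stream,
        # filtered per band in a single vectorized call.
        for bi, band in enumerate(BANDS):
            white = rng_sig.standard_normal((len(rows) + 1, n))
            x = sosfiltfilt(sos[band.name], white, axis=-1)
            x /= x.std(axis=-1, keepdims=True)
            amp = np.sqrt(effects.base_power.loc[(roi, band.name)])
            cm = amp * effects.cm_scale * x[-1]
            for j, contact_idx in enumerate(rows):
                gain = np.ones(n)
                for e in range(n_epochs):
                    d_true = effects.delta_p_true.loc[
                        (events["condition"].iloc[e], roi, band.name)
                    ]
                    if 1.0 + d_true <= 0.0:
                        raise ValidationError(
                            f"planted power change {d_true:.3f} <= -1 in "
                            f"({events['condition'].iloc[e]}, {roi}, {band.name}): "
                            "power cannot be negative"
                        )
                    dpe = d_true + b_trial[e] + b_chan[contact_idx] + eps[e, contact_idx, bi]
                    if 1.0 + dpe <= GAIN_FLOOR:
                        # rare Gaussian-tail draw below the physical floor;
                        # power saturates rather than going negative
                        n_clipped += 1
                        dpe = GAIN_FLOOR - 1.0
                    gain[starts[e]:ends[e]] = np.sqrt(1.0 + dpe)
                signals[contact_idx] += amp * x[j] * gain
            signals[rows] += cm
    if n_clipped:
        log.info("clipped %d effective power changes at the positivity floor", n_clipped)
    ev = events.copy()
    ev["subject"] = subject
    ev["dataset"] = dataset
    return RecordingSession(
        signals=signals.astype(np.float32),
        sampling_rate=fs,
        channels=contacts,
        events=ev,
        subject=subject,
        dataset=dataset,
        meta={
            "pre_s": design.pre_s,
            "stim_s": design.stim_s,
            "post_s": design.post_s,
            **PULSE_METADATA,
        },
    )


def synthesize_recording(
    design: StudyDesign, effects: EffectSpec, seed: int = 0
) -> dict[tuple[str, str], RecordingSession]:
    """All sessions of the study, keyed by (subject, dataset)."""
    return {
        (s, d): synthesize_session(design, effects, s, d, seed)
        for s, d in design.datasets
    }


def inject_edge_artifacts(
    session: RecordingSession,
    fraction: float,
    amplitude: float = 8.0,
    seed: int = 0,
) -> tuple[RecordingSession, np.ndarray]:
    """Contaminate a fraction of epochs with onset/offset edge artifacts.

    Exactly ``round(fraction * n_epochs)`` epochs receive tapered
    broadband bursts (``amplitude`` times the channel's standard
    deviation) in the 100 ms windows flanking stimulation onset and
    offset.  Returns the contaminated session and the sorted epoch
    indices that were hit, for screening validation.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    n_epochs = len(session.events)
    k = int(round(fraction * n_epochs))
    rng = default_rng(seed)
    labels = np.sort(rng.choice(n_epochs, size=k, replace=False))
    if k == 0:
        return session, labels
    fs = session.sampling_rate
    stim_s = session.meta.get("stim_s", 1.0)
    w = int(round(0.1 * fs))
    pad = w
    taper = windows.hann(w)
    # A stimulation-edge transient rings across the analysis band; model
    # it as a tapered 15-50 Hz noise burst, unit-rms over the window,
    # scaled to `amplitude` times the channel's standard deviation and
    # drawn independently per contact (so it survives bipolar
    # differencing).
    sos = butter(4, [15.0, 50.0], btype="bandpass", fs=fs, output="sos")
    signals = session.signals.astype(np.float64).copy()
    ch_sd = signals.std(axis=-1)
    for e in labels:
        onset = session.events["onset_s"].iloc[int(e)]
        for t0 in (onset - 0.1, onset + stim_s):
            i0 = int(round(t0 * fs))
            raw = sosfiltfilt(sos, rng.standard_normal((signals.shape[0], w + 2 * pad)), axis=-1)
            burst = raw[:, pad:pad + w] * taper
            burst /= np.sqrt((burst ** 2).mean(axis=-1, keepdims=True))
            signals[:, i0:i0 + w] += amplitude * ch_sd[:, None] * burst
    out = replace(session, signals=signals.astype(np.float32))
    return out, labels


# ---------------------------------------------------------------------------
# statistical-level generation
# ---------------------------------------------------------------------------


def simulate_power_table(design: StudyDesign, effects: EffectSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a band-power table directly from the hierarchical model.

    Emulates the output of the preprocessing + spectral stages (one row
    per epoch x bipolar channel x band) without signal synthesis:
    ``delta_p`` is the planted cell effect plus trial and channel random
    intercepts plus Gaussian residual; ``p_pre`` is the baseline band
    power with mild log-normal jitter and ``p_post`` follows from the
    delta-p identity.
    """
    rng = default_rng(seed)
    conds = list(design.conditions)
    n_s = len(design.subjects)
    n_d = design.datasets_per_subject
    n_t = design.trials_per_condition
    n_e = len(conds) * n_t
    rois, bands = list(design.rois), list(BAND_NAMES)
    n_ch = max(design.channels_per_roi - 1, 1)  # bipolar channels per ROI
    n_roi, n_b = len(rois), len(bands)

    delta_arr = np.array(
        [[[effects.delta_p_true.loc[(c, r, b)] for b in bands] for r in rois] for c in conds]
    )  # (C, R, B)
    base_arr = np.array([[effects.base_power.loc[(r, b)] for b in bands] for r in rois])

    b_trial = rng.standard_normal((n_s, n_d, n_e)) * effects.sd_trial
    b_chan = rng.standard_normal((n_s, n_roi, n_ch)) * effects.sd_channel
    eps = rng.standard_normal((n_s, n_d, n_e, n_roi, n_ch, n_b)) * effects.sd_residual
    jitter = np.exp(rng.standard_normal((n_s, n_d, n_e, n_roi, n_ch, n_b)) * 0.2)

    cond_of_epoch = np.repeat(np.arange(len(conds)), n_t)  # epoch e -> condition index
    dp = (
        delta_arr[cond_of_epoch][None, None, :, :, None, :]
        + b_trial[:, :, :, None, None, None]
        + b_chan[:, None, None, :, :, None]
        + eps
    )
    p_pre = base_arr[None, None, None, :, None, :] * jitter
    p_post = p_pre * (1.0 + dp)

    idx = pd.MultiIndex.from_product(
        [design.subjects, [f"d{d}" for d in range(n_d)], np.arange(n_e), rois,
         np.arange(n_ch), bands],
        names=["subject", "dataset", "epoch", "roi", "chb", "band"],
    )
    df = idx.to_frame(index=False)
    df["condition"] = np.asarray(conds, dtype=object)[cond_of_epoch[df["epoch"].values]]
    df["trial"] = df["epoch"].map(lambda e: f"t{e:03d}")
    df["epoch_id"] = df["subject"] + "/" + df["dataset"] + "/e" + df["epoch"].astype(str)
    df["channel"] = df["subject"] + "/" + df["roi"] + "b" + df["chb"].astype(str)
    df["p_pre"] = p_pre.ravel()
    df["p_post"] = p_post.ravel()
    df["delta_p"] = dp.ravel()
    return df[
        ["epoch_id", "subject", "dataset", "trial", "channel", "roi", "band",
         "condition", "p_pre", "p_post", "delta_p"]
    ]


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(
    sessions: RecordingSession | dict,
    tables: dict[str, pd.DataFrame],
    path: str | Path,
) -> Path:
    """Write sessions + tables to ``path``: HDF5 signals, JSON sidecar, CSVs.

    Round-trips losslessly (float32 signals) through
    :func:`read_fixture`.  Raises on empty sessions rather than writing
    an unusable fixture.
    """
    path = Path(path)
    if isinstance(sessions, RecordingSession):
        sessions = {(sessions.subject, sessions.dataset): sessions}
    if not sessions:
        raise ValidationError("no sessions to write")
    for key, ses in sessions.items():
        if ses.signals.size == 0 or len(ses.channels) == 0:
            raise ValidationError(f"session {key} is empty")
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"sessions": {}}
    with h5py.File(path / "signals.h5", "w") as h5:
        for (subject, dataset), ses in sessions.items():
            key = f"{subject}_{dataset}"
            h5.create_dataset(key, data=ses.signals.astype(np.float32))
            meta["sessions"][key] = {
                "subject": subject,
                "dataset": dataset,
                "sampling_rate_hz": ses.sampling_rate,
                "channels": ses.channels.to_dict(orient="records"),
                "events": ses.events[["onset_s", "condition", "trial"]].to_dict(orient="records"),
                "meta": {k: list(v) if isinstance(v, tuple) else v for k, v in ses.meta.items()},
            }
    first = next(iter(sessions.values()))
    meta["sampling_rate_hz"] = first.sampling_rate
    meta["rois"] = sorted(set(first.channels["roi"]))
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False)
    return path


def read_fixture(path: str | Path) -> tuple[dict[tuple[str, str], RecordingSession], dict[str, pd.DataFrame]]:
    """Read a fixture written by :func:`write_fixture`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    sessions: dict[tuple[str, str], RecordingSession] = {}
    with h5py.File(path / "signals.h5", "r") as h5:
        for key, m in meta["sessions"].items():
            events = pd.DataFrame(m["events"])
            events["subject"] = m["subject"]
            events["dataset"] = m["dataset"]
            smeta = dict(m["meta"])
            if "pulse_width_us" in smeta:
                smeta["pulse_width_us"] = tuple(smeta["pulse_width_us"])
            sessions[(m["subject"], m["dataset"])] = RecordingSession(
                signals=h5[key][()],
                sampling_rate=m["sampling_rate_hz"],
                channels=pd.DataFrame(m["channels"]),
                events=events,
                subject=m["subject"],
                dataset=m["dataset"],
                meta=smeta,
            )
    tables = {p.stem: pd.read_csv(p) for p in sorted(path.glob("*.csv"))}
    return sessions, tables
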