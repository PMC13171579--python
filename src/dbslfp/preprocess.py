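"""Preprocessing: bipolar re-referencing, decimation and epoch segmentation.

Monopolar depth-electrode recordings are re-referenced to the adjacent
contact on the same lead (only when both contacts sit in the same ROI),
low-pass filtered and downsampled to the 1 kHz working rate, and cut
into 3 s epochs (1 s pre-stimulation, 1 s stimulation, 1 s
post-stimulation) around each stimulation onset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import decimate as _scipy_decimate
from scipy.signal import resample_poly

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecordingSession:
    """One recording session: channel x time voltages plus metadata.

    ``channels`` has columns name, roi, hemisphere, lead, contact;
    ``events`` has onset_s (stimulation onset, seconds), condition,
    trial, subject, dataset.
    """

    signals: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channels: pd.DataFrame
    events: pd.DataFrame
    subject: str = ""
    dataset: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a (channels, samples) matrix")
        if self.signals.shape[0] != len(self.channels):
            raise ValidationError("channel metadata does not match signal matrix")
        if not self.events["onset_s"].is_monotonic_increasing:
            object.__setattr__(self, "events", self.events.sort_values("onset_s").reset_index(drop=True))

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class EpochSet:
    """Segmented epochs: (n_epochs, n_channels, n_samples) at the working rate."""

    epochs: np.ndarray
    sampling_rate: float
    channels: pd.DataFrame
    manifest: pd.DataFrame  # epoch_id, subject, dataset, trial, condition
    pre_s: float = 1.0
    stim_s: float = 1.0
    post_s: float = 1.0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bipolar_rereference(session: RecordingSession) -> RecordingSession:
    """Difference adjacent same-lead, same-ROI contacts.

    Output channel k is input contact k minus contact k+1
    (deeper-minus-shallower); adjacent pairs spanning two ROIs are
    dropped.  A lead that yields no valid pair contributes no channels
    and triggers a warning.  Any signal common to all contacts of a lead
    cancels exactly.
    """
    chans = session.channels
    out_sig, out_meta = [], []
    for lead, grp in chans.groupby("lead", sort=False):
        grp = grp.sort_values("contact")
        idx = grp.index.to_numpy()
        made = 0
        for a, b in zip(idx[:-1], idx[1:]):
            if chans.loc[a, "contact"] + 1 != chans.loc[b, "contact"]:
                continue
            if chans.loc[a, "roi"] != chans.loc[b, "roi"]:
                continue
            ia, ib = chans.index.get_loc(a), chans.index.get_loc(b)
            out_sig.append(session.signals[ia] - session.signals[ib])
            out_meta.append(
                (
                    f"{chans.loc[a, 'name']}-{chans.loc[b, 'name']}",
                    chans.loc[a, "roi"],
                    chans.loc[a, "hemisphere"],
                    lead,
                    chans.loc[a, "contact"],
                )
            )
            made += 1
        if made == 0:
            warnings.warn(f"lead '{lead}' has no same-ROI adjacent contact pair; dropped", stacklevel=2)
    signals = np.asarray(out_sig) if out_sig else np.empty((0, session.signals.shape[1]))
    channels = pd.DataFrame(out_meta, columns=["name", "roi", "hemisphere", "lead", "contact"])
    return RecordingSession(
        signals=signals,
        sampling_rate=session.sampling_rate,
        channels=channels,
        events=session.events,
        subject=session.subject,
        dataset=session.dataset,
        meta=session.meta,
    )


def decimate(session: RecordingSession, target_rate: float) -> RecordingSession:
    """Anti-aliased downsampling to ``target_rate``.

    Integer ratios use a zero-phase FIR low-pass (flat passband, so
    sub-100 Hz amplitudes survive to well under 1%) before integer
    downsampling; non-integer ratios fall back to polyphase resampling.
    Event onsets are stored in seconds and are unaffected.
    """
    fs = session.sampling_rate
    if target_rate > fs:
        raise ValidationError(f"target_rate {target_rate} exceeds sampling rate {fs}")
    if target_rate == fs:
        return session
    ratio = fs / target_rate
    x = session.signals.astype(np.float64)
    if abs(ratio - round(ratio)) < 1e-9:
        x = _scipy_decimate(x, int(round(ratio)), ftype="fir", zero_phase=True, axis=-1)
    else:
        frac = Fraction(target_rate / fs).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return RecordingSession(
        signals=x,
        sampling_rate=target_rate,
        channels=session.channels,
        events=session.events,
        subject=session.subject,
        dataset=session.dataset,
        meta=session.meta,
    )


def segment_epochs(session: RecordingSession) -> EpochSet:
    """Cut one 3 s epoch (pre | stim | post) per stimulation event.

    Events whose epoch would extend past either end of the recording are
    skipped with a logged reason, never zero-padded.
    """
    fs = session.sampling_rate
    pre = session.meta.get("pre_s", 1.0)
    stim = session.meta.get("stim_s", 1.0)
    post = session.meta.get("post_s", 1.0)
    n_samp = int(round((pre + stim + post) * fs))
    n_total = session.signals.shape[1]
    epochs, rows = [], []
    for i, ev in session.events.reset_index(drop=True).iterrows():
        i0 = int(round((ev["onset_s"] - pre) * fs))
        if i0 < 0 or i0 + n_samp > n_total:
            log.info("skipping event %d at t=%.3fs: epoch outside recording", i, ev["onset_s"])
            continue
        epochs.append(session.signals[:, i0:i0 + n_samp])
        rows.append(
            (
                f"{ev.get('subject', session.subject)}/{ev.get('dataset', session.dataset)}/e{i}",
                ev.get("subject", session.subject),
                ev.get("dataset", session.dataset),
                ev.get("trial", f"t{i:03d}"),
                ev["condition"],
            )
        )
    arr = (
        np.asarray(epochs)
        if epochs
        else np.empty((0, session.signals.shape[0], n_samp))
    )
    manifest = pd.DataFrame(rows, columns=["epoch_id", "subject", "dataset", "trial", "condition"])
    return EpochSet(
        epochs=arr,
        sampling_rate=fs,
        channels=session.channels,
        manifest=manifest,
        pre_s=pre,
        stim_s=stim,
        post_s=post,
    )


def preprocess_session(session: RecordingSession, target_rate: float = 1000.0) -> EpochSet:
    """Bipolar re-reference, decimate, segment: the standard chain."""
    return segment_epochs(decimate(bipolar_rereference(session), target_rate))
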