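"""Study design: subjects, datasets, trials, channels, ROIs and the condition schedule.

The design mirrors a multi-site deep-brain-stimulation experiment: depth
electrodes record local field potentials from twelve regions of interest
(six anatomical labels x two hemispheres) while seven stimulation
conditions -- four unilateral targets, two bilateral single-target
combinations and one bilateral multi-target combination -- are delivered
in one-second bursts, repeated several times per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

#: The six anatomical labels, left and right hemisphere.
ROIS: tuple[str, ...] = (
    "lACC", "rACC",
    "lmPFC", "rmPFC",
    "lOFC", "rOFC",
    "lDLPFC", "rDLPFC",
    "lAmyHC", "rAmyHC",
    "lTL", "rTL",
)

#: The seven stimulation conditions: right/left subcallosal cingulate (SCC),
#: right/left ventral capsule/ventral striatum (VCVS), bilateral SCC,
#: bilateral VCVS, and simultaneous bilateral SCC + VCVS ("ALL").
CONDITIONS: tuple[str, ...] = ("rSCC", "lSCC", "rVCVS", "lVCVS", "bSCC", "bVCVS", "ALL")

UNILATERAL_CONDITIONS: tuple[str, ...] = ("rSCC", "lSCC", "rVCVS", "lVCVS")

#: The three combination pairs analysed for additivity: each maps a pair
#: name to (condition A, condition B, combined condition AB).
PAIRS: dict[str, tuple[str, str, str]] = {
    "SCC_bilateral": ("rSCC", "lSCC", "bSCC"),
    "VCVS_bilateral": ("rVCVS", "lVCVS", "bVCVS"),
    "multi_target": ("bSCC", "bVCVS", "ALL"),
}

#: Stimulation pulse settings carried as fixture metadata only; the pulse
#: waveform itself is never synthesized because the analysis compares the
#: pre- and post-stimulation windows and discards the stimulation window.
PULSE_METADATA = {"pulse_rate_hz": 130, "pulse_width_us": (90, 180)}


def hemisphere_of(roi: str) -> str:
    """'l...' -> 'left', 'r...' -> 'right'."""
    return {"l": "left", "r": "right"}[roi[0]]


@dataclass(frozen=True)
class StudyDesign:
    """Immutable description of the recording/stimulation schedule.

    Parameters
    ----------
    subjects : tuple of str
        Subject identifiers.
    datasets_per_subject : int
        Number of recording sessions (datasets) per subject.
    trials_per_condition : int
        One-second stimulation repetitions of each condition per dataset.
    rois : tuple of str
        Region-of-interest labels; each recording channel maps to exactly
        one ROI.
    channels_per_roi : int
        Monopolar contacts implanted per ROI (one lead per ROI).
    conditions : tuple of str
        Stimulation condition codes; all seven must be present.
    sampling_rate : float
        Synthesis sampling rate in Hz.
    pre_s, stim_s, post_s : float
        Epoch layout in seconds (pre-stimulation, stimulation,
        post-stimulation).
    gap_s : float
        Quiet gap between consecutive epochs in the synthesized timeline.
    """

    subjects: tuple[str, ...]
    datasets_per_subject: int = 2
    trials_per_condition: int = 10
    rois: tuple[str, ...] = ROIS
    channels_per_roi: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    sampling_rate: float = 2000.0
    pre_s: float = 1.0
    stim_s: float = 1.0
    post_s: float = 1.0
    gap_s: float = 0.5

    def __post_init__(self):
        if len(self.subjects) < 1:
            raise ConfigurationError("design needs at least one subject")
        if self.trials_per_condition < 1:
            raise ConfigurationError("trials_per_condition must be >= 1")
        if self.channels_per_roi < 1:
            raise ConfigurationError("channels_per_roi must be >= 1")
        if self.datasets_per_subject < 1:
            raise ConfigurationError("datasets_per_subject must be >= 1")
        if set(CONDITIONS) - set(self.conditions):
            missing = sorted(set(CONDITIONS) - set(self.conditions))
            raise ConfigurationError(f"all 7 conditions required; missing {missing}")
        # The analysis grid tops out at 50 Hz; synthesis must resolve it.
        if self.sampling_rate < 2 * 55.0:
            raise ConfigurationError("sampling_rate must exceed twice the highest analysis frequency")

    @property
    def epoch_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def epochs_per_dataset(self) -> int:
        return len(self.conditions) * self.trials_per_condition

    @property
    def datasets(self) -> list[tuple[str, str]]:
        return [
            (s, f"d{d}")
            for s in self.subjects
            for d in range(self.datasets_per_subject)
        ]


_REQUIRED = ("subjects", "trials_per_condition", "channels_per_roi")


def make_design(config: dict, seed: int = 0) -> StudyDesign:
    """Build a :class:`StudyDesign` from a configuration mapping.

    ``subjects`` may be an integer count (ids are generated as ``S01``,
    ``S02``, ...) or an explicit list of ids.  The design skeleton is a
    deterministic function of the configuration alone; ``seed`` is
    accepted for interface symmetry but randomness only enters later, in
    signal synthesis.
    """
    for key in _REQUIRED:
        if key not in config:
            raise ConfigurationError(f"missing required design field: '{key}'")
    subjects = config["subjects"]
    if isinstance(subjects, int):
        if subjects < 1:
            raise ConfigurationError("subjects count must be >= 1")
        subjects = tuple(f"S{i + 1:02d}" for i in range(subjects))
    else:
        subjects = tuple(subjects)
    kwargs = {
        k: config[k]
        for k in (
            "datasets_per_subject", "trials_per_condition", "rois",
            "channels_per_roi", "sampling_rate", "pre_s", "stim_s",
            "post_s", "gap_s",
        )
        if k in config
    }
    if "rois" in kwargs:
        kwargs["rois"] = tuple(kwargs["rois"])
    return StudyDesign(subjects=subjects, **kwargs)
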