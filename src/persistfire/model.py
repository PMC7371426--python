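"""Domain types: stimulus protocols, sweeps, cells, EMG trials, sessions.

Unit conventions (used everywhere in the package):
time in seconds (0-based from sweep start), voltage in mV, current in pA
(2 nA pulses are stored as 2000 pA), rates in Hz / spikes per second.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

GROUPS = ("YN", "AN", "YC", "YP", "AU", "AI", "other")
CONDITIONS = ("baseline", "carbachol", "carbachol_plus_blocker")
TRIAL_TYPES = ("paired", "cs_alone", "us_alone")
PARADIGMS = ("conditioned", "pseudoconditioned")

FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class StimulusProtocol:
    """One stimulation design. ``kind`` selects which fields are meaningful.

    - ``step``: ``step_amplitude_pA`` for ``step_duration_s``.
    - ``pulse_train``: pulses of ``pulse_amplitude_nA`` / ``pulse_width_ms``
      at ``pulse_frequency_hz`` for ``train_duration_s``.
    - ``ahp_burst``: ``n_pulses`` pulses at ``pulse_frequency_hz`` from an
      absolute holding potential.

    ``holding_offset_mV`` is the amount *below* the cell's spontaneous firing
    threshold at which the membrane is held; 0 means ``absolute_holding_mV``
    applies instead.
    """

    name: str
    kind: str  # step | pulse_train | ahp_burst
    stim_onset_s: float = 1.0
    step_amplitude_pA: float = 0.0
    step_duration_s: float = 0.0
    pulse_amplitude_nA: float = 0.0
    pulse_width_ms: float = 0.0
    pulse_frequency_hz: float = 0.0
    train_duration_s: float = 0.0
    n_pulses: int = 0
    holding_offset_mV: float = 0.0
    absolute_holding_mV: Optional[float] = None
    n_repeats: int = 3

    def __post_init__(self):
        if self.kind not in ("step", "pulse_train", "ahp_burst"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "pulse_train":
            if self.pulse_width_ms <= 0 or self.pulse_frequency_hz <= 0:
                raise ValueError("pulse protocols need positive width and frequency")
            if self.train_duration_s <= 0:
                raise ValueError("pulse protocols need positive train duration")
        if self.kind == "ahp_burst" and self.n_pulses <= 0:
            raise ValueError("ahp_burst needs n_pulses > 0")

    @property
    def stim_duration_s(self) -> float:
        if self.kind == "step":
            return self.step_duration_s
        if self.kind == "pulse_train":
            return self.train_duration_s
        # burst: last pulse starts at (n-1)/f and lasts pulse_width
        return (self.n_pulses - 1) / self.pulse_frequency_hz + self.pulse_width_ms / 1e3

    @property
    def stim_offset_s(self) -> float:
        """Time of stimulus end, from sweep start."""
        return self.stim_onset_s + self.stim_duration_s

    def pulse_onsets_s(self) -> np.ndarray:
        """Start times of individual pulses (pulse_train / ahp_burst)."""
        if self.kind == "step":
            return np.array([self.stim_onset_s])
        if self.kind == "ahp_burst":
            n = self.n_pulses
        else:
            n = int(round(self.train_duration_s * self.pulse_frequency_hz))
        return self.stim_onset_s + np.arange(n) / self.pulse_frequency_hz

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "stim_onset_s": self.stim_onset_s,
            "step_amplitude_pA": self.step_amplitude_pA,
            "step_duration_s": self.step_duration_s,
            "pulse_amplitude_nA": self.pulse_amplitude_nA,
            "pulse_width_ms": self.pulse_width_ms,
            "pulse_frequency_hz": self.pulse_frequency_hz,
            "train_duration_s": self.train_duration_s,
            "n_pulses": self.n_pulses,
            "holding_offset_mV": self.holding_offset_mV,
            "absolute_holding_mV": self.absolute_holding_mV,
            "n_repeats": self.n_repeats,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


def standard_protocols() -> dict:
    """The study's stimulation designs, keyed by CLI-facing names."""
    protos = {}
    for amp in (100, 150, 200):
        protos[f"step{amp}"] = StimulusProtocol(
            name=f"step{amp}", kind="step", step_amplitude_pA=float(amp),
            step_duration_s=2.0, holding_offset_mV=2.0)
    protos["train20hz_2s"] = StimulusProtocol(
        name="train20hz_2s", kind="pulse_train", pulse_amplitude_nA=2.0,
        pulse_width_ms=2.0, pulse_frequency_hz=20.0, train_duration_s=2.0,
        holding_offset_mV=2.0)
    for off in (2, 5):
        protos[f"train20hz_250ms_{off}mv"] = StimulusProtocol(
            name=f"train20hz_250ms_{off}mv", kind="pulse_train",
            pulse_amplitude_nA=2.0, pulse_width_ms=2.0, pulse_frequency_hz=20.0,
            train_duration_s=0.25, holding_offset_mV=float(off))
    protos["adp_10mv"] = StimulusProtocol(
        name="adp_10mv", kind="pulse_train", pulse_amplitude_nA=2.0,
        pulse_width_ms=2.0, pulse_frequency_hz=20.0, train_duration_s=0.25,
        holding_offset_mV=10.0)
    protos["ahp_burst"] = StimulusProtocol(
        name="ahp_burst", kind="ahp_burst", stim_onset_s=0.5,
        pulse_amplitude_nA=2.0, pulse_width_ms=2.0, pulse_frequency_hz=50.0,
        n_pulses=15, holding_offset_mV=0.0, absolute_holding_mV=-69.0,
        n_repeats=5)
    return protos


PERSISTENCE_PROTOCOLS = (
    "step100", "step150", "step200",
    "train20hz_2s", "train20hz_250ms_2mv", "train20hz_250ms_5mv",
)


@dataclass
class Sweep:
    """One episodic current-clamp recording epoch."""

    sample_rate_hz: float
    voltage_mV: np.ndarray
    command_current_pA: np.ndarray
    protocol: StimulusProtocol
    sweep_index: int
    duration_s: float
    holding_mV: Optional[float] = None

    def __post_init__(self):
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.command_current_pA = np.asarray(self.command_current_pA, dtype=float)
        n = int(round(self.sample_rate_hz * self.duration_s))
        if len(self.voltage_mV) != n or len(self.command_current_pA) != n:
            from .errors import SeriesLengthMismatchError
            raise SeriesLengthMismatchError(
                f"series length {len(self.voltage_mV)}/{len(self.command_current_pA)} "
                f"!= round(rate*duration) = {n}")
        if self.protocol.stim_offset_s >= self.duration_s:
            raise ValueError("stimulus extends past end of sweep")

    @property
    def n_samples(self) -> int:
        return len(self.voltage_mV)

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class CellQC:
    """Inclusion criteria for a recorded cell.

    passes is true iff RMP in [-80, -50] mV (closed interval), input
    resistance strictly > 25 MOhm, and max AP height >= 70 mV above holding.
    """

    resting_potential_mV: float
    input_resistance_MOhm: float
    max_ap_height_above_holding_mV: float

    @property
    def passes(self) -> bool:
        return (
            -80.0 <= self.resting_potential_mV <= -50.0
            and self.input_resistance_MOhm > 25.0
            and self.max_ap_height_above_holding_mV >= 70.0
        )

    def to_dict(self) -> dict:
        return {
            "resting_potential_mV": self.resting_potential_mV,
            "input_resistance_MOhm": self.input_resistance_MOhm,
            "max_ap_height_above_holding_mV": self.max_ap_height_above_holding_mV,
            "passes": self.passes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellQC":
        return cls(
            resting_potential_mV=d["resting_potential_mV"],
            input_resistance_MOhm=d["input_resistance_MOhm"],
            max_ap_height_above_holding_mV=d["max_ap_height_above_holding_mV"],
        )


@dataclass
class CellRecord:
    """One recorded neuron with sweeps grouped by protocol name."""

    cell_id: str
    group: str
    spontaneous_threshold_mV: float
    resting_potential_mV: float
    condition: str = "carbachol"
    sweeps: dict = field(default_factory=dict)  # protocol name -> list[Sweep]
    qc: Optional[CellQC] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.spontaneous_threshold_mV > self.resting_potential_mV:
            raise ValueError("spontaneous threshold must exceed resting potential")

    def holding_for(self, protocol: StimulusProtocol) -> float:
        if protocol.holding_offset_mV:
            return self.spontaneous_threshold_mV - protocol.holding_offset_mV
        if protocol.absolute_holding_mV is None:
            raise ValueError("protocol has neither holding offset nor absolute holding")
        return protocol.absolute_holding_mV


@dataclass
class EMGTrial:
    """One rectified-EMG trial with CS/US timing metadata."""

    sample_rate_hz: float
    emg: np.ndarray
    cs_onset_s: float
    trial_type: str = "paired"
    cs_duration_s: float = 0.250
    trace_duration_s: float = 0.500
    us_onset_s: Optional[float] = None

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.us_onset_s is None:
            # derived US reference also applies to cs_alone trials
            self.us_onset_s = self.cs_onset_s + self.cs_duration_s + self.trace_duration_s

    @property
    def duration_s(self) -> float:
        return len(self.emg) / self.sample_rate_hz


@dataclass
class Session:
    """One behavioral session (habituation = index 0, training 1..5)."""

    session_index: int
    trials: list
    paradigm: str = "conditioned"

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")


@dataclass
class Animal:
    """One behavioral subject and its sessions."""

    animal_id: str
    group: str
    paradigm: str
    sessions: list = field(default_factory=list)


@dataclass
class Cohort:
    """A full dataset: recorded cells plus behavioral animals."""

    cells: list = field(default_factory=list)
    animals: list = field(default_factory=list)
    format_version: str = FORMAT_VERSION


__all__ = [
    "StimulusProtocol", "Sweep", "CellQC", "CellRecord", "EMGTrial",
    "Session", "Animal", "Cohort", "standard_protocols",
    "PERSISTENCE_PROTOCOLS", "GROUPS", "FORMAT_VERSION", "replace",
]
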