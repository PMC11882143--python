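"""Core data containers for self-paced mating behavior and calcium imaging.

All times are seconds from the start of the recording. Zone occupancy is a
regularly sampled two-state sequence (interaction / isolation); fluorescence
traces are cells x samples matrices at 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Closed set of annotated behaviors.
BEHAVIORS = ("sniff", "self_groom", "ano_sniff", "mount", "intromission", "ejaculation")

#: Behaviors that require the female to be in the interaction zone at onset.
CONSUMMATORY = ("mount", "intromission", "ejaculation")

INTERACTION = "interaction"
ISOLATION = "isolation"
ZONES = (INTERACTION, ISOLATION)

#: Planted response classes for simulated cells.
RESPONSE_CLASSES = ("fast", "slow", "late", "weak", "negative", "nonresponder")

CELL_TYPES = ("Vgat", "Vglut2")


class InvalidParameterError(ValueError):
    """Raised when generator or analysis parameters violate their contracts."""


class InvalidEpochError(ValueError):
    """Raised for empty or out-of-range analysis epochs."""


@dataclass(frozen=True)
class BehaviorEvent:
    """One annotated behavioral episode."""

    behavior: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise InvalidParameterError(f"unknown behavior label {self.behavior!r}")
        if not self.onset_s < self.offset_s:
            raise InvalidParameterError(
                f"event onset {self.onset_s} must precede offset {self.offset_s}"
            )


@dataclass
class Ethogram:
    """Timestamped behavioral record of one mating session.

    Events are kept sorted by onset; at most one ejaculation event is
    allowed (the assay ends shortly after ejaculation).
    """

    session_id: str
    duration_s: float
    events: list[BehaviorEvent] = field(default_factory=list)
    male_entry_s: float = 0.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        n_ej = sum(e.behavior == "ejaculation" for e in self.events)
        if n_ej > 1:
            raise InvalidParameterError(f"{n_ej} ejaculation events; at most one allowed")

    def of(self, behavior: str) -> list[BehaviorEvent]:
        return [e for e in self.events if e.behavior == behavior]

    @property
    def ejaculation_time_s(self) -> Optional[float]:
        ej = self.of("ejaculation")
        return ej[0].onset_s if ej else None


@dataclass
class ZoneTrack:
    """Regularly sampled zone occupancy of the female subject.

    ``zones[k]`` is the zone at time ``k / frame_rate``. ``male_entry_s``
    and ``ejaculation_s`` mark the epoch boundaries (control / pre / post).
    """

    session_id: str
    frame_rate: float
    zones: np.ndarray  # dtype '<U11', values in ZONES
    male_entry_s: float = 0.0
    ejaculation_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones)
        bad = set(np.unique(self.zones)) - set(ZONES)
        if bad:
            raise InvalidParameterError(f"unknown zone labels: {sorted(bad)}")

    @property
    def duration_s(self) -> float:
        return len(self.zones) / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.zones)) / self.frame_rate


@dataclass(frozen=True)
class EpochSpec:
    """Half-open analysis epoch [start_s, end_s)."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise InvalidEpochError(
                f"epoch {self.name!r}: start {self.start_s} must precede end {self.end_s}"
            )

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def default_epochs(etho: Ethogram) -> dict[str, EpochSpec]:
    """Pre/post epochs around ejaculation (pre = [male entry, ejaculation),
    post = [ejaculation, session end)); a session without ejaculation yields
    a single 'control' epoch spanning the full record."""
    ej = etho.ejaculation_time_s
    if ej is None:
        return {"control": EpochSpec("control", 0.0, etho.duration_s)}
    return {
        "pre": EpochSpec("pre", etho.male_entry_s, ej),
        "post": EpochSpec("post", ej, etho.duration_s),
    }


@dataclass
class TraceMatrix:
    """Cells x samples fluorescence at 10 Hz with per-cell metadata."""

    cell_ids: list[str]
    cell_types: list[str]
    animal_ids: list[str]
    values: np.ndarray  # (n_cells, n_samples)
    frame_rate: float = 10.0
    background_window: tuple[float, float] = (0.0, 60.0)
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if not (len(self.cell_ids) == len(self.cell_types) == len(self.animal_ids) == n):
            raise InvalidParameterError("cell metadata lengths must match trace rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def background_slice(self) -> slice:
        lo = int(round(self.background_window[0] * self.frame_rate))
        hi = int(round(self.background_window[1] * self.frame_rate))
        return slice(lo, hi)


@dataclass(frozen=True)
class SessionParams:
    """Generative parameters of one self-paced mating session.

    Rates are events per minute; dwell parameters are the mean holding
    times (seconds) of the two-state zone-occupancy Markov process before
    and after ejaculation. ``ejaculation_time_s=None`` simulates a control
    trial without a male ejaculation.
    """

    duration_s: float = 3600.0
    male_entry_s: float = 300.0
    sniff_rate_pre: float = 2.0
    sniff_rate_post: float = 2.0
    mount_rate_pre: float = 1.0
    mount_rate_post: float = 0.1
    p_intromission: float = 0.7
    groom_rate_pre: float = 0.5
    groom_rate_post: float = 1.0
    ano_sniff_rate_pre: float = 0.5
    ano_sniff_rate_post: float = 0.5
    ejaculation_time_s: Optional[float] = 2100.0
    zone_dwell_interaction_pre: float = 240.0
    zone_dwell_isolation_pre: float = 40.0
    zone_dwell_interaction_post: float = 60.0
    zone_dwell_isolation_post: float = 300.0
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        rates = (
            self.sniff_rate_pre, self.sniff_rate_post,
            self.mount_rate_pre, self.mount_rate_post,
            self.groom_rate_pre, self.groom_rate_post,
            self.ano_sniff_rate_pre, self.ano_sniff_rate_post,
        )
        if any(r < 0 for r in rates):
            raise InvalidParameterError("behavior rates must be >= 0")
        dwells = (
            self.zone_dwell_interaction_pre, self.zone_dwell_isolation_pre,
            self.zone_dwell_interaction_post, self.zone_dwell_isolation_post,
        )
        if any(d <= 0 for d in dwells):
            raise InvalidParameterError("zone dwell means must be > 0")
        if not 0.0 <= self.p_intromission <= 1.0:
            raise InvalidParameterError("p_intromission must be in [0, 1]")
        if self.ejaculation_time_s is not None:
            if not self.male_entry_s < self.ejaculation_time_s < self.duration_s:
                raise InvalidParameterError(
                    "ejaculation_time_s must lie between male entry and session end"
                )
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.male_entry_s < 60.0:
            raise InvalidParameterError(
                "male_entry_s must leave >= 60 s of pre-entry background"
            )


@dataclass(frozen=True)
class ClassKinetics:
    """Transient kinetics of one planted response class (GCaMP6s-like)."""

    amplitude: float  # z-units; negative for suppressed responses
    rise_tau_s: float
    decay_tau_s: float
    onset_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidParameterError("kinetic time constants must be > 0")
        if self.decay_tau_s <= self.rise_tau_s:
            raise InvalidParameterError("decay_tau_s must exceed rise_tau_s")


# GCaMP6s-like defaults mirroring the observed temporal phenotypes: a brief
# transient (fast), a sustained response (slow), a delayed ramp (late), a
# small brief response (weak), and a suppression (negative).
DEFAULT_KINETICS: dict[str, ClassKinetics] = {
    "fast": ClassKinetics(amplitude=6.0, rise_tau_s=0.6, decay_tau_s=8.0),
    "slow": ClassKinetics(amplitude=5.0, rise_tau_s=3.0, decay_tau_s=45.0),
    "late": ClassKinetics(amplitude=5.0, rise_tau_s=8.0, decay_tau_s=35.0,
                          onset_delay_s=40.0),
    "weak": ClassKinetics(amplitude=2.5, rise_tau_s=0.6, decay_tau_s=4.0),
    "negative": ClassKinetics(amplitude=-3.0, rise_tau_s=2.0, decay_tau_s=30.0),
}


def _default_counts() -> dict[tuple[str, str], int]:
    # Class x cell-type composition loosely mirroring the recorded
    # population: mostly inhibitory cells, late responders all inhibitory.
    return {
        ("fast", "Vgat"): 26, ("fast", "Vglut2"): 16,
        ("slow", "Vgat"): 33, ("slow", "Vglut2"): 1,
        ("late", "Vgat"): 37, ("late", "Vglut2"): 0,
        ("weak", "Vgat"): 47, ("weak", "Vglut2"): 13,
        ("negative", "Vgat"): 41, ("negative", "Vglut2"): 5,
        ("nonresponder", "Vgat"): 338, ("nonresponder", "Vglut2"): 236,
    }


@dataclass
class CellSpec:
    """Composition and kinetics of a simulated cell population."""

    n_cells_per_class: Mapping[tuple[str, str], int] = field(default_factory=_default_counts)
    kinetics: Mapping[str, ClassKinetics] = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    noise_sd: float = 0.5
    coupled_behaviors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {c: ("ejaculation",) for c in RESPONSE_CLASSES if c != "nonresponder"}
    )
    n_animals: Mapping[str, int] = field(default_factory=lambda: {"Vgat": 6, "Vglut2": 4})

    def __post_init__(self) -> None:
        for (cls, ct), n in self.n_cells_per_class.items():
            if cls not in RESPONSE_CLASSES:
                raise InvalidParameterError(f"unknown response class {cls!r}")
            if ct not in CELL_TYPES:
                raise InvalidParameterError(f"unknown cell type {ct!r}")
            if n < 0:
                raise InvalidParameterError("cell counts must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for cls in {c for c, _ in self.n_cells_per_class if c != "nonresponder"}:
            if self.n_cells_per_class.get((cls, "Vgat"), 0) + self.n_cells_per_class.get(
                (cls, "Vglut2"), 0
            ) > 0 and cls not in self.kinetics:
                raise InvalidParameterError(f"no kinetics given for class {cls!r}")
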