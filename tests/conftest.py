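import numpy as np
import pytest

from pacedmating.types import CellSpec, ClassKinetics, Ethogram, SessionParams, ZoneTrack


@pytest.fixture(scope="session")
def short_params() -> SessionParams:
    """A 10-minute session: 2 min background, ejaculation at 7 min."""
    return SessionParams(duration_s=600.0, male_entry_s=120.0, ejaculation_time_s=420.0)


@pytest.fixture(scope="session")
def five_class_spec() -> CellSpec:
    """Five planted temporal classes, 40 cells each, amplitudes >= 4 z-units."""
    kinetics = {
        "fast": ClassKinetics(amplitude=6.0, rise_tau_s=0.6, decay_tau_s=8.0),
        "slow": ClassKinetics(amplitude=5.0, rise_tau_s=3.0, decay_tau_s=45.0),
        "late": ClassKinetics(amplitude=5.0, rise_tau_s=8.0, decay_tau_s=35.0,
                              onset_delay_s=40.0),
        "weak": ClassKinetics(amplitude=4.0, rise_tau_s=0.6, decay_tau_s=4.0),
        "negative": ClassKinetics(amplitude=-4.0, rise_tau_s=2.0, decay_tau_s=30.0),
    }
    counts = {}
    for cls in ("fast", "slow", "late", "weak", "negative"):
        counts[(cls, "Vgat")] = 32
        counts[(cls, "Vglut2")] = 8
    return CellSpec(n_cells_per_class=counts, kinetics=kinetics, noise_sd=0.5)


def make_zone_track(zones, frame_rate=1.0, **kwargs) -> ZoneTrack:
    mapping = {"I": "interaction", "S": "isolation"}
    zones = [mapping.get(z, z) for z in zones]
    return ZoneTrack(session_id="t", frame_rate=frame_rate,
                     zones=np.array(zones), **kwargs)


def make_ethogram(events, duration_s=1000.0, male_entry_s=0.0) -> Ethogram:
    from pacedmating.types import BehaviorEvent

    return Ethogram(
        session_id="t",
        duration_s=duration_s,
        events=[BehaviorEvent(*e) for e in events],
        male_entry_s=male_entry_s,
    )
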