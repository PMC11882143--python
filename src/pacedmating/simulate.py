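"""Synthetic self-paced mating sessions with planted ground truth.

Generates (i) ethograms and zone-occupancy tracks from a two-state Markov
process whose switching statistics change after male ejaculation, (ii)
GCaMP6s-like fluorescence traces with planted per-cell response classes,
and (iii) hierarchical region-count tables with planted group effects.
Every generator is deterministic under a fixed seed, so downstream metrics
can be checked against closed-form oracles and planted labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CONSUMMATORY,
    INTERACTION,
    ISOLATION,
    BehaviorEvent,
    CellSpec,
    Ethogram,
    InvalidParameterError,
    SessionParams,
    TraceMatrix,
    ZoneTrack,
)

# Episode durations (s), drawn uniformly from these ranges.
_DURATIONS = {
    "sniff": (1.0, 3.0),
    "ano_sniff": (1.0, 3.0),
    "self_groom": (3.0, 8.0),
    "mount": (5.0, 12.0),
}
_EJACULATION_DURATION_S = 10.0


def calcium_kernel(
    t: np.ndarray, amplitude: float, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to ``amplitude``.

    k(t) = A * (exp(-t/tau_d) - exp(-t/tau_r)) / k_max for t >= 0, 0 before.
    The peak time is analytic, t* = tau_r*tau_d/(tau_d-tau_r)*ln(tau_d/tau_r),
    which keeps the kernel integrable in closed form for test oracles.
    """
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau_s * decay_tau_s / (decay_tau_s - rise_tau_s) * np.log(
        decay_tau_s / rise_tau_s
    )
    peak = np.exp(-t_peak / decay_tau_s) - np.exp(-t_peak / rise_tau_s)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (
        amplitude * (np.exp(-t[pos] / decay_tau_s) - np.exp(-t[pos] / rise_tau_s)) / peak
    )
    return out


def _markov_segments(
    rng: np.random.Generator,
    start_s: float,
    end_s: float,
    dwell_interaction: float,
    dwell_isolation: float,
    start_zone: Optional[str] = None,
) -> list[tuple[str, float, float]]:
    """Alternating-renewal occupancy segments on [start_s, end_s).

    Holding times are exponential with the given means. If ``start_zone`` is
    None the initial state is drawn from the stationary distribution.
    """
    dwell = {INTERACTION: dwell_interaction, ISOLATION: dwell_isolation}
    if start_zone is None:
        p_iso = dwell_isolation / (dwell_interaction + dwell_isolation)
        zone = ISOLATION if rng.random() < p_iso else INTERACTION
    else:
        zone = start_zone
    segments = []
    t = start_s
    while t < end_s:
        hold = rng.exponential(dwell[zone])
        segments.append((zone, t, min(t + hold, end_s)))
        t += hold
        zone = ISOLATION if zone == INTERACTION else INTERACTION
    return segments


def _sample_segments(
    segments: list[tuple[str, float, float]], frame_rate: float, n_samples: int
) -> np.ndarray:
    zones = np.empty(n_samples, dtype="<U11")
    for zone, a, b in segments:
        lo = int(np.ceil(a * frame_rate - 1e-9))
        hi = int(np.ceil(b * frame_rate - 1e-9))
        zones[lo : min(hi, n_samples)] = zone
    return zones


def _zone_at(segments: list[tuple[str, float, float]], t: float) -> tuple[str, float, float]:
    for zone, a, b in segments:
        if a <= t < b:
            return zone, a, b
    zone, a, b = segments[-1]
    return zone, a, b


def _poisson_onsets(
    rng: np.random.Generator, rate_per_min: float, start_s: float, end_s: float
) -> np.ndarray:
    if end_s <= start_s or rate_per_min <= 0:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * (end_s - start_s))
    return np.sort(rng.uniform(start_s, end_s, size=n))


def simulate_session(params: SessionParams, seed: int) -> tuple[Ethogram, ZoneTrack]:
    """Simulate one self-paced mating session.

    Returns an ethogram (appetitive and consummatory episodes, at most one
    ejaculation) and the female's zone-occupancy track sampled at
    ``params.frame_rate``. Consummatory episodes are placed only while the
    female occupies the interaction zone; the post-ejaculation occupancy
    process starts in the interaction zone (where ejaculation is received)
    with the post-epoch dwell parameters.
    """
    if not isinstance(params, SessionParams):
        raise InvalidParameterError("params must be a SessionParams")
    rng = np.random.default_rng(seed)
    t_ej = params.ejaculation_time_s
    fr = params.frame_rate
    switch = params.duration_s if t_ej is None else t_ej

    segments = _markov_segments(
        rng, 0.0, switch,
        params.zone_dwell_interaction_pre, params.zone_dwell_isolation_pre,
    )
    if t_ej is not None:
        segments = [s for s in segments if s[1] < t_ej]
        zone, a, b = segments[-1]
        segments[-1] = (zone, a, min(b, t_ej))
        # Ejaculation is received in the interaction zone: the post-epoch
        # occupancy process starts there at the event onset.
        segments += _markov_segments(
            rng, t_ej, params.duration_s,
            params.zone_dwell_interaction_post, params.zone_dwell_isolation_post,
            start_zone=INTERACTION,
        )

    n_samples = int(round(params.duration_s * fr))
    zones = _sample_segments(segments, fr, n_samples)

    margin = 1.0 / fr

    def in_interaction(t0: float, t1: Optional[float] = None) -> bool:
        # [t0, t1] must fit inside one interaction segment (with a one-sample
        # margin so the sampled track agrees); mounts keep the female in the
        # interaction zone for their whole bout
        zone, a, b = _zone_at(segments, t0)
        t1 = t0 if t1 is None else t1
        return zone == INTERACTION and (t0 - a) >= margin and (b - t1) >= margin

    events: list[BehaviorEvent] = []
    epochs = [(params.male_entry_s, switch, "pre")]
    if t_ej is not None:
        epochs.append((t_ej, params.duration_s, "post"))

    rates = {
        "sniff": (params.sniff_rate_pre, params.sniff_rate_post),
        "ano_sniff": (params.ano_sniff_rate_pre, params.ano_sniff_rate_post),
        "self_groom": (params.groom_rate_pre, params.groom_rate_post),
        "mount": (params.mount_rate_pre, params.mount_rate_post),
    }
    for behavior in ("sniff", "ano_sniff", "self_groom", "mount"):
        lo_d, hi_d = _DURATIONS[behavior]
        for start, end, which in epochs:
            rate = rates[behavior][0] if which == "pre" else rates[behavior][1]
            for onset in _poisson_onsets(rng, rate, start, end):
                dur = rng.uniform(lo_d, hi_d)
                offset = min(onset + dur, params.duration_s)
                # male-directed behaviors require the female in the
                # interaction zone; mounts for their entire bout
                if behavior == "mount" and not in_interaction(onset, offset):
                    continue
                if behavior in ("sniff", "ano_sniff") and not in_interaction(onset):
                    continue
                if offset <= onset:
                    continue
                events.append(BehaviorEvent(behavior, onset, offset))
                if behavior == "mount" and rng.random() < params.p_intromission:
                    mdur = offset - onset
                    i_on = onset + 0.2 * mdur
                    i_off = onset + 0.8 * mdur
                    events.append(BehaviorEvent("intromission", i_on, i_off))

    if t_ej is not None:
        events.append(
            BehaviorEvent(
                "ejaculation", t_ej, min(t_ej + _EJACULATION_DURATION_S, params.duration_s)
            )
        )

    etho = Ethogram(
        session_id=f"sim{seed}",
        duration_s=params.duration_s,
        events=events,
        male_entry_s=params.male_entry_s,
    )
    track = ZoneTrack(
        session_id=etho.session_id,
        frame_rate=fr,
        zones=zones,
        male_entry_s=params.male_entry_s,
        ejaculation_s=t_ej,
    )
    return etho, track


def expected_isolation_time(
    dwell_interaction: float, dwell_isolation: float, epoch_length_s: float,
    start_zone: str = INTERACTION,
) -> float:
    """Exact expected isolation time of the two-state Markov process over a
    finite window, starting from ``start_zone``. Tends to the stationary
    value pi_iso * T for long windows."""
    r1 = 1.0 / dwell_interaction
    r2 = 1.0 / dwell_isolation
    pi_iso = r1 / (r1 + r2)  # = dwell_iso / (dwell_int + dwell_iso)
    relax = (1.0 - np.exp(-(r1 + r2) * epoch_length_s)) / (r1 + r2)
    if start_zone == INTERACTION:
        return pi_iso * epoch_length_s - pi_iso * relax
    return pi_iso * epoch_length_s + (1 - pi_iso) * relax


def simulate_traces(
    etho: Ethogram, spec: CellSpec, seed: int
) -> tuple[TraceMatrix, pd.DataFrame]:
    """Simulate 10 Hz fluorescence traces for a planted cell population.

    Each cell of a responder class emits one peak-normalized
    difference-of-exponentials transient per coupled behavior onset
    (delayed by its class onset delay); transients sum linearly and ride on
    i.i.d. Gaussian noise. Samples before male entry are pure noise and
    serve as the z-scoring background. Returns the trace matrix and a
    ground-truth table (one row per cell) for parameter-recovery checks.
    """
    if not etho.events:
        raise InvalidParameterError("ethogram has no events")
    if etho.male_entry_s < 60.0:
        raise InvalidParameterError("need >= 60 s of pre-entry background")
    fs = 10.0
    rng = np.random.default_rng(seed)
    n = int(round(etho.duration_s * fs))
    t = np.arange(n) / fs

    present = {e.behavior for e in etho.events}
    class_templates: dict[str, np.ndarray] = {}
    for cls, behaviors in spec.coupled_behaviors.items():
        if cls == "nonresponder":
            continue
        kin = spec.kinetics[cls]
        onsets = [
            e.onset_s + kin.onset_delay_s
            for b in behaviors
            for e in etho.of(b)
        ]
        if not onsets and any(
            spec.n_cells_per_class.get((cls, ct), 0) > 0 for ct in ("Vgat", "Vglut2")
        ):
            missing = sorted(set(behaviors) - present)
            warnings.warn(
                f"response class {cls!r}: no events for coupled behaviors "
                f"{missing}; cells generated but never fire",
                stacklevel=2,
            )
        template = np.zeros(n)
        for onset in onsets:
            template += calcium_kernel(
                t - onset, kin.amplitude, kin.rise_tau_s, kin.decay_tau_s
            )
        class_templates[cls] = template

    cell_ids, cell_types, animal_ids, rows, truth_rows = [], [], [], [], []
    animal_counter = {ct: 0 for ct in spec.n_animals}
    for (cls, ct), count in spec.n_cells_per_class.items():
        kin = spec.kinetics.get(cls)
        template = class_templates.get(cls, np.zeros(n))
        for i in range(count):
            cid = f"{ct}_{cls}_{i:03d}"
            na = max(1, spec.n_animals.get(ct, 1))
            animal = f"{ct}_a{animal_counter[ct] % na}"
            animal_counter[ct] += 1
            noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
            rows.append(template + noise)
            cell_ids.append(cid)
            cell_types.append(ct)
            animal_ids.append(animal)
            truth_rows.append(
                {
                    "cell_id": cid,
                    "cell_type": ct,
                    "animal_id": animal,
                    "response_class": cls,
                    "amplitude": kin.amplitude if (kin and cls != "nonresponder") else 0.0,
                    "rise_tau_s": kin.rise_tau_s if (kin and cls != "nonresponder") else np.nan,
                    "decay_tau_s": kin.decay_tau_s if (kin and cls != "nonresponder") else np.nan,
                    "onset_delay_s": kin.onset_delay_s if (kin and cls != "nonresponder") else np.nan,
                }
            )

    traces = TraceMatrix(
        cell_ids=cell_ids,
        cell_types=cell_types,
        animal_ids=animal_ids,
        values=np.vstack(rows) if rows else np.zeros((0, n)),
        frame_rate=fs,
        background_window=(0.0, etho.male_entry_s),
        zscored=False,
    )
    truth = pd.DataFrame(truth_rows)
    return traces, truth


# ---------------------------------------------------------------------------
# Region-count tables


@dataclass
class RegionTable:
    """Hierarchical atlas nodes with volumes and per-subject labeled-cell counts."""

    regions: pd.DataFrame  # region_id, name, parent_id, level, volume_mm3
    counts: pd.DataFrame  # subject_id, group, region_id, count
    effect_regions: Mapping[str, float] = field(default_factory=dict)


def build_region_tree(
    n_regions_per_level: Mapping[int, int], root_volume_mm3: float = 100.0
) -> pd.DataFrame:
    """Balanced synthetic atlas tree: one level-1 root, children assigned
    round-robin, each parent's volume split equally among its children with
    a 5% residual so child volumes sum to <= the parent volume."""
    levels = sorted(n_regions_per_level)
    if not levels or levels[0] != 1 or n_regions_per_level[1] != 1:
        raise InvalidParameterError("tree must have exactly one level-1 root")
    rows = [
        {"region_id": "L1_0", "name": "root", "parent_id": "", "level": 1,
         "volume_mm3": root_volume_mm3}
    ]
    prev = ["L1_0"]
    volumes = {"L1_0": root_volume_mm3}
    for lvl in levels[1:]:
        n_here = n_regions_per_level[lvl]
        ids = [f"L{lvl}_{i}" for i in range(n_here)]
        n_children = {p: 0 for p in prev}
        for i, rid in enumerate(ids):
            n_children[prev[i % len(prev)]] += 1
        for i, rid in enumerate(ids):
            parent = prev[i % len(prev)]
            vol = volumes[parent] * 0.95 / n_children[parent]
            volumes[rid] = vol
            rows.append(
                {"region_id": rid, "name": rid, "parent_id": parent, "level": lvl,
                 "volume_mm3": vol}
            )
        prev = ids
    return pd.DataFrame(rows)


def simulate_region_counts(
    n_regions_per_level: Mapping[int, int],
    groups: Sequence[str],
    effect_regions: Mapping[str, float],
    base_density: float,
    dispersion: float,
    n_subjects_per_group: int,
    seed: int,
    effect_group: Optional[str] = None,
    root_volume_mm3: float = 100.0,
) -> RegionTable:
    """Negative-binomial labeled-cell counts on a synthetic atlas tree.

    Leaf counts are drawn around ``volume * base_density * fold`` with the
    NB parameterization var = mu + mu^2 / dispersion. ``effect_regions``
    maps a region id (leaf or internal node; folds multiply down the tree)
    to a fold-change applied in ``effect_group`` (default: the last listed
    group). Planted effects are recorded on the returned table.
    """
    if dispersion <= 0:
        raise InvalidParameterError("dispersion must be > 0")
    if base_density < 0:
        raise InvalidParameterError("base_density must be >= 0")
    if n_subjects_per_group < 1:
        raise InvalidParameterError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    regions = build_region_tree(n_regions_per_level, root_volume_mm3)
    effect_group = effect_group if effect_group is not None else groups[-1]
    if effect_group not in groups:
        raise InvalidParameterError(f"effect_group {effect_group!r} not in groups")

    parents = dict(zip(regions.region_id, regions.parent_id))
    children = set(regions.parent_id) - {""}
    leaves = [r for r in regions.region_id if r not in children]

    def fold_of(leaf: str) -> float:
        fold, node = 1.0, leaf
        while node:
            fold *= effect_regions.get(node, 1.0)
            node = parents[node]
        return fold

    vol = dict(zip(regions.region_id, regions.volume_mm3))
    rows = []
    for group in groups:
        for s in range(n_subjects_per_group):
            sid = f"{group}_{s}"
            for leaf in leaves:
                mu = vol[leaf] * base_density
                if group == effect_group:
                    mu *= fold_of(leaf)
                if mu <= 0:
                    count = 0
                else:
                    count = int(
                        rng.negative_binomial(dispersion, dispersion / (dispersion + mu))
                    )
                rows.append(
                    {"subject_id": sid, "group": group, "region_id": leaf, "count": count}
                )
    return RegionTable(
        regions=regions, counts=pd.DataFrame(rows), effect_regions=dict(effect_regions)
    )
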