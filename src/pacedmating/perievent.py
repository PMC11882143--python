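"""Per-cell peri-event calcium analysis and responder classification.

Traces are z-scored against a pre-intruder background segment, aligned to
behavior onsets in half-open windows ([-5, +15) s by default, 10 Hz),
averaged across events, and baseline-subtracted over [-5, 0). The response
magnitude is the mean over [0, +5) s; cells with |magnitude| > 2 (two
background SDs, the 2-delta rule) are positive/negative responders.
Specificity categories assign each responder to the behavior with the
largest positive magnitude among sniff / mount / ejaculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import Ethogram, InvalidParameterError, TraceMatrix

#: Responder threshold in background-SD units (the 2-delta rule).
RESPONDER_THRESHOLD = 2.0

#: Behaviors entering the specificity categorization, in tie-break priority
#: order (highest first).
SPECIFICITY_BEHAVIORS = ("ejaculation", "mount", "sniff")


def zscore_traces(raw: TraceMatrix) -> TraceMatrix:
    """Z-score each cell against its background segment.

    z = (x - mu_bg) / sigma_bg with the mean and sample SD (ddof=1) of the
    cell's samples inside ``background_window``. Cells with zero background
    variance are reported together in one error.
    """
    lo, hi = raw.background_window
    if hi - lo < 10.0:
        raise InvalidParameterError("background window must be >= 10 s")
    bg = raw.values[:, raw.background_slice()]
    mu = bg.mean(axis=1, keepdims=True)
    sd = bg.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = [raw.cell_ids[i] for i in flat]
        raise InvalidParameterError(f"zero background variance for cells: {bad}")
    return TraceMatrix(
        cell_ids=list(raw.cell_ids),
        cell_types=list(raw.cell_types),
        animal_ids=list(raw.animal_ids),
        values=(raw.values - mu) / sd,
        frame_rate=raw.frame_rate,
        background_window=raw.background_window,
        zscored=True,
    )


def filter_appetitive_sniffs(etho: Ethogram) -> Ethogram:
    """Drop sniff events at or after the first mount onset.

    Restricts sniffing to the appetitive phase: once mounting has begun,
    female-to-male sniffs are no longer unambiguous approach behavior.
    """
    mounts = etho.of("mount")
    if not mounts:
        return etho
    first_mount = mounts[0].onset_s
    kept = [
        e for e in etho.events
        if not (e.behavior == "sniff" and e.onset_s >= first_mount)
    ]
    return Ethogram(
        session_id=etho.session_id,
        duration_s=etho.duration_s,
        events=kept,
        male_entry_s=etho.male_entry_s,
    )


@dataclass
class PeriEventTensor:
    """Event-averaged peri-event traces per cell and behavior.

    ``traces[behavior]`` is (n_cells, n_window_samples); behaviors with no
    fully covered event are absent (never zero-filled).
    """

    cell_ids: list[str]
    cell_types: list[str]
    window_s: tuple[float, float]
    frame_rate: float
    traces: dict[str, np.ndarray] = field(default_factory=dict)
    n_events: dict[str, int] = field(default_factory=dict)
    baseline_subtracted: bool = False

    def window_times(self) -> np.ndarray:
        a, b = self.window_s
        n = int(round((b - a) * self.frame_rate))
        return a + np.arange(n) / self.frame_rate


def extract_perievent(
    traces: TraceMatrix,
    etho: Ethogram,
    window_s: tuple[float, float] = (-5.0, 15.0),
    baseline_subtract: bool = True,
) -> PeriEventTensor:
    """Average peri-event windows around each behavior's onsets.

    Onsets are snapped to the nearest sample; windows are half-open
    [window[0], window[1]) at sample resolution. Events whose window
    extends past the recording are dropped with a warning (padding would
    bias the average). After averaging, the mean over [-5, 0) is
    subtracted so responses are relative to the immediate pre-event level.
    """
    a, b = window_s
    if not a < 0 <= b:
        raise InvalidParameterError("window must span the onset (a < 0 <= b)")
    fs = traces.frame_rate
    n_before = int(round(-a * fs))
    n_after = int(round(b * fs))
    n_samples = traces.n_samples
    out = PeriEventTensor(
        cell_ids=list(traces.cell_ids),
        cell_types=list(traces.cell_types),
        window_s=window_s,
        frame_rate=fs,
        baseline_subtracted=baseline_subtract,
    )
    behaviors = sorted({e.behavior for e in etho.events})
    for behavior in behaviors:
        windows = []
        n_dropped = 0
        for event in etho.of(behavior):
            idx = int(round(event.onset_s * fs))
            lo, hi = idx - n_before, idx + n_after
            if lo < 0 or hi > n_samples:
                n_dropped += 1
                continue
            windows.append(traces.values[:, lo:hi])
        if n_dropped:
            warnings.warn(
                f"{behavior}: dropped {n_dropped} event(s) without full "
                f"window coverage",
                stacklevel=2,
            )
        if not windows:
            continue
        avg = np.mean(windows, axis=0)
        if baseline_subtract:
            avg = avg - avg[:, :n_before].mean(axis=1, keepdims=True)
        out.traces[behavior] = avg
        out.n_events[behavior] = len(windows)
    return out


def response_magnitude(tensor: PeriEventTensor) -> pd.DataFrame:
    """Mean z-scored response over [0, +5) s per cell x behavior (long table)."""
    if not tensor.baseline_subtracted:
        raise InvalidParameterError("magnitude requires a baseline-subtracted tensor")
    fs = tensor.frame_rate
    onset_idx = int(round(-tensor.window_s[0] * fs))
    n_mag = int(round(5.0 * fs))
    rows = []
    for behavior, mat in tensor.traces.items():
        mags = mat[:, onset_idx : onset_idx + n_mag].mean(axis=1)
        for cid, ct, m in zip(tensor.cell_ids, tensor.cell_types, mags):
            rows.append(
                {"cell_id": cid, "cell_type": ct, "behavior": behavior,
                 "magnitude": float(m)}
            )
    return pd.DataFrame(rows)


def classify_responders(
    magnitudes: pd.DataFrame, threshold: float = RESPONDER_THRESHOLD
) -> pd.DataFrame:
    """Label each cell x behavior as positive / negative / none.

    Strict inequality: magnitude > +threshold is positive, < -threshold is
    negative; values exactly at the boundary are non-responders.
    """
    out = magnitudes.copy()
    mag = out["magnitude"].to_numpy()
    cls = np.where(mag > threshold, "positive", np.where(mag < -threshold, "negative", "none"))
    out["responder"] = cls
    return out


def categorize_specificity(
    responses: pd.DataFrame,
    behaviors: tuple[str, ...] = SPECIFICITY_BEHAVIORS,
) -> pd.DataFrame:
    """Assign each cell a specificity category among the key behaviors.

    Cells positive for at least one of ``behaviors`` take the behavior with
    the largest magnitude among their positive responses (ties broken by
    the fixed priority ejaculation > mount > sniff); the overlap set lists
    every behavior with a positive response. Other cells get 'none'.
    """
    sub = responses[responses["behavior"].isin(behaviors)]
    rows = []
    priority = {b: i for i, b in enumerate(behaviors)}  # lower = higher priority
    for cell_id, grp in sub.groupby("cell_id", sort=False):
        pos = grp[grp["responder"] == "positive"]
        if pos.empty:
            category, overlap = "none", ()
        else:
            pos = pos.assign(_prio=pos["behavior"].map(priority))
            best = pos.sort_values(["magnitude", "_prio"], ascending=[False, True]).iloc[0]
            category = best["behavior"]
            overlap = tuple(sorted(pos["behavior"], key=priority.get))
        rows.append(
            {"cell_id": cell_id, "category": category,
             "overlap": ";".join(overlap)}
        )
    return pd.DataFrame(rows)


def responder_proportion_test(
    k1: int, n1: int, k2: int, n2: int, m: int = 1
) -> dict[str, float]:
    """Chi-square test on a 2x2 responder table with Bonferroni correction.

    Pearson chi-square WITHOUT continuity correction on
    [[k1, n1-k1], [k2, n2-k2]]; corrected p = min(1, m * p). Degenerate
    margins (no responders in either group, or all cells responding) give
    statistic 0, p 1.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise InvalidParameterError("counts must satisfy 0 <= k <= n")
    if m < 1:
        raise InvalidParameterError("number of comparisons m must be >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # zero margin: proportions identical (0 or 1)
        return {"chi2": 0.0, "p": 1.0, "p_bonferroni": 1.0, "m": m}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "p_bonferroni": float(min(1.0, m * p)),
        "m": m,
    }
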