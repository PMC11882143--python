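"""Behavioral metrics of the self-paced mating assay and their statistics.

The assay places the female in a two-zone apparatus in which only she can
cross between an interaction zone (with the male) and an isolation zone.
Approach metrics (zone transitions, isolation time, latency to return,
per-behavior episode rates, receptive score) index sexual motivation and
are compared across control / pre-ejaculation / post-ejaculation epochs
with repeated-measures ANOVA + Tukey HSD or exact Wilcoxon signed-rank
tests, mirroring the standard analysis of this assay.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import (
    BEHAVIORS,
    ISOLATION,
    EpochSpec,
    Ethogram,
    InvalidEpochError,
    InvalidParameterError,
    ZoneTrack,
    default_epochs,
)

#: Sentinel for metrics that are undefined for a session (e.g. latency to
#: return when the behavior never occurred). Distinguishable from 0.0.
NOT_APPLICABLE = float("nan")


def _epoch_slice(track: ZoneTrack, epoch: EpochSpec) -> np.ndarray:
    if epoch.length_s <= 0:
        raise InvalidEpochError(f"epoch {epoch.name!r} has zero length")
    if epoch.start_s < 0 or epoch.end_s > track.duration_s + 1e-9:
        raise InvalidEpochError(
            f"epoch {epoch.name!r} [{epoch.start_s}, {epoch.end_s}) outside track "
            f"duration {track.duration_s}"
        )
    lo = int(np.ceil(epoch.start_s * track.frame_rate - 1e-9))
    hi = int(np.ceil(epoch.end_s * track.frame_rate - 1e-9))
    return track.zones[lo:hi]


def zone_transitions_rate(track: ZoneTrack, epoch: EpochSpec) -> float:
    """Zone transitions per 10 min within the epoch.

    A transition is any sample-to-sample zone change; the count is scaled
    by 600 / epoch length. No debouncing is applied (the divider hole makes
    spurious flicker unlikely).
    """
    zones = _epoch_slice(track, epoch)
    n_transitions = int(np.count_nonzero(zones[1:] != zones[:-1]))
    return n_transitions * 600.0 / epoch.length_s


def time_in_isolation(track: ZoneTrack, epoch: EpochSpec) -> float:
    """Seconds spent in the isolation zone within the epoch
    (#isolation samples / frame rate)."""
    zones = _epoch_slice(track, epoch)
    return float(np.count_nonzero(zones == ISOLATION)) / track.frame_rate


def time_in_interaction(track: ZoneTrack, epoch: EpochSpec) -> float:
    """Seconds spent in the interaction zone within the epoch."""
    zones = _epoch_slice(track, epoch)
    return float(np.count_nonzero(zones != ISOLATION)) / track.frame_rate


def latency_to_return(
    track: ZoneTrack,
    etho: Ethogram,
    behavior: str,
    statistic: str = "mean",
) -> float:
    """Mean latency to return to the interaction zone after a behavior.

    For each episode of ``behavior`` followed by an exit to the isolation
    zone before the next episode, the latency is the time from the episode
    offset to the first re-entry into the interaction zone. Episodes with
    no subsequent exit contribute 0 (no avoidance); an exit with no
    re-entry before the record ends is censored at the record end. Returns
    NaN (not-applicable) when the behavior never occurs.
    """
    episodes = etho.of(behavior)
    if not episodes:
        return NOT_APPLICABLE
    zones = track.zones
    fr = track.frame_rate
    iso = zones == ISOLATION
    latencies = []
    for i, ep in enumerate(episodes):
        next_onset = episodes[i + 1].onset_s if i + 1 < len(episodes) else track.duration_s
        lo = int(np.ceil(ep.offset_s * fr - 1e-9))
        hi = int(np.ceil(next_onset * fr - 1e-9))
        window = iso[lo:hi]
        exits = np.flatnonzero(window)
        if exits.size == 0:
            latencies.append(0.0)
            continue
        after_exit = iso[lo + exits[0]:]
        reentries = np.flatnonzero(~after_exit)
        if reentries.size == 0:
            latencies.append(track.duration_s - ep.offset_s)
        else:
            t_return = (lo + exits[0] + reentries[0]) / fr
            latencies.append(t_return - ep.offset_s)
    if statistic == "mean":
        return float(np.mean(latencies))
    if statistic == "median":
        return float(np.median(latencies))
    raise InvalidParameterError(f"unknown statistic {statistic!r}")


def episode_rate(etho: Ethogram, behavior: str, epoch: EpochSpec) -> float:
    """Episodes of ``behavior`` with onset inside the epoch, per 10 min."""
    if behavior not in BEHAVIORS:
        raise InvalidParameterError(f"unknown behavior label {behavior!r}")
    if epoch.length_s <= 0:
        raise InvalidEpochError(f"epoch {epoch.name!r} has zero length")
    count = sum(1 for e in etho.of(behavior) if epoch.start_s <= e.onset_s < epoch.end_s)
    return count * 600.0 / epoch.length_s


def receptive_score(etho: Ethogram, definition: str = "per_mount") -> float:
    """Fraction of mount episodes containing intromission.

    A mount contains intromission when an intromission event overlaps its
    interval. The default bounded-in-[0,1] per-mount-episode form is used;
    ``definition='ratio'`` gives the alternative total-intromissions /
    total-mounts ratio. Returns NaN when there are no mounts.
    """
    mounts = etho.of("mount")
    if not mounts:
        return NOT_APPLICABLE
    intromissions = etho.of("intromission")
    if definition == "ratio":
        return len(intromissions) / len(mounts)
    if definition != "per_mount":
        raise InvalidParameterError(f"unknown receptive-score definition {definition!r}")
    containing = sum(
        any(i.onset_s < m.offset_s and i.offset_s > m.onset_s for i in intromissions)
        for m in mounts
    )
    return containing / len(mounts)


def summarize_session(
    etho: Ethogram,
    track: ZoneTrack,
    epochs: Optional[dict[str, EpochSpec]] = None,
) -> pd.DataFrame:
    """Per-epoch behavioral summary of one session (long format)."""
    epochs = epochs if epochs is not None else default_epochs(etho)
    rows = []
    for name, epoch in epochs.items():
        row = {
            "session_id": etho.session_id,
            "epoch": name,
            "transitions_per_10min": zone_transitions_rate(track, epoch),
            "isolation_time_s": time_in_isolation(track, epoch),
            "receptive_score": receptive_score(etho),
        }
        for behavior in BEHAVIORS:
            row[f"rate_{behavior}_per_10min"] = episode_rate(etho, behavior, epoch)
        for behavior in ("sniff", "mount", "ejaculation"):
            row[f"latency_after_{behavior}_s"] = latency_to_return(track, etho, behavior)
        rows.append(row)
    return pd.DataFrame(rows)


def power_min_n(
    mean1: float, sd1: float, mean2: float, sd2: float,
    alpha: float = 0.05, power: float = 0.8, n_max: int = 100000,
) -> int:
    """Smallest balanced per-group n for a two-sided two-sample t-test.

    Effect size d = |mean1 - mean2| / sqrt((sd1^2 + sd2^2) / 2) (RMS-pooled
    SDs, the only pooling available from per-group mean +/- SD summaries);
    power is evaluated with the noncentral-t distribution
    (df = 2n - 2, noncentrality d * sqrt(n/2)).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidParameterError("SDs must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidParameterError("alpha and power must be in (0, 1)")
    d = abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)
    if d == 0:
        raise InvalidParameterError("zero effect size: no finite n achieves the power")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        t_crit = stats.t.ppf(1 - alpha / 2, df)
        nc = d * math.sqrt(n / 2.0)
        achieved = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
        if achieved >= power:
            return n
    raise InvalidParameterError(f"power not reached within n <= {n_max}")


def epoch_stats(
    summaries: pd.DataFrame, value: str, subject: str = "session_id",
    epoch: str = "epoch", fwer: float = 0.05,
) -> dict:
    """Within-subject comparison of one behavioral metric across epochs.

    Three or more epochs: one-way repeated-measures ANOVA with Tukey HSD
    pairwise comparisons at the given FWER. Exactly two epochs: exact
    Wilcoxon signed-rank test on the paired differences. Requires a
    complete balanced subject x epoch table (no silent imputation).
    """
    df = summaries[[subject, epoch, value]].copy()
    if df[value].isna().any():
        raise InvalidParameterError(f"missing values in {value!r}")
    counts = df.groupby([subject, epoch]).size()
    if (counts != 1).any():
        raise InvalidParameterError("need exactly one value per subject x epoch cell")
    wide = df.pivot(index=subject, columns=epoch, values=value)
    if wide.isna().any().any():
        raise InvalidParameterError("unbalanced design: missing subject x epoch cells")
    levels = list(wide.columns)
    n_subjects = len(wide)
    if len(levels) < 2:
        raise InvalidParameterError("need >= 2 epochs")

    if len(levels) == 2:
        if n_subjects < 2:
            raise InvalidParameterError("need >= 2 subjects for a paired test")
        diffs = wide[levels[1]] - wide[levels[0]]
        if np.allclose(diffs, 0):
            return {"test": "wilcoxon", "statistic": float("nan"), "p": 1.0,
                    "n": n_subjects, "levels": levels}
        res = stats.wilcoxon(
            wide[levels[0]], wide[levels[1]], alternative="two-sided", method="exact"
        )
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "p": float(res.pvalue), "n": n_subjects, "levels": levels}

    if n_subjects < 3:
        raise InvalidParameterError("need >= 3 subjects for repeated-measures ANOVA")
    if np.allclose(df.groupby(epoch)[value].mean().var(ddof=0), 0) and np.allclose(
        wide.to_numpy().var(axis=0, ddof=0).sum(), 0
    ):
        # identical values everywhere: F = 0 by definition, nothing to test
        anova_f, anova_p = 0.0, 1.0
        df1, df2 = len(levels) - 1, (len(levels) - 1) * (n_subjects - 1)
    else:
        res = AnovaRM(df, depvar=value, subject=subject, within=[epoch]).fit()
        row = res.anova_table.iloc[0]
        anova_f, anova_p = float(row["F Value"]), float(row["Pr > F"])
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        if not np.isfinite(anova_f):  # zero residual variance with equal means
            anova_f, anova_p = 0.0, 1.0
    tukey = pairwise_tukeyhsd(df[value].to_numpy(), df[epoch].to_numpy(), alpha=fwer)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "test": "rm_anova",
        "F": anova_f, "df": (df1, df2), "p": anova_p,
        "n": n_subjects, "levels": levels, "tukey": pairwise,
    }
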