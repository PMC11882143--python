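"""Temporal persistence of ejaculation responses: decay length and
unsupervised classification of long-window response shapes.

Ejaculation happens once per session, so each cell contributes a single
baseline-subtracted trace over [-5, +120) s around the onset. The decay
length measures how long the elevated response takes to return to baseline
(first strictly-negative sample, capped at the window end). Response
shapes are classified by PCA (4 components) followed by spectral
clustering on a symmetrized k-nearest-neighbor graph, selecting the
(n_clusters, n_neighbors) grid point that maximizes the mean silhouette in
the PC embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import spectral_embedding
from sklearn.metrics import silhouette_score
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .perievent import PeriEventTensor, extract_perievent
from .types import Ethogram, InvalidParameterError, TraceMatrix

LONG_WINDOW_S = (-5.0, 120.0)


def decay_length(
    trace: np.ndarray,
    frame_rate: float = 10.0,
    cap_s: float = 120.0,
    smooth_boxcar_s: float = 0.0,
    mode: str = "first_crossing",
) -> float:
    """Seconds until a baseline-subtracted response returns to baseline.

    ``trace`` starts at the event onset (t = 0). In the default
    ``first_crossing`` mode the decay length is the time of the first
    sample strictly below 0, or ``cap_s`` when the trace never goes
    negative. ``mode='time_above'`` instead returns the total time the
    signal is >= 0 within [0, cap_s). An optional boxcar pre-smoothing
    (seconds) is applied before thresholding.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size == 0:
        raise InvalidParameterError("trace must be a non-empty 1-D array")
    n_cap = int(round(cap_s * frame_rate))
    x = trace[:n_cap]
    if smooth_boxcar_s > 0:
        w = max(1, int(round(smooth_boxcar_s * frame_rate)))
        kernel = np.ones(w) / w
        x = np.convolve(x, kernel, mode="same")
    if mode == "first_crossing":
        neg = np.flatnonzero(x < 0)
        return cap_s if neg.size == 0 else float(neg[0] / frame_rate)
    if mode == "time_above":
        return float(np.count_nonzero(x >= 0) / frame_rate)
    raise InvalidParameterError(f"unknown decay-length mode {mode!r}")


@dataclass
class LongWindowMatrix:
    """Baseline-subtracted single-trial ejaculation traces, [-5, +120) s."""

    cell_ids: list[str]
    cell_types: list[str]
    values: np.ndarray  # (n_cells, n_window_samples)
    window_s: tuple[float, float] = LONG_WINDOW_S
    frame_rate: float = 10.0

    @property
    def onset_index(self) -> int:
        return int(round(-self.window_s[0] * self.frame_rate))

    def post_onset(self) -> np.ndarray:
        return self.values[:, self.onset_index :]

    def decay_lengths(self, **kwargs) -> np.ndarray:
        cap = self.window_s[1]
        return np.array(
            [decay_length(row, self.frame_rate, cap_s=cap, **kwargs) for row in self.post_onset()]
        )

    def magnitudes(self) -> np.ndarray:
        lo = self.onset_index
        hi = lo + int(round(5.0 * self.frame_rate))
        return self.values[:, lo:hi].mean(axis=1)


def build_long_window_matrix(
    traces: TraceMatrix,
    etho: Ethogram,
    responses: Optional[pd.DataFrame] = None,
    cell_ids: Optional[Sequence[str]] = None,
    window_s: tuple[float, float] = LONG_WINDOW_S,
) -> LongWindowMatrix:
    """Assemble the long-window matrix around the ejaculation onset.

    By default only cells with a positive ejaculation responder class (from
    ``responses``, see perievent.classify_responders) are included; an
    explicit ``cell_ids`` list overrides the filter (useful for analyzing a
    planted population).
    """
    if cell_ids is None:
        if responses is None:
            raise InvalidParameterError("provide either responses or cell_ids")
        sel = responses[
            (responses["behavior"] == "ejaculation")
            & (responses["responder"] == "positive")
        ]["cell_id"].tolist()
    else:
        sel = list(cell_ids)
    if not sel:
        raise InvalidParameterError("no ejaculation-positive cells to analyze")
    tensor = extract_perievent(traces, etho, window_s=window_s, baseline_subtract=True)
    if "ejaculation" not in tensor.traces:
        raise InvalidParameterError("no fully covered ejaculation event in the recording")
    index = {cid: i for i, cid in enumerate(tensor.cell_ids)}
    rows = [index[c] for c in sel]
    return LongWindowMatrix(
        cell_ids=sel,
        cell_types=[tensor.cell_types[i] for i in rows],
        values=tensor.traces["ejaculation"][rows],
        window_s=window_s,
        frame_rate=tensor.frame_rate,
    )


@dataclass
class ClusterModel:
    """Fitted spectral-clustering model with its hyperparameter grid."""

    n_components: int
    grid: pd.DataFrame  # n_clusters, n_neighbors, silhouette
    n_clusters: int
    n_neighbors: int
    silhouette: float
    labels: np.ndarray  # 1-based cluster labels
    seed: int
    pc_coords: np.ndarray = field(repr=False, default=None)


def cluster_responses(
    mat: LongWindowMatrix,
    grid_clusters: Sequence[int] = tuple(range(2, 9)),
    grid_neighbors: Sequence[int] = tuple(range(5, 101, 5)),
    seed: int = 0,
    n_components: int = 4,
) -> ClusterModel:
    """Cluster long-window response shapes with model selection.

    The trace matrix (rows = cells, already in common z-units; no per-row
    renormalization) is reduced to ``n_components`` principal components.
    For every (n_clusters, n_neighbors) grid point a symmetric kNN
    connectivity graph is built in the PC embedding (mutual-or rule: edge
    if either endpoint lists the other), spectral clustering is run with a
    seeded k-means assignment, and the mean silhouette (Euclidean, PC
    space) is recorded. The silhouette-maximizing grid point is selected;
    ties prefer fewer clusters, then fewer neighbors.
    """
    X = np.asarray(mat.values, dtype=float)
    n_rows = X.shape[0]
    if n_rows < 2 * max(grid_clusters):
        raise InvalidParameterError(
            f"need >= {2 * max(grid_clusters)} cells for grid_clusters up to "
            f"{max(grid_clusters)}; got {n_rows}"
        )
    if np.allclose(X, X[0]):
        raise InvalidParameterError("all rows identical: silhouette undefined")
    pca = PCA(n_components=n_components, random_state=seed)
    coords = pca.fit_transform(X)

    k_max = max(grid_clusters)
    records = []
    labels_by_point: dict[tuple[int, int], np.ndarray] = {}
    for n_neighbors in sorted(grid_neighbors):
        if n_neighbors >= n_rows:
            warnings.warn(
                f"skipping n_neighbors={n_neighbors} >= n_cells={n_rows}", stacklevel=2
            )
            continue
        conn = kneighbors_graph(coords, n_neighbors, mode="connectivity", include_self=False)
        affinity = conn.maximum(conn.T)  # mutual-or symmetrization
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Graph is not fully connected")
            emb = spectral_embedding(
                affinity, n_components=k_max, drop_first=False, random_state=seed
            )
        for k in sorted(grid_clusters):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(emb[:, :k])
            if len(np.unique(labels)) < 2:
                continue
            sil = float(silhouette_score(coords, labels, metric="euclidean"))
            records.append(
                {"n_clusters": k, "n_neighbors": n_neighbors, "silhouette": sil}
            )
            labels_by_point[(k, n_neighbors)] = labels
    if not records:
        raise InvalidParameterError("no valid grid point (all skipped or degenerate)")
    grid = pd.DataFrame(records)
    best = grid.sort_values(
        ["silhouette", "n_clusters", "n_neighbors"], ascending=[False, True, True]
    ).iloc[0]
    k_star, nn_star = int(best["n_clusters"]), int(best["n_neighbors"])
    return ClusterModel(
        n_components=n_components,
        grid=grid,
        n_clusters=k_star,
        n_neighbors=nn_star,
        silhouette=float(best["silhouette"]),
        labels=labels_by_point[(k_star, nn_star)] + 1,
        seed=seed,
        pc_coords=coords,
    )


def cluster_profile(
    model: ClusterModel, mat: LongWindowMatrix, fwer: float = 0.05
) -> dict:
    """Per-cluster aggregates and across-cluster tests.

    Returns per-cluster mean traces, and a summary table with mean decay
    length and mean magnitude with 95% t-based confidence intervals, plus
    one-way ANOVA + Tukey HSD across clusters for both statistics.
    Clusters of size < 2 are reported but excluded from the ANOVA.
    """
    decays = mat.decay_lengths()
    mags = mat.magnitudes()
    labels = np.asarray(model.labels)
    rows, mean_traces = [], {}
    for c in np.unique(labels):
        sel = labels == c
        mean_traces[int(c)] = mat.values[sel].mean(axis=0)
        for name, vals in (("decay_length_s", decays[sel]), ("magnitude", mags[sel])):
            n = vals.size
            mean = float(vals.mean())
            if n > 1:
                half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
            else:
                half = np.nan
            rows.append(
                {"cluster": int(c), "statistic": name, "n": int(n), "mean": mean,
                 "ci95_lo": mean - half, "ci95_hi": mean + half}
            )
    summary = pd.DataFrame(rows)

    tests = {}
    big = np.array([c for c in np.unique(labels) if (labels == c).sum() >= 2])
    excluded = [int(c) for c in np.unique(labels) if c not in big]
    if excluded:
        warnings.warn(f"clusters {excluded} have < 2 cells; excluded from ANOVA",
                      stacklevel=2)
    keep = np.isin(labels, big)
    for name, vals in (("decay_length_s", decays), ("magnitude", mags)):
        if big.size < 2:
            tests[name] = {"F": np.nan, "p": np.nan, "tukey": None}
            continue
        groups = [vals[labels == c] for c in big]
        if all(np.allclose(g, groups[0].mean()) for g in groups):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        tukey = pairwise_tukeyhsd(vals[keep], labels[keep], alpha=fwer)
        tests[name] = {
            "F": float(f_stat), "p": float(p),
            "tukey": pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0]),
        }
    return {"summary": summary, "mean_traces": mean_traces, "tests": tests,
            "excluded_clusters": excluded}


def cluster_composition_test(
    labels: np.ndarray,
    cell_types: Sequence[str],
    m: Optional[int] = None,
    types: tuple[str, str] = ("Vgat", "Vglut2"),
) -> pd.DataFrame:
    """Per-cluster 2x2 test of membership vs cell type.

    For each cluster c, tests (members of c among type-1 cells) vs (members
    of c among type-2 cells) with the chi-square responder-proportion test,
    Bonferroni-corrected with m = number of clusters by default. With a
    single cell type present the p-values are NaN (not applicable).
    """
    from .perievent import responder_proportion_test

    labels = np.asarray(labels)
    ctypes = np.asarray(cell_types)
    clusters = np.unique(labels)
    if m is None:
        m = len(clusters)
    t1, t2 = types
    n1 = int(np.count_nonzero(ctypes == t1))
    n2 = int(np.count_nonzero(ctypes == t2))
    rows = []
    for c in clusters:
        k1 = int(np.count_nonzero((labels == c) & (ctypes == t1)))
        k2 = int(np.count_nonzero((labels == c) & (ctypes == t2)))
        if n1 == 0 or n2 == 0:
            rows.append(
                {"cluster": int(c), f"k_{t1}": k1, f"n_{t1}": n1, f"k_{t2}": k2,
                 f"n_{t2}": n2, "chi2": np.nan, "p": np.nan, "p_bonferroni": np.nan}
            )
            continue
        res = responder_proportion_test(k1, n1, k2, n2, m=m)
        rows.append(
            {"cluster": int(c), f"k_{t1}": k1, f"n_{t1}": n1, f"k_{t2}": k2,
             f"n_{t2}": n2, "chi2": res["chi2"], "p": res["p"],
             "p_bonferroni": res["p_bonferroni"]}
        )
    return pd.DataFrame(rows)
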