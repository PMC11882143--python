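#!/usr/bin/env python
"""Optional validation against the original deposited imaging dataset.

Not used by the test suite: it requires a local copy of the deposited
long-window matrix (ejaculation-responsive cells x samples over
[-5, +120) s at 10 Hz, baseline-subtracted, one row per cell) exported as
CSV with a leading cell_id column and a cell_type column.

    python scripts/validate_deposited.py --matrix long_window.csv --seed 0

Reruns the PCA + spectral-clustering grid search and prints the selected
(n_clusters, n_neighbors, mean silhouette) for comparison with the
originally reported optimum (5 clusters, 55 neighbors, silhouette 0.405).
"""

from __future__ import annotations

import argparse

import pandas as pd

from pacedmating import persistence as ps


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--matrix", required=True,
                        help="CSV: cell_id, cell_type, then one column per sample")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    df = pd.read_csv(args.matrix)
    mat = ps.LongWindowMatrix(
        cell_ids=df["cell_id"].astype(str).tolist(),
        cell_types=df["cell_type"].astype(str).tolist(),
        values=df.drop(columns=["cell_id", "cell_type"]).to_numpy(dtype=float),
    )
    model = ps.cluster_responses(mat, seed=args.seed)
    print(f"selected n_clusters = {model.n_clusters}")
    print(f"selected n_neighbors = {model.n_neighbors}")
    print(f"mean silhouette      = {model.silhouette:.3f}")
    print("reported optimum     = 5 clusters, 55 neighbors, silhouette 0.405")


if __name__ == "__main__":
    main()
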