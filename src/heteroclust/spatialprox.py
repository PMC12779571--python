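"""Multiplex-IF proximity analysis.

Marker-flag reclassification of centroid tables, nearest-neighbour distances
between cell classes, and the 10-um heterotypic-cluster classification of CD8
T cells (T-tumour clusters take precedence over T-APC clusters when both
criteria hold; the cutoff is a strict inequality).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "reclassify_cells",
    "nearest_class_distances",
    "classify_proximity_clusters",
]

FLAG_COLUMNS = ("sox10_hmb45", "cd8", "cd11c")


def reclassify_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Resolve multi-positive marker flags into a final class.

    Rules, in order: tumour+CD8 double positives and tumour+CD8+CD11c triple
    positives become Unclassified; tumour+CD11c becomes Tumour (CD11c
    membrane protrusions into tumour tissue cause false CD11c calls);
    CD8+CD11c becomes CD8 for the same reason; single positives keep their
    class; all-negative cells are Unclassified.
    """
    for col in FLAG_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"missing flag column {col!r}")
    sox = table["sox10_hmb45"].astype(bool).to_numpy()
    cd8 = table["cd8"].astype(bool).to_numpy()
    cd11c = table["cd11c"].astype(bool).to_numpy()

    final = np.select(
        [
            sox & cd8,  # covers the triple-positive case too
            sox & cd11c,
            cd8 & cd11c,
            sox,
            cd8,
            cd11c,
        ],
        ["Unclassified", "Tumour", "CD8", "Tumour", "CD8", "CD11c"],
        default="Unclassified",
    )
    out = table.copy()
    out["final_class"] = final
    return out


def nearest_class_distances(
    table: pd.DataFrame, classes: tuple[str, ...] = ("Tumour", "CD8", "CD11c")
) -> pd.DataFrame:
    """Distance from every cell to its nearest cell of each class.

    Euclidean centroid-to-centroid distances; a cell is never its own
    neighbour (self-exclusion within its own class).  Distances to an absent
    class are infinite.
    """
    if "final_class" not in table.columns:
        raise KeyError("run reclassify_cells first (missing 'final_class')")
    xy = table[["x_um", "y_um"]].to_numpy(float)
    out = pd.DataFrame(index=table.index)
    for cls in classes:
        member = (table["final_class"] == cls).to_numpy()
        col = f"dist_{cls}"
        if member.sum() == 0:
            out[col] = np.inf
            continue
        nn = NearestNeighbors(n_neighbors=min(2, member.sum())).fit(xy[member])
        dist, _ = nn.kneighbors(xy)
        d = dist[:, 0].copy()
        # self-exclusion: a class member's nearest same-class hit is itself
        if member.sum() >= 2:
            d[member] = dist[member, 1]
        else:
            d[member] = np.inf
        out[col] = d
    return out


def classify_proximity_clusters(
    table: pd.DataFrame, cutoff_um: float = 10.0
) -> tuple[pd.DataFrame, dict]:
    """Label each CD8 cell as T-Tum cluster, T-APC cluster or unclustered.

    A CD8 cell strictly closer than ``cutoff_um`` to a Tumour cell is a
    T-Tum cluster (regardless of any nearby CD11c cell: proximity to both is
    defined as T-Tum); otherwise, strictly closer than the cutoff to a CD11c
    cell makes it a T-APC cluster; otherwise it is unclustered.

    Returns the labelled table (column ``cluster_label``, empty for non-CD8
    cells) and a summary with counts and fractions per label.
    """
    if "final_class" not in table.columns:
        table = reclassify_cells(table)
    dists = nearest_class_distances(table)
    is_cd8 = (table["final_class"] == "CD8").to_numpy()
    out = table.copy()
    out[["dist_Tumour", "dist_CD8", "dist_CD11c"]] = dists[
        ["dist_Tumour", "dist_CD8", "dist_CD11c"]
    ].to_numpy()
    label = np.where(
        dists["dist_Tumour"].to_numpy() < cutoff_um,
        "T-Tum cluster",
        np.where(
            dists["dist_CD11c"].to_numpy() < cutoff_um, "T-APC cluster", "unclustered"
        ),
    )
    label = np.where(is_cd8, label, "")
    out["cluster_label"] = label

    n_cd8 = int(is_cd8.sum())
    if n_cd8 == 0:
        warnings.warn("no CD8 cells in table", stacklevel=2)
    counts = {
        lab: int((label[is_cd8] == lab).sum())
        for lab in ("T-Tum cluster", "T-APC cluster", "unclustered")
    }
    summary = {
        "n_cd8": n_cd8,
        "counts": counts,
        "fractions": {
            lab: (c / n_cd8 if n_cd8 else float("nan")) for lab, c in counts.items()
        },
        "cutoff_um": cutoff_um,
    }
    return out, summary
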