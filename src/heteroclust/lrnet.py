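"""Rule-based ligand-receptor curation and sender/receiver assignment.

Curation keeps a pair iff its network weight exceeds 0.75, at least one
provenance branch holds (curated-annotation membership, experimental PPI
membership, weight > 0.9, or weight > 0.8 plus membership of a CellTalk-like
or SingleCellSignalR-like list) and the receptor's subcellular localization
mentions "cell membrane" or "surface".  Expression filtering and the
mean-plus-one-SD exclusivity rule assign each gene to a single cell-state
subgroup or to "unspecific".
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd

from .scquant import normalize_log1p

__all__ = [
    "curate_pairs",
    "expression_filter",
    "assign_subgroups",
    "T_STATE_MERGE",
    "merge_t_states",
    "activity_geneset",
]

LR_COLUMNS = (
    "ligand",
    "receptor",
    "weight",
    "in_annotation_db",
    "in_ppi",
    "in_celltalk_like",
    "in_scsr_like",
    "receptor_localization",
)

#: merge map from fine CD8 T cell states to the six receiver groups
T_STATE_MERGE = {
    "TOXhigh_Tex": "Tex",
    "GZMKhigh_Tex": "Tex",
    "LAG3high_Tex": "Tex",
    "TCF7_stemlike_Tex": "Tex",
    "Tex": "Tex",
    "MKI67high_Tex_Tprol": "Tprol",
    "MKI67_Tex_Tprol": "Tprol",
    "MKI67_Tem_NKlike_Tprol": "Tprol",
    "Tex_Tprol": "Tprol",
    "Tn": "Tn_Tmem",
    "Tn_Tmem": "Tn_Tmem",
    "Tem_early": "Tem",
    "Tem": "Tem",
    "Tem_NKlike": "Tem",
    "ISG": "ISG",
    "Tc17_MAIT": "Tc17_MAIT",
}

_LOC_KEY_TERMS = ("cell membrane", "surface")


def _localization_ok(loc) -> bool:
    if loc is None or (isinstance(loc, float) and np.isnan(loc)):
        return False
    s = str(loc).lower()
    return any(term in s for term in _LOC_KEY_TERMS)


def curate_pairs(db: pd.DataFrame) -> pd.DataFrame:
    """Apply the weight / provenance / localization curation rule.

    Keep a pair iff weight > 0.75 AND (in_annotation_db OR in_ppi OR
    weight > 0.9 OR (weight > 0.8 AND (in_celltalk_like OR in_scsr_like)))
    AND a localization term contains "cell membrane" or "surface"
    (case-insensitive substring).  Pairs with missing localization are
    dropped with a warning.
    """
    for col in LR_COLUMNS:
        if col not in db.columns:
            raise KeyError(f"missing column {col!r}")
    w = db["weight"].to_numpy(float)
    branch = (
        db["in_annotation_db"].to_numpy(bool)
        | db["in_ppi"].to_numpy(bool)
        | (w > 0.9)
        | ((w > 0.8) & (db["in_celltalk_like"].to_numpy(bool) | db["in_scsr_like"].to_numpy(bool)))
    )
    loc_ok = db["receptor_localization"].map(_localization_ok).to_numpy(bool)
    n_missing = int(db["receptor_localization"].isna().sum())
    if n_missing:
        warnings.warn(f"dropped {n_missing} pairs with missing localization", stacklevel=2)
    keep = (w > 0.75) & branch & loc_ok
    return db[keep].reset_index(drop=True)


def expression_filter(
    db: pd.DataFrame,
    expr: ad.AnnData,
    senders,
    receivers,
    min_pct: float = 0.10,
    min_pct_receiver: float | None = None,
    origin_col: str = "origin",
    cluster_origins: tuple[str, ...] = ("T-Tum cluster", "T-APC cluster"),
    restrict_to_clusters: bool = True,
) -> pd.DataFrame:
    """Drop pairs whose ligand/receptor is expressed in too few cells.

    An edge is kept iff the ligand has nonzero counts in at least ``min_pct``
    of sender cells and the receptor in at least ``min_pct_receiver``
    (default: same as ``min_pct``) of receiver cells; cells are restricted to
    cluster origins when ``restrict_to_clusters``.  ``senders`` / ``receivers``
    are boolean masks or index arrays over ``expr.obs``.  Adds
    ``pct_ligand_senders`` / ``pct_receptor_receivers`` columns.
    """
    genes = set(expr.var_names)
    needed = set(db["ligand"]) | set(db["receptor"])
    if not (needed & genes):
        raise ValueError("no ligand or receptor gene present in the expression data")
    if min_pct_receiver is None:
        min_pct_receiver = min_pct

    X = expr.X
    nz = np.asarray((X > 0).todense()) if hasattr(X, "todense") else (np.asarray(X) > 0)
    in_cluster = expr.obs[origin_col].isin(cluster_origins).to_numpy()

    def mask_of(sel) -> np.ndarray:
        m = np.zeros(expr.n_obs, dtype=bool)
        sel = np.asarray(sel)
        if sel.dtype == bool:
            m = sel.copy()
        else:
            m[expr.obs_names.get_indexer(sel)] = True
        if restrict_to_clusters:
            m &= in_cluster
        return m

    sm, rm = mask_of(senders), mask_of(receivers)
    if sm.sum() == 0 or rm.sum() == 0:
        raise ValueError("sender/receiver cell sets are empty")
    gi = {g: i for i, g in enumerate(expr.var_names)}

    def pct(gene: str, m: np.ndarray) -> float:
        if gene not in gi:
            return 0.0
        return float(nz[m, gi[gene]].mean())

    out = db.copy()
    out["pct_ligand_senders"] = [pct(g, sm) for g in out["ligand"]]
    out["pct_receptor_receivers"] = [pct(g, rm) for g in out["receptor"]]
    keep = (out["pct_ligand_senders"] >= min_pct) & (
        out["pct_receptor_receivers"] >= min_pct_receiver
    )
    return out[keep].reset_index(drop=True)


def merge_t_states(states: pd.Series, merge_map: dict[str, str] | None = None) -> pd.Series:
    """Collapse fine T cell states into the six merged receiver groups."""
    merge_map = merge_map or T_STATE_MERGE
    return states.map(lambda s: merge_map.get(s, s))


def assign_subgroups(
    subgroup_means: dict[str, float] | pd.Series,
    population_sd: bool = True,
) -> str:
    """Assign a gene to the one subgroup exceeding mean + 1 SD, else "unspecific".

    The threshold is the mean plus one standard deviation (population SD by
    default) of the per-subgroup average expressions.  Exactly one subgroup
    above the threshold wins; zero or several above mean the gene is shared
    ("unspecific").  A single subgroup is unspecific by convention.
    """
    s = pd.Series(subgroup_means, dtype=float)
    if len(s) < 1:
        raise ValueError("need at least one subgroup")
    if len(s) == 1:
        warnings.warn("single subgroup: assignment is unspecific by convention", stacklevel=2)
        return "unspecific"
    thr = s.mean() + s.std(ddof=0 if population_sd else 1)
    above = s.index[s > thr]
    return str(above[0]) if len(above) == 1 else "unspecific"


def activity_geneset(
    de: pd.DataFrame,
    max_p_adj: float = 0.05,
    min_log2fc: float = 0.1,
    min_pct: float = 0.05,
) -> list[str]:
    """Upregulated-gene set exported for external ligand-activity scorers.

    Filters a differential-expression table to genes with adjusted P below
    ``max_p_adj``, log2 fold change above ``min_log2fc`` and expression in
    more than ``min_pct`` of the interacting group.
    """
    keep = (
        (de["p_adj"] < max_p_adj)
        & (de["avg_log2FC"] > min_log2fc)
        & (de["pct_group1"] > min_pct)
    )
    return de.loc[keep, "gene"].tolist()
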