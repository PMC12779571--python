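"""Cluster-signature construction, ranking-AUC cell scoring and tertile
responder stratification.

The cluster signature is built from cluster-vs-singlet differential
expression: genes with -log10 adjusted P above a threshold and expressed in
more than 30% of cluster-origin cells are reordered by average log2 fold
change and truncated to the requested sizes (30 and 100 by default).  Cells
are scored for a signature by the area under the recovery curve of signature
genes within the top fraction of the cell's expression ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .scquant import CLUSTER_ORIGINS, normalize_log1p

__all__ = [
    "GeneSignature",
    "differential_expression",
    "build_cluster_signature",
    "score_cells_auc",
    "tertile_response_analysis",
]


@dataclass
class GeneSignature:
    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")

    @classmethod
    def load(cls, path, name: str | None = None) -> "GeneSignature":
        with open(path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return cls(name=name or str(path), genes=genes)


def _wilcoxon_de(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Default per-gene test: two-sided Mann-Whitney on normalized expression."""
    if np.ptp(np.concatenate([x1, x2])) == 0:
        return 0.0, 1.0  # zero-variance gene: p = 1 by convention
    p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
    eps = 1e-9
    lfc = float(np.log2((x1.mean() + eps) / (x2.mean() + eps)))
    return lfc, p


def differential_expression(
    ds: ad.AnnData,
    contrast_col: str = "origin",
    cluster_origins: tuple[str, ...] = CLUSTER_ORIGINS,
    method=None,
) -> pd.DataFrame:
    """Cluster-vs-singlet differential expression, one row per gene.

    The default method is a per-gene two-sided Wilcoxon rank-sum test on
    log-normalized expression with Bonferroni adjustment; ``method`` may be
    any callable ``(x_cluster, x_singlet) -> (log2FC, p)``.  ``pct_group1`` /
    ``pct_group2`` are the fractions of cluster / singlet cells with nonzero
    expression.  Positive log2FC means higher in cluster-origin cells.
    """
    in_cluster = ds.obs[contrast_col].isin(cluster_origins).to_numpy()
    if in_cluster.sum() == 0 or (~in_cluster).sum() == 0:
        raise ValueError("both contrast groups must be non-empty")
    expr = normalize_log1p(ds)
    x1, x2 = expr[in_cluster], expr[~in_cluster]
    test = method or _wilcoxon_de
    rows = []
    if method is None:
        # vectorized fast path for the built-in test
        const = np.ptp(expr, axis=0) == 0
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x1, x2, alternative="two-sided", axis=0)
        pvals = np.where(const, 1.0, res.pvalue)
        eps = 1e-9
        lfcs = np.log2((x1.mean(axis=0) + eps) / (x2.mean(axis=0) + eps))
        lfcs = np.where(const, 0.0, lfcs)
    else:
        pvals = np.empty(ds.n_vars)
        lfcs = np.empty(ds.n_vars)
        for j in range(ds.n_vars):
            lfcs[j], pvals[j] = test(x1[:, j], x2[:, j])
    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)
    out = pd.DataFrame(
        {
            "gene": list(ds.var_names),
            "avg_log2FC": lfcs,
            "p": pvals,
            "p_adj": np.minimum(1.0, pvals * ds.n_vars),
            "pct_group1": pct1,
            "pct_group2": pct2,
        }
    )
    return out


def build_cluster_signature(
    de: pd.DataFrame,
    neglog10p_min: float = 150.0,
    min_pct_clusters: float = 0.30,
    sizes: tuple[int, ...] = (30, 100),
    name_prefix: str = "cluster",
) -> dict[int, GeneSignature]:
    """Top-gene signatures from a differential-expression table.

    Genes with -log10(adjusted P) above ``neglog10p_min`` and expressed in
    more than ``min_pct_clusters`` of cluster cells are preselected, reordered
    by descending average log2 fold change (ties broken by gene name for
    determinism) and truncated to each requested size.  If fewer genes
    qualify than a requested size, all qualifying genes are returned with a
    warning.
    """
    for col in ("gene", "avg_log2FC", "p_adj", "pct_group1"):
        if col not in de.columns:
            raise KeyError(f"missing DE column {col!r}")
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(de["p_adj"].to_numpy(float))
    qual = de[(neglogp > neglog10p_min) & (de["pct_group1"] > min_pct_clusters)]
    ordered = qual.sort_values(
        ["avg_log2FC", "gene"], ascending=[False, True], kind="mergesort"
    )["gene"].tolist()
    out = {}
    for size in sorted(sizes):
        if len(ordered) < size:
            warnings.warn(
                f"only {len(ordered)} qualifying genes for requested size {size}",
                stacklevel=2,
            )
        out[size] = GeneSignature(name=f"{name_prefix}{size}", genes=ordered[:size])
    return out


def score_cells_auc(
    ds: ad.AnnData,
    sig: GeneSignature,
    top_fraction: float = 0.05,
) -> pd.Series:
    """Per-cell ranking-AUC score of a gene signature, in [0, 1].

    Genes are ranked per cell by decreasing expression (ties broken by the
    fixed gene order of the dataset); the score is the area under the
    recovery curve of signature genes within the top ``top_fraction`` of the
    ranking, normalized so that a cell whose top ranks are exactly the
    signature genes scores 1.
    """
    present = [g for g in sig.genes if g in set(ds.var_names)]
    if not present:
        raise ValueError("no signature gene present in the dataset")
    expr = normalize_log1p(ds)
    n_cells, n_genes = expr.shape
    t = max(1, int(round(top_fraction * n_genes)))
    sig_ix = np.array([list(ds.var_names).index(g) for g in present])
    is_sig = np.zeros(n_genes, dtype=bool)
    is_sig[sig_ix] = True

    # stable argsort on -expr keeps the fixed gene order among ties
    order = np.argsort(-expr, axis=1, kind="stable")
    in_top = is_sig[order[:, :t]]  # (cells, t): signature hit at each rank
    # recovery curve: cumulative hits over ranks 1..t; AUC = sum of cumcounts
    cum = np.cumsum(in_top, axis=1)
    auc = cum.sum(axis=1).astype(float)
    m = min(len(present), t)
    max_auc = float(np.arange(t - m + 1, t + 1).sum())  # all hits at the top
    return pd.Series(auc / max_auc, index=ds.obs_names, name=sig.name)


def tertile_response_analysis(
    scores: pd.Series,
    patients: pd.Series,
    responses: pd.Series,
) -> dict:
    """Stratify per-cell scores into pooled tertiles and compare responders.

    Tertile boundaries come from the pooled score distribution across all
    cells; each patient contributes the fraction of its cells per tertile;
    responder (R) vs non-responder (NR) patients are compared per tertile by
    two-sided unpaired t-test.  ``responses`` maps patient -> 'R'/'NR'.
    """
    scores = scores.astype(float)
    if np.ptp(scores.to_numpy()) == 0:
        raise ValueError("constant scores: tertiles undefined")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    tert = pd.cut(
        scores, [-np.inf, q1, q2, np.inf], labels=["low", "medium", "high"]
    )
    df = pd.DataFrame({"patient": patients.to_numpy(), "tertile": tert.to_numpy()})
    frac = (
        df.groupby("patient", observed=True)["tertile"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["low", "medium", "high"], fill_value=0.0)
    )
    resp = responses.reindex(frac.index)
    groups = resp.unique()
    tests = {}
    for tcol in ("low", "medium", "high"):
        r = frac.loc[resp == "R", tcol]
        nr = frac.loc[resp == "NR", tcol]
        if len(r) >= 2 and len(nr) >= 2:
            t, p = stats.ttest_ind(r, nr)
            tests[tcol] = {"t": float(t), "p": float(p)}
        else:
            tests[tcol] = {"t": float("nan"), "p": float("nan")}
    return {
        "boundaries": (float(q1), float(q2)),
        "fractions": frac,
        "response": resp,
        "tests": tests,
        "groups": list(map(str, groups)),
    }
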