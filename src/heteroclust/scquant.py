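"""Single-cell pipeline stages for cluster-vs-singlet T cell comparisons.

Quality-control filtering, hashtag demultiplexing by density local minima,
equal-patient-weighted cell-state frequencies, binomial mixed-model abundance
tests (with a stratified permutation oracle), neighbour-smoothed CD39 status
calls and paired alpha/beta clonotype analytics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

from .glmm import GLMMResult, fit_binomial_glmm, stratified_permutation_test

__all__ = [
    "qc_filter",
    "hashtag_demux",
    "state_frequencies_equalweight",
    "state_enrichment_test",
    "cd39_status",
    "clonotype_build",
    "clonotype_compare",
    "normalize_log1p",
]

CLUSTER_ORIGINS = ("T-Tum cluster", "T-APC cluster")
_CDR3_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def _counts(ds: ad.AnnData) -> sparse.csr_matrix:
    X = ds.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def normalize_log1p(ds: ad.AnnData, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` then log1p, returned dense (cells x genes)."""
    X = _counts(ds).astype(float)
    tot = np.asarray(X.sum(axis=1)).ravel()
    tot[tot == 0] = 1.0
    norm = X.multiply(scale / tot[:, None]).tocsr()
    return np.log1p(np.asarray(norm.todense()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    ds: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 8000,
    max_mito_pct: float = 15.0,
) -> tuple[ad.AnnData, dict]:
    """Drop cells by detected-gene count and mitochondrial fraction.

    A cell is kept iff its number of detected genes lies in
    [``min_genes``, ``max_genes``] and its mitochondrial read percentage is at
    most ``max_mito_pct``.  The report counts removals per criterion (a cell
    can fail several).
    """
    if "mito" not in ds.var.columns:
        raise KeyError("var must carry a boolean 'mito' column")
    X = _counts(ds)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(X[:, ds.var["mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito_counts / total, 0.0)

    too_few = n_genes < min_genes
    too_many = n_genes > max_genes
    too_mito = mito_pct > max_mito_pct
    keep = ~(too_few | too_many | too_mito)
    report = {
        "n_input": int(ds.n_obs),
        "n_kept": int(keep.sum()),
        "removed_low_genes": int(too_few.sum()),
        "removed_high_genes": int(too_many.sum()),
        "removed_mito": int(too_mito.sum()),
    }
    return ds[keep].copy(), report


# ---------------------------------------------------------------------------
# Hashtag demultiplexing
# ---------------------------------------------------------------------------


def _density_threshold(counts: np.ndarray) -> float:
    """Threshold at the lowest KDE local minimum between the two top modes.

    Operates on log1p counts.  Raises when the density has no interior local
    minimum (unimodal or degenerate channel).
    """
    x = np.log1p(counts.astype(float))
    if np.ptp(x) == 0:
        raise ValueError("degenerate hashtag channel (constant counts)")
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.where((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))[0]
    minima = np.where((np.hstack([d, 1]) > 0) & (np.hstack([-1, d]) < 0))[0]
    if len(maxima) < 2 or len(minima) == 0:
        raise ValueError(
            "hashtag density has no interior local minimum (unimodal channel); "
            f"found {len(maxima)} mode(s)"
        )
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(grid[top2])
    between = [m for m in minima if lo < grid[m] < hi]
    if not between:
        raise ValueError("no local minimum between the two highest modes")
    m = min(between, key=lambda i: dens[i])
    return float(np.expm1(grid[m]))


def hashtag_demux(hashtag_counts: pd.DataFrame) -> pd.Series:
    """Assign cells to hashtags from two bimodal count channels.

    Per channel a kernel-density estimate of log1p counts sets the positivity
    threshold at the lowest local minimum between the two highest modes.
    Cells above both thresholds are cross-sample doublets (removed); cells
    above neither are negative.
    """
    if hashtag_counts.shape[1] != 2:
        raise ValueError("expect exactly two hashtag channels")
    c1, c2 = (hashtag_counts.iloc[:, i].to_numpy(float) for i in (0, 1))
    t1 = _density_threshold(c1)
    t2 = _density_threshold(c2)
    p1, p2 = c1 > t1, c2 > t2
    names = list(hashtag_counts.columns)
    call = np.select(
        [p1 & p2, p1, p2],
        ["doublet-removed", names[0], names[1]],
        default="negative",
    )
    return pd.Series(call, index=hashtag_counts.index, name="hashtag_call")


# ---------------------------------------------------------------------------
# Cell-state frequencies & enrichment
# ---------------------------------------------------------------------------


def state_frequencies_equalweight(
    ds: ad.AnnData,
    group_by: str = "origin",
    state_col: str = "state",
    patient_col: str = "patient",
) -> pd.DataFrame:
    """Average per-patient cell-state frequencies per origin, patients weighted
    equally regardless of their cell numbers.

    Patients lacking an origin are omitted for that origin (logged via
    warning).  Rows (origins) sum to 1 over states.
    """
    obs = ds.obs
    out = {}
    for origin, d_or in obs.groupby(group_by, observed=True):
        per_patient = []
        for pat, d in d_or.groupby(patient_col, observed=True):
            per_patient.append(d[state_col].value_counts(normalize=True))
        missing = set(obs[patient_col].unique()) - set(d_or[patient_col].unique())
        if missing:
            warnings.warn(
                f"origin {origin!r}: patients {sorted(map(str, missing))} have no "
                "cells and are omitted",
                stacklevel=2,
            )
        freq = pd.concat(per_patient, axis=1).fillna(0.0).mean(axis=1)
        out[origin] = freq
    table = pd.DataFrame(out).T.fillna(0.0)
    table = table.reindex(sorted(table.columns), axis=1)
    return table


def state_enrichment_test(
    ds: ad.AnnData,
    states: list[str] | None = None,
    contrast_col: str = "origin",
    cluster_origins: tuple[str, ...] = CLUSTER_ORIGINS,
    state_col: str = "state",
    patient_col: str = "patient",
    with_permutation: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-vs-singlet differential abundance per cell state.

    For each state, membership is modelled with a binomial random-intercept
    GLMM: interaction status (cell from a cluster origin) as the fixed effect,
    patient as the random intercept.  P values are Bonferroni-adjusted over
    the tested states.  With ``with_permutation`` a stratified permutation
    test (shuffling interaction status within patient) is added as an oracle.
    """
    obs = ds.obs
    x = obs[contrast_col].isin(cluster_origins).to_numpy().astype(int)
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("both contrast levels must be present")
    groups = obs[patient_col].to_numpy()
    if states is None:
        states = sorted(obs[state_col].unique())
    rows = []
    for st in states:
        y = (obs[state_col] == st).to_numpy().astype(int)
        flagged = y.sum() == 0 or min(y[x == 1].sum(), y[x == 0].sum()) == 0
        res: GLMMResult = fit_binomial_glmm(y, x, groups)
        row = {
            "state": st,
            "log_odds": res.beta1,
            "se": res.se_beta1,
            "sigma": res.sigma,
            "p": res.p,
            "converged": res.converged,
            "separation": res.separation or flagged,
        }
        if with_permutation:
            row["p_perm"] = stratified_permutation_test(
                y, x, groups, n_perm=n_perm, seed=seed
            )["p"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adj"] = np.minimum(1.0, table["p"] * len(states))
    return table


# ---------------------------------------------------------------------------
# CD39 status
# ---------------------------------------------------------------------------


def cd39_status(
    ds: ad.AnnData,
    cd39_gene: str = "ENTPD1",
    k: int = 10,
    tau: float = 0.0,
    embedding: str = "X_embed",
    own_weight: float = 0.5,
) -> pd.Series:
    """Call per-cell CD39 status from neighbour-smoothed expression.

    The smoothed value mixes each cell's own normalized log expression with
    the average of its ``k`` nearest neighbours in the embedding
    (``own_weight`` on the cell itself); a cell is CD39+ iff the smoothed
    value exceeds ``tau``.  Averaging over neighbours rescues dropout-driven
    false negatives.
    """
    if cd39_gene not in ds.var_names:
        raise KeyError(f"gene {cd39_gene!r} absent from the dataset")
    if k >= ds.n_obs:
        raise ValueError("k must be smaller than the number of cells")
    if embedding in ds.obsm:
        coords = np.asarray(ds.obsm[embedding])
    else:
        # fall back to principal components of the normalized matrix
        from sklearn.decomposition import PCA

        expr_all = normalize_log1p(ds)
        n_comp = min(30, ds.n_obs - 1, ds.n_vars)
        coords = PCA(n_components=n_comp, random_state=0).fit_transform(expr_all)
    gi = list(ds.var_names).index(cd39_gene)
    expr = normalize_log1p(ds)[:, gi]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, ind = nn.kneighbors(coords)
    neigh_mean = expr[ind[:, 1:]].mean(axis=1)  # excludes the cell itself
    smoothed = own_weight * expr + (1 - own_weight) * neigh_mean
    call = np.where(smoothed > tau, "CD39+", "CD39-")
    return pd.Series(call, index=ds.obs_names, name="cd39_status")


# ---------------------------------------------------------------------------
# Clonotypes
# ---------------------------------------------------------------------------


def clonotype_build(tcr: pd.DataFrame) -> pd.DataFrame:
    """Build paired alpha/beta clonotypes from an AIRR-style chain table.

    The clonotype key concatenates the sorted set of alpha CDR3 amino-acid
    sequences and the sorted set of beta CDR3s, so cells with multiple alpha
    or beta chains form their own unique clonotype.  Cells missing either
    chain are excluded; rows with malformed CDR3 characters are rejected with
    a warning.

    Returns a table indexed by ``cell_id`` with columns ``clonotype`` and
    ``clonotype_size``.
    """
    for col in ("cell_id", "chain", "cdr3_aa"):
        if col not in tcr.columns:
            raise KeyError(f"missing column {col!r}")
    ok = tcr["cdr3_aa"].astype(str).str.match(_CDR3_RE)
    if (~ok).any():
        warnings.warn(f"rejected {int((~ok).sum())} rows with malformed CDR3", stacklevel=2)
    tcr = tcr[ok]
    keys = {}
    for cell, d in tcr.groupby("cell_id", sort=True, observed=True):
        alphas = sorted(set(d.loc[d["chain"] == "TRA", "cdr3_aa"]))
        betas = sorted(set(d.loc[d["chain"] == "TRB", "cdr3_aa"]))
        if not alphas or not betas:
            continue  # missing alpha or beta: excluded from clonotype analyses
        keys[cell] = "+".join(alphas) + "|" + "+".join(betas)
    out = pd.DataFrame({"clonotype": pd.Series(keys)})
    out.index.name = "cell_id"
    sizes = out["clonotype"].value_counts()
    out["clonotype_size"] = out["clonotype"].map(sizes).astype(int)
    return out


def _equal_weight_mean(values: pd.Series, patients: pd.Series) -> float:
    return float(values.groupby(patients, observed=True).mean().mean())


def clonotype_compare(
    clonotypes: pd.DataFrame,
    ds: ad.AnnData,
    scores: pd.Series | None = None,
    top_n: int = 15,
    min_cells: int = 10,
    top_per_patient: int = 10,
    origin_col: str = "origin",
    patient_col: str = "patient",
    cluster_origins: tuple[str, ...] = CLUSTER_ORIGINS,
) -> dict:
    """Clonotype expansion and matched-clonotype score comparisons.

    (i) Per patient, the frequency of the union of its ``top_n`` largest
    clonotypes within single vs clustered T cells, averaged with equal patient
    weights.  (ii) With per-cell ``scores``: clonotypes with at least
    ``min_cells`` cells in each cluster origin are compared between origins by
    mean score per clonotype (top ``top_per_patient`` clonotypes per patient by
    total size; ties broken by lexicographic key), two-sided paired Wilcoxon
    across the matched clonotypes; the per-clonotype mean-score matrix is also
    returned row z-scored.
    """
    obs = ds.obs[[patient_col, origin_col]].copy()
    obs = obs.join(clonotypes, how="inner")
    obs["clustered"] = obs[origin_col].isin(cluster_origins)

    # (i) top-clonotype frequencies
    per_patient = []
    for pat, d in obs.groupby(patient_col, observed=True):
        sizes = d["clonotype"].value_counts()
        order = sorted(sizes.index, key=lambda ct: (-sizes[ct], ct))
        top = set(order[:top_n])
        for clustered, dd in d.groupby("clustered"):
            per_patient.append(
                {
                    "patient": pat,
                    "group": "clustered" if clustered else "single",
                    "top_clonotype_freq": float(dd["clonotype"].isin(top).mean()),
                }
            )
    freq = pd.DataFrame(per_patient)
    freq_summary = (
        freq.groupby("group")["top_clonotype_freq"].mean().to_dict()
    )  # equal patient weight

    result: dict = {"top_freq_per_patient": freq, "top_freq_mean": freq_summary}

    # (ii) matched-clonotype score comparison between the two cluster origins
    if scores is not None:
        d = obs[obs[origin_col].isin(cluster_origins)].copy()
        d["score"] = scores.reindex(d.index).to_numpy()
        counts = d.pivot_table(
            index="clonotype", columns=origin_col, values="score",
            aggfunc="count", fill_value=0, observed=True,
        )
        eligible = counts.index[(counts[list(cluster_origins)] >= min_cells).all(axis=1)]
        if len(eligible) == 0:
            result["matched"] = None
            result["matched_report"] = "no clonotype meets min_cells in every cluster origin"
            return result
        d = d[d["clonotype"].isin(eligible)]
        picked = []
        for pat, dd in d.groupby(patient_col, observed=True):
            sizes = dd["clonotype"].value_counts()
            order = sorted(sizes.index, key=lambda ct: (-sizes[ct], ct))
            picked.extend((pat, ct) for ct in order[:top_per_patient])
        keep = {ct for _, ct in picked}
        d = d[d["clonotype"].isin(keep)]
        means = d.pivot_table(
            index="clonotype", columns=origin_col, values="score",
            aggfunc="mean", observed=True,
        )[list(cluster_origins)].dropna()
        a, b = means.iloc[:, 0], means.iloc[:, 1]
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        z = means.sub(means.mean(axis=1), axis=0).div(
            means.std(axis=1, ddof=0).replace(0.0, 1.0), axis=0
        )
        result["matched"] = means
        result["matched_z"] = z
        result["matched_p"] = p
        result["n_matched"] = int(len(means))
    return result
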