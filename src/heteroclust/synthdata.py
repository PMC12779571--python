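"""Synthetic-data generators with planted ground truth.

Every generator here emulates one input modality of the heterotypic-cluster
analyses: flow-cytometry event tables from T cell / tumour cell competition
co-cultures, imaging-flow-cytometry doublet images with an immune-synapse
marker, multiplex-IF centroid tables, single-cell RNA/TCR datasets with
patients as batches, and ligand-receptor network tables.

All generators are pure functions of their arguments: the same seed produces
byte-identical output.  Planted truth travels with the data (extra columns,
mask lists, ``AnnData.uns``/``obs`` entries) so downstream operators can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import binary_dilation, binary_erosion

__all__ = [
    "CompetitionTruth",
    "SynapseTruth",
    "SCTruth",
    "MultiChannelImage",
    "gen_competition_events",
    "gen_synapse_images",
    "gen_centroid_table",
    "gen_sc_dataset",
    "gen_lr_tables",
    "default_sc_truth",
]

# Lognormal intensity model: "negative" and "positive" marker populations
# separated by far more than 3 SD in log space, so threshold gating on
# synthetic data is unambiguous.
_NEG_LOG_MEAN, _NEG_LOG_SD = np.log(10.0), 0.35
_POS_LOG_MEAN, _POS_LOG_SD = np.log(1000.0), 0.35


def _positive(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.lognormal(_POS_LOG_MEAN, _POS_LOG_SD, n)


def _negative(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.lognormal(_NEG_LOG_MEAN, _NEG_LOG_SD, n)


# ---------------------------------------------------------------------------
# Competition events
# ---------------------------------------------------------------------------


@dataclass
class CompetitionTruth:
    """Planted parameters of a competition co-culture experiment."""

    input_specific_fraction: float
    planted_fold_change: float
    cluster_fraction: float
    #: specificity probability among clustered T cells after clamping at 1
    q_cluster: float = 0.0
    #: True when planted_fold_change x input_specific_fraction exceeded 1
    clamped: bool = False


def gen_competition_events(
    n_tumour: int,
    n_t: int,
    input_specific_fraction: float,
    planted_fold_change: float,
    cluster_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, CompetitionTruth]:
    """Simulate flow events from a tumour cell + mixed T cell co-culture.

    A fraction ``cluster_fraction`` of T cells is conjugated to a tumour cell
    (a double-positive event); the rest are T singlets.  Singlet T cells are
    antigen-specific with probability ``q_s = input_specific_fraction`` and
    clustered T cells with ``q_c = min(1, planted_fold_change * q_s)``; if the
    product exceeds 1 the value is clamped and flagged on the returned truth.

    Returns an event table (one row per flow event) and the planted truth.
    """
    if not (0.0 <= input_specific_fraction <= 1.0):
        raise ValueError("input_specific_fraction must be in [0, 1]")
    if not (0.0 <= cluster_fraction <= 1.0):
        raise ValueError("cluster_fraction must be in [0, 1]")
    if planted_fold_change <= 0:
        raise ValueError("planted_fold_change must be positive")
    if n_t < 100:
        raise ValueError("need at least 100 T cells")

    rng = np.random.default_rng(seed)
    n_clusters = int(round(cluster_fraction * n_t))
    n_clusters = min(n_clusters, n_tumour)  # each cluster consumes a tumour cell
    n_t_singlet = n_t - n_clusters
    n_tum_singlet = n_tumour - n_clusters

    q_s = input_specific_fraction
    q_c_raw = planted_fold_change * q_s
    clamped = q_c_raw > 1.0
    q_c = min(1.0, q_c_raw)

    pops = (
        ["T-singlet"] * n_t_singlet
        + ["tumour-singlet"] * n_tum_singlet
        + ["T-tumour cluster"] * n_clusters
    )
    n = len(pops)
    pop = np.asarray(pops)
    is_t = pop == "T-singlet"
    is_tum = pop == "tumour-singlet"
    is_clu = pop == "T-tumour cluster"

    t_label = np.where(is_t | is_clu, _positive(rng, n), _negative(rng, n))
    tum_label = np.where(is_tum | is_clu, _positive(rng, n), _negative(rng, n))

    specific = np.zeros(n, dtype=bool)
    specific[is_t] = rng.random(is_t.sum()) < q_s
    specific[is_clu] = rng.random(is_clu.sum()) < q_c
    spec_marker = np.where(specific, _positive(rng, n), _negative(rng, n))

    # Scatter surrogates.  Per-cell "height" is size-like; singlet area tracks
    # height, a doublet's area is the sum of its members' areas while its
    # height is the max -- so doublets fall off the area~height diagonal.
    h_cell = rng.lognormal(np.log(100.0), 0.08, n)
    area = h_cell * (1.0 + rng.normal(0.0, 0.03, n))
    height = h_cell.copy()
    h2 = rng.lognormal(np.log(100.0), 0.08, n)
    a2 = h2 * (1.0 + rng.normal(0.0, 0.03, n))
    area[is_clu] = area[is_clu] + a2[is_clu]
    height[is_clu] = np.maximum(height[is_clu], h2[is_clu])

    events = pd.DataFrame(
        {
            "event_id": np.arange(n),
            "t_label": t_label,
            "tumour_label": tum_label,
            "specific_marker": spec_marker,
            "scatter_area": area,
            "scatter_height": height,
            "truth_population": pop,
            "truth_specific": specific.astype(int),
        }
    )
    # stable shuffle so population blocks are interleaved as on a cytometer
    events = events.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
        drop=True
    )
    truth = CompetitionTruth(
        input_specific_fraction=q_s,
        planted_fold_change=planted_fold_change,
        cluster_fraction=cluster_fraction,
        q_cluster=q_c,
        clamped=clamped,
    )
    return events, truth


# ---------------------------------------------------------------------------
# Synapse images
# ---------------------------------------------------------------------------


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels sharing one shape, with pixel size in um."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    object_id: int = 0

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SynapseTruth:
    """Ground truth for generated doublet/singlet images."""

    relocalization_strength: float
    #: per-image integer mask (0 background, 1 = T cell, 2 = tumour cell)
    label_masks: list[np.ndarray] = field(default_factory=list)
    #: per-image boolean mask of the T-cell interface membrane arc
    interface_masks: list[np.ndarray] = field(default_factory=list)
    #: per-image flag: True for doublets, False for singlets
    is_doublet: list[bool] = field(default_factory=list)


def _disk_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def shared_boundary_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixels of either mask 8-adjacent to the other: the contact line."""
    s3 = np.ones((3, 3), dtype=bool)
    return (a & binary_dilation(b, s3)) | (b & binary_dilation(a, s3))


def _disk_selem(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def gen_synapse_images(
    n_doublets: int,
    n_singlets: int,
    relocalization_strength: float,
    pixel_size_um: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    radius_range: tuple[int, int] = (10, 14),
    membrane_band_px: int = 6,
    interface_reach_px: int = 6,
    blur_sigma: float = 1.0,
) -> tuple[list[MultiChannelImage], SynapseTruth]:
    """Generate touching T cell / tumour cell doublets with a synapse marker.

    Each doublet image holds two touching disks of different cell types
    (overlap pixels resolved to the nearer centre): a textured bright-field
    surrogate, one type-marker channel per cell type, and a synapse-marker
    channel on the T cell's membrane band (``membrane_band_px`` wide, starting
    one pixel inside the cell boundary, as a membrane stain images at this
    pixel scale).  The marker mass is a mixture: weight
    ``1 - relocalization_strength`` spread uniformly over the whole band plus
    weight ``relocalization_strength`` concentrated on the contact arc (band
    pixels within ``interface_reach_px`` of the shared T/tumour boundary
    line).  Strength 0 is therefore a uniform membrane stain and strength 1 a
    fully relocalized one.  A light Gaussian blur (``blur_sigma``) emulates
    finite imaging resolution.
    """
    if not (0.0 <= relocalization_strength <= 1.0):
        raise ValueError("relocalization_strength must be in [0, 1]")
    rmax = radius_range[1]
    if 2 * (2 * rmax + 4) > min(shape):
        raise ValueError("image too small to fit two cells of the given radius")

    from scipy.ndimage import gaussian_filter
    from scipy.ndimage import grey_dilation as ndi_grey_dilation

    rng = np.random.default_rng(seed)
    s = relocalization_strength
    images: list[MultiChannelImage] = []
    truth = SynapseTruth(relocalization_strength=s)
    yy, xx = np.mgrid[: shape[0], : shape[1]]

    for i in range(n_doublets + n_singlets):
        doublet = i < n_doublets
        cy, cx = shape[0] // 2, shape[1] // 2
        r1 = int(rng.integers(radius_range[0], radius_range[1] + 1))
        if doublet:
            r2 = int(rng.integers(radius_range[0], radius_range[1] + 1))
            theta = rng.uniform(0, 2 * np.pi)
            # slight overlap guarantees a contact arc several pixels long
            d = r1 + r2 - 3
            c1 = (cy - d / 2 * np.sin(theta), cx - d / 2 * np.cos(theta))
            c2 = (cy + d / 2 * np.sin(theta), cx + d / 2 * np.cos(theta))
            d1 = (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2
            d2 = (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2
            in1, in2 = d1 <= r1**2, d2 <= r2**2
            m1 = in1 & (~in2 | (d1 <= d2))
            m2 = in2 & ~m1
        else:
            m1 = _disk_mask(shape, cy, cx, r1)
            m2 = np.zeros(shape, dtype=bool)

        cells = m1 | m2
        bf = 100.0 + rng.normal(0.0, 8.0, shape)
        bf[cells] += 60.0 + rng.normal(0.0, 15.0, int(cells.sum()))
        ch = {"brightfield": np.clip(bf, 0, None)}
        t_marker = np.full(shape, 5.0) + rng.normal(0.0, 1.0, shape)
        t_marker[m1] += 800.0 + rng.normal(0.0, 40.0, int(m1.sum()))
        tum_marker = np.full(shape, 5.0) + rng.normal(0.0, 1.0, shape)
        tum_marker[m2] += 800.0 + rng.normal(0.0, 40.0, int(m2.sum()))
        ch["t_marker"] = np.clip(t_marker, 0, None)
        ch["tumour_marker"] = np.clip(tum_marker, 0, None)

        # membrane band of the T cell, one pixel inside its boundary
        inner = binary_erosion(m1, _disk_selem(1))
        band = inner & ~binary_erosion(inner, _disk_selem(membrane_band_px))
        if doublet:
            line = shared_boundary_mask(m1, m2)
            reach = np.ones((2 * interface_reach_px + 1,) * 2, dtype=bool)
            near = binary_dilation(line, reach)
            interface = band & near
            noninterface = band & ~near
        else:
            interface = np.zeros(shape, dtype=bool)
            noninterface = band

        syn = np.zeros(shape)
        total_mass = 2.0e4
        n_int, n_non = int(interface.sum()), int(noninterface.sum())
        n_band = n_int + n_non
        if doublet and n_int > 0 and n_band > 0:
            # uniform component (weight 1-s) + relocalized component (weight s)
            syn[interface] += total_mass * (s / n_int + (1.0 - s) / n_band)
            if n_non > 0:
                syn[noninterface] += total_mass * (1.0 - s) / n_band
        else:
            syn[band] += total_mass / max(int(band.sum()), 1)
        # soft outer edge: the boundary row renders at half density, as a
        # sub-pixel membrane edge does at this resolution
        edge = m1 & ~inner
        if edge.any():
            dil = ndi_grey_dilation(syn, footprint=np.ones((3, 3)))
            syn[edge] = 0.5 * dil[edge]
        syn = gaussian_filter(syn, blur_sigma) + np.abs(rng.normal(2.0, 0.5, shape))
        ch["synapse_marker"] = syn

        images.append(MultiChannelImage(channels=ch, pixel_size_um=pixel_size_um, object_id=i))
        lab = np.zeros(shape, dtype=np.int32)
        lab[m1] = 1
        lab[m2] = 2
        truth.label_masks.append(lab)
        truth.interface_masks.append(interface)
        truth.is_doublet.append(doublet)

    return images, truth


# ---------------------------------------------------------------------------
# Centroid tables
# ---------------------------------------------------------------------------


def gen_centroid_table(
    n_cells: int,
    class_proportions: dict[str, float] | None = None,
    niche_fraction: float = 0.3,
    field_size_um: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
    min_spacing_um: float = 12.0,
    niche_distance_um: tuple[float, float] = (4.0, 9.0),
) -> pd.DataFrame:
    """Scatter cell centroids over a tissue field with planted CD8 niches.

    A fraction ``niche_fraction`` of CD8 cells is placed within 10 um of a
    tumour or CD11c anchor (alternating), truth-labelled T-Tum / T-APC; all
    other placements respect ``min_spacing_um`` so non-niche CD8 cells are
    unambiguously unclustered.  A fixed block of multi-positive rows covering
    every marker-reclassification rule is appended at the end of the table.
    """
    if class_proportions is None:
        class_proportions = {"Tumour": 0.4, "CD8": 0.4, "CD11c": 0.2}
    if abs(sum(class_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if not (0.0 <= niche_fraction <= 1.0):
        raise ValueError("niche_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    fx, fy = field_size_um
    classes = list(class_proportions)
    counts = {c: int(round(class_proportions[c] * n_cells)) for c in classes}

    placed_xy: list[tuple[float, float]] = []
    rows: list[dict] = []

    def try_place(min_d: float, max_tries: int = 2000) -> tuple[float, float]:
        grid = np.asarray(placed_xy) if placed_xy else None
        for _ in range(max_tries):
            x, y = rng.uniform(0, fx), rng.uniform(0, fy)
            if grid is None or len(grid) == 0:
                return x, y
            d2 = (grid[:, 0] - x) ** 2 + (grid[:, 1] - y) ** 2
            if d2.min() >= min_d**2:
                return x, y
        raise RuntimeError(
            "cell density too high to control planted distances; "
            "reduce n_cells or min_spacing_um"
        )

    def add(x, y, cls, sox, cd8, cd11c, truth):
        placed_xy.append((x, y))
        rows.append(
            {
                "cell_id": len(rows),
                "x_um": x,
                "y_um": y,
                "sox10_hmb45": sox,
                "cd8": cd8,
                "cd11c": cd11c,
                "truth_class": cls,
                "truth_cluster": truth,
            }
        )

    # anchors first: tumour and APC cells
    anchors: dict[str, list[tuple[float, float]]] = {"Tumour": [], "CD11c": []}
    for cls, sox, cd8, cd11c in (("Tumour", 1, 0, 0), ("CD11c", 0, 0, 1)):
        for _ in range(counts.get(cls, 0)):
            x, y = try_place(min_spacing_um)
            anchors[cls].append((x, y))
            add(x, y, cls, sox, cd8, cd11c, "none")

    n_cd8 = counts.get("CD8", 0)
    n_niche = int(round(niche_fraction * n_cd8))
    for j in range(n_cd8):
        if j < n_niche and (anchors["Tumour"] or anchors["CD11c"]):
            kind = "Tumour" if (j % 2 == 0 and anchors["Tumour"]) or not anchors["CD11c"] else "CD11c"
            ax, ay = anchors[kind][int(rng.integers(len(anchors[kind])))]
            for _ in range(200):
                r = rng.uniform(*niche_distance_um)
                th = rng.uniform(0, 2 * np.pi)
                x, y = ax + r * np.cos(th), ay + r * np.sin(th)
                if 0 <= x <= fx and 0 <= y <= fy:
                    break
            add(x, y, "CD8", 0, 1, 0, "T-Tum cluster" if kind == "Tumour" else "T-APC cluster")
        else:
            x, y = try_place(min_spacing_um)
            add(x, y, "CD8", 0, 1, 0, "unclustered")

    # planted multi-positive rows, far corner, exercising every rule branch
    extras = [
        ("Tumour+CD8", 1, 1, 0),
        ("Tumour+CD8+CD11c", 1, 1, 1),
        ("Tumour+CD11c", 1, 0, 1),
        ("CD8+CD11c", 0, 1, 1),
        ("negative", 0, 0, 0),
    ]
    for k, (name, sox, cd8, cd11c) in enumerate(extras):
        add(fx - 1.0 - 20.0 * k, fy - 1.0, name, sox, cd8, cd11c, "none")

    table = pd.DataFrame(rows)
    # niche CD8 truth may be ambiguous if the placement landed near the other
    # anchor type as well; resolve with the same geometric rule used downstream
    cd8_rows = table["cd8"].eq(1) & table["sox10_hmb45"].eq(0) & table["cd11c"].eq(0)
    tum_xy = table.loc[table["truth_class"].eq("Tumour"), ["x_um", "y_um"]].to_numpy()
    apc_xy = table.loc[table["truth_class"].eq("CD11c"), ["x_um", "y_um"]].to_numpy()
    for idx in table.index[cd8_rows]:
        x, y = table.at[idx, "x_um"], table.at[idx, "y_um"]
        d_tum = np.sqrt(((tum_xy - [x, y]) ** 2).sum(axis=1)).min() if len(tum_xy) else np.inf
        d_apc = np.sqrt(((apc_xy - [x, y]) ** 2).sum(axis=1)).min() if len(apc_xy) else np.inf
        if d_tum < 10.0:
            table.at[idx, "truth_cluster"] = "T-Tum cluster"
        elif d_apc < 10.0:
            table.at[idx, "truth_cluster"] = "T-APC cluster"
        else:
            table.at[idx, "truth_cluster"] = "unclustered"
    return table


# ---------------------------------------------------------------------------
# Single-cell dataset
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SCTruth:
    """Planted structure of a synthetic single-cell dataset."""

    #: baseline cell-state proportions (sum to 1)
    state_props: dict[str, float]
    #: per-state log-odds shift applied to cells from cluster origins
    enrichment_logodds: dict[str, float]
    #: fractions of cells per origin label
    origin_props: dict[str, float]
    #: SD of the per-patient random intercept on state log-abundance
    patient_sigma: float = 0.3
    #: exponent of the power-law clonotype size distribution
    clonotype_exponent: float = 1.5
    #: extra log-weight of expanded clonotypes in cluster-origin cells
    clonotype_cluster_bias: float = 1.0
    #: probability that a truly CD39+ cell's ENTPD1 count drops to zero
    cd39_dropout: float = 0.3
    #: states whose cells are truly CD39 positive
    cd39_states: tuple[str, ...] = ("Tex", "Tex_Tprol")
    #: planted log2 fold changes (cluster vs singlet origins), gene -> lfc
    de_log2fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.state_props.values()) - 1.0) > 1e-6:
            raise ValueError("state proportions must sum to 1")
        if abs(sum(self.origin_props.values()) - 1.0) > 1e-6:
            raise ValueError("origin proportions must sum to 1")
        unknown = set(self.enrichment_logodds) - set(self.state_props)
        if unknown:
            raise ValueError(f"enrichment log-odds for unknown states: {unknown}")


def default_sc_truth(
    n_de_genes: int = 40, de_log2fc: float = 2.0, enrichment: float | None = None
) -> SCTruth:
    """Default study conditions: 8 CD8 states, exhausted/proliferating states
    enriched in cluster origins, naive/memory states depleted."""
    states = {
        "Tn": 0.18,
        "Tn_Tmem": 0.12,
        "Tem_early": 0.12,
        "Tem": 0.18,
        "Tex": 0.15,
        "Tex_Tprol": 0.10,
        "ISG": 0.07,
        "Tc17_MAIT": 0.08,
    }
    logodds = {
        "Tex": 1.0 if enrichment is None else enrichment,
        "Tex_Tprol": 0.8 if enrichment is None else enrichment,
        "Tn": -0.8 if enrichment is None else 0.0,
        "Tem": -0.5 if enrichment is None else 0.0,
    }
    origins = {"T-singlet": 0.5, "T-Tum cluster": 0.25, "T-APC cluster": 0.25}
    de = {f"DEG{i:04d}": de_log2fc for i in range(n_de_genes)}
    return SCTruth(
        state_props=states,
        enrichment_logodds=logodds,
        origin_props=origins,
        de_log2fc=de,
    )


def _random_cdr3(rng: np.random.Generator, length_range=(10, 16)) -> str:
    n = int(rng.integers(*length_range))
    return "C" + "".join(rng.choice(list(_AA), n - 2)) + "F"


def gen_sc_dataset(
    n_patients: int,
    cells_per_patient: int,
    n_genes: int,
    sc_truth: SCTruth | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a CD8 single-cell dataset with paired TCR table.

    Counts are negative binomial with state/origin-specific means; cell-state
    abundance carries patient random intercepts and planted cluster-origin
    enrichment; clonotype sizes are power-law with expanded clonotypes biased
    toward cluster origins; the ENTPD1 (CD39) gene suffers planted dropout;
    two hashtag channels are bimodal.  Truth lives in ``obs`` columns prefixed
    ``truth_`` and in ``uns['truth']``.

    Returns the AnnData (cells x genes, sparse counts) and an AIRR-style TCR
    table with columns ``cell_id``, ``chain``, ``cdr3_aa``.
    """
    if sc_truth is None:
        sc_truth = default_sc_truth()
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if len(sc_truth.origin_props) < 2:
        raise ValueError("need at least 2 origins")

    rng = np.random.default_rng(seed)
    states = list(sc_truth.state_props)
    base_logp = np.log(np.asarray([sc_truth.state_props[s] for s in states]))
    origins = list(sc_truth.origin_props)
    origin_p = np.asarray([sc_truth.origin_props[o] for o in origins])
    cluster_origins = [o for o in origins if "cluster" in o]

    n_cells = n_patients * cells_per_patient
    patient = np.repeat([f"P{i + 1}" for i in range(n_patients)], cells_per_patient)
    origin = rng.choice(origins, size=n_cells, p=origin_p)
    is_cluster = np.isin(origin, cluster_origins)

    shift = np.asarray([sc_truth.enrichment_logodds.get(s, 0.0) for s in states])
    state = np.empty(n_cells, dtype=object)
    for i, p in enumerate(np.unique(patient)):
        u = rng.normal(0.0, sc_truth.patient_sigma, len(states))
        for clustered in (False, True):
            mask = (patient == p) & (is_cluster == clustered)
            logits = base_logp + u + (shift if clustered else 0.0)
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            state[mask] = rng.choice(states, size=int(mask.sum()), p=probs)

    # --- genes -------------------------------------------------------------
    mito_genes = [f"MT-GENE{i}" for i in range(5)]
    de_genes = list(sc_truth.de_log2fc)
    if len(de_genes) + len(mito_genes) + 1 > n_genes:
        raise ValueError("n_genes too small for the planted gene sets")
    n_filler = n_genes - len(de_genes) - len(mito_genes) - 1
    genes = de_genes + ["ENTPD1"] + mito_genes + [f"G{i:05d}" for i in range(n_filler)]

    base_mu = rng.lognormal(np.log(0.3), 1.0, n_genes)
    base_mu = np.clip(base_mu, 0.01, 50.0)
    mu = np.tile(base_mu, (n_cells, 1))
    lfc = np.array([sc_truth.de_log2fc.get(g, 0.0) for g in genes])
    mu[is_cluster] *= 2.0 ** lfc

    entpd1_ix = genes.index("ENTPD1")
    cd39_true = np.isin(state, list(sc_truth.cd39_states))
    mu[:, entpd1_ix] = np.where(cd39_true, 3.0, 0.02)
    mito_ix = [genes.index(g) for g in mito_genes]
    mu[:, mito_ix] = 1.0  # ~constant housekeeping-like mitochondrial load

    theta = 2.0  # NB dispersion: var = mu + mu^2/theta
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam)

    # planted dropout on ENTPD1 for truly positive cells
    drop = cd39_true & (rng.random(n_cells) < sc_truth.cd39_dropout)
    counts[drop, entpd1_ix] = 0

    # --- embedding: one Gaussian blob per state ----------------------------
    angles = np.linspace(0, 2 * np.pi, len(states), endpoint=False)
    centers = {s: 10.0 * np.array([np.cos(a), np.sin(a)]) for s, a in zip(states, angles)}
    emb = np.stack([centers[s] for s in state]) + rng.normal(0.0, 1.2, (n_cells, 2))

    # --- hashtags ----------------------------------------------------------
    hash_truth = np.where(
        origin == "T-Tum cluster", "hash1", np.where(origin == "T-APC cluster", "hash2", "negative")
    )
    h1 = np.where(
        hash_truth == "hash1",
        rng.lognormal(np.log(300.0), 0.4, n_cells),
        rng.lognormal(np.log(4.0), 0.7, n_cells),
    )
    h2 = np.where(
        hash_truth == "hash2",
        rng.lognormal(np.log(300.0), 0.4, n_cells),
        rng.lognormal(np.log(4.0), 0.7, n_cells),
    )

    # --- clonotypes --------------------------------------------------------
    n_clono = max(20, n_cells // 8)
    ranks = np.arange(1, n_clono + 1, dtype=float)
    w = ranks ** (-sc_truth.clonotype_exponent)
    expanded = np.zeros(n_clono, dtype=bool)
    expanded[: max(1, n_clono // 10)] = True
    w_cluster = w * np.where(expanded, np.exp(sc_truth.clonotype_cluster_bias), 1.0)
    p_single = w / w.sum()
    p_clust = w_cluster / w_cluster.sum()
    clono_ix = np.where(
        is_cluster,
        rng.choice(n_clono, size=n_cells, p=p_clust),
        rng.choice(n_clono, size=n_cells, p=p_single),
    )
    alpha = [_random_cdr3(rng) for _ in range(n_clono)]
    beta = [_random_cdr3(rng) for _ in range(n_clono)]

    cell_ids = np.array([f"{p}_cell{i:05d}" for i, p in enumerate(patient)])
    tcr_rows = []
    missing_chain = rng.random(n_cells) < 0.02
    extra_alpha = (~missing_chain) & (rng.random(n_cells) < 0.02)
    truth_key = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        ci = clono_ix[i]
        a_chains = [alpha[ci]]
        if extra_alpha[i]:
            a_chains.append(_random_cdr3(rng))
        if missing_chain[i]:
            # drop one chain entirely: cell excluded from clonotype analyses
            tcr_rows.append((cell_ids[i], "TRA", alpha[ci]))
            truth_key[i] = ""
            continue
        for a in a_chains:
            tcr_rows.append((cell_ids[i], "TRA", a))
        tcr_rows.append((cell_ids[i], "TRB", beta[ci]))
        truth_key[i] = "+".join(sorted(a_chains)) + "|" + beta[ci]
    tcr = pd.DataFrame(tcr_rows, columns=["cell_id", "chain", "cdr3_aa"])

    obs = pd.DataFrame(
        {
            "patient": patient,
            "origin": origin,
            "state": state.astype(str),
            "hash1_count": np.round(h1).astype(int),
            "hash2_count": np.round(h2).astype(int),
            "truth_hashtag": hash_truth,
            "truth_cd39": cd39_true,
            "truth_cd39_dropout": drop,
            "truth_clonotype": truth_key.astype(str),
        },
        index=cell_ids,
    )
    var = pd.DataFrame({"mito": [g.startswith("MT-") for g in genes]}, index=genes)
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=var,
        obsm={"X_embed": emb},
        uns={
            "truth": {
                "de_log2fc": dict(sc_truth.de_log2fc),
                "enrichment_logodds": dict(sc_truth.enrichment_logodds),
                "cd39_dropout": sc_truth.cd39_dropout,
                "cluster_origins": cluster_origins,
            }
        },
    )
    return adata, tcr


# ---------------------------------------------------------------------------
# Ligand-receptor tables
# ---------------------------------------------------------------------------

_LOCALIZATIONS = ["Cell membrane", "Cell surface", "Cytoplasm", "Nucleus", "Secreted"]

#: planted rows covering every branch of the curation rule (kept / dropped)
_PLANTED_LR = [
    # weight, ann, ppi, celltalk, scsr, localization, expected_keep
    (0.74, 1, 1, 1, 1, "Cell membrane", False),  # fails weight > 0.75
    (0.95, 0, 0, 0, 0, "Cell surface", True),  # branch 3: weight > 0.9
    (0.92, 1, 1, 1, 1, "Nucleus", False),  # fails localization
    (0.85, 0, 0, 1, 0, "Cell membrane", True),  # branch 4 via celltalk
    (0.85, 0, 0, 0, 1, "Cell surface", True),  # branch 4 via scsr
    (0.85, 0, 0, 0, 0, "Cell membrane", False),  # no branch holds
    (0.78, 1, 0, 0, 0, "Cell membrane", True),  # branch 1: annotation db
    (0.78, 0, 1, 0, 0, "Cell surface", True),  # branch 2: ppi
    (0.78, 0, 0, 1, 1, "Cell membrane", False),  # celltalk/scsr need weight>0.8
]


def gen_lr_tables(n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Random ligand-receptor network table plus planted rule-branch rows.

    Random pair weights are uniform on [0.5, 1] with independent database
    membership flags; localization terms are drawn from a fixed vocabulary.
    Planted rows (column ``planted`` True) carry ``truth_keep``, the expected
    curation outcome.
    """
    if n_pairs < 20:
        raise ValueError("need at least 20 pairs")
    rng = np.random.default_rng(seed)
    n_rand = n_pairs - len(_PLANTED_LR)
    rows = []
    for i in range(n_rand):
        terms = rng.choice(_LOCALIZATIONS, size=int(rng.integers(1, 3)), replace=False)
        rows.append(
            {
                "ligand": f"LIG{i:04d}",
                "receptor": f"REC{i:04d}",
                "weight": rng.uniform(0.5, 1.0),
                "in_annotation_db": bool(rng.random() < 0.4),
                "in_ppi": bool(rng.random() < 0.4),
                "in_celltalk_like": bool(rng.random() < 0.4),
                "in_scsr_like": bool(rng.random() < 0.4),
                "receptor_localization": ";".join(terms),
                "planted": False,
                "truth_keep": pd.NA,
            }
        )
    for j, (w, ann, ppi, ct, sc, loc, keep) in enumerate(_PLANTED_LR):
        rows.append(
            {
                "ligand": f"PLIG{j:02d}",
                "receptor": f"PREC{j:02d}",
                "weight": w,
                "in_annotation_db": bool(ann),
                "in_ppi": bool(ppi),
                "in_celltalk_like": bool(ct),
                "in_scsr_like": bool(sc),
                "receptor_localization": loc,
                "planted": True,
                "truth_keep": keep,
            }
        )
    return pd.DataFrame(rows)
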