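"""Imaging-flow-cytometry workflow for immune-synapse relocalization.

Stages: build segmentation inputs from a bright-field variance filter and
normalized fluorescence channels, segment and contract labels (built-in
Otsu + watershed segmenter or any plug-in), type cells by k-means on channel
means + area, extract 1:1 heterotypic doublets from the touching graph, and
score marker relocalization on the interface arc of the membrane versus the
rest of the membrane, with a cohort-level paired test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .synthdata import MultiChannelImage, shared_boundary_mask

__all__ = [
    "CellRecord",
    "DoubletRecord",
    "prepare_inputs",
    "variance_filter",
    "builtin_segmenter",
    "segment_and_contract",
    "classify_cells_kmeans",
    "extract_doublets",
    "interface_relocalization",
]


@dataclass
class CellRecord:
    label: int
    area_px: int
    channel_means: dict[str, float]
    cell_type: str = "unassigned"


@dataclass
class DoubletRecord:
    """A 1:1 cluster of two touching cells of different types."""

    object_id: int
    labels: tuple[int, int]
    types: tuple[str, str]
    interface_mean: float = np.nan
    noninterface_mean: float = np.nan
    #: fraction of membrane marker mass on the interface arc
    interface_mass_fraction: float = np.nan
    #: interface share of the membrane area
    interface_area_fraction: float = np.nan
    #: excess relocalized mass fraction: (mass_frac - area_frac)/(1 - area_frac)
    relocalized_fraction: float = np.nan
    excluded: bool = False


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def variance_filter(image: np.ndarray, radius: int = 2) -> np.ndarray:
    """Local variance over a square neighbourhood of the given radius.

    Computed as E[x^2] - E[x]^2 with uniform filters over the
    (2*radius+1)^2 window, clipped at zero against round-off.
    """
    size = 2 * radius + 1
    x = image.astype(float)
    m = ndimage.uniform_filter(x, size=size)
    m2 = ndimage.uniform_filter(x * x, size=size)
    return np.clip(m2 - m * m, 0.0, None)


def prepare_inputs(
    image: MultiChannelImage,
    mode: str = "invitro",
    brightfield: str = "brightfield",
    type_channels: tuple[str, ...] = ("t_marker", "tumour_marker"),
) -> dict[str, np.ndarray]:
    """Build the channels fed to segmentation.

    ``invitro``: membranous = variance filter (radius 2 px) of the
    bright-field; nuclear = min-max-normalized sum of the T and tumour
    marker channels.  ``patient``: one combined channel = sum of all
    normalized fluorescence channels plus the normalized variance-filtered
    bright-field.
    """
    if brightfield not in image.channels:
        raise KeyError(f"missing channel {brightfield!r}")
    var = variance_filter(image.channels[brightfield], radius=2)
    if mode == "invitro":
        for ch in type_channels:
            if ch not in image.channels:
                raise KeyError(f"missing channel {ch!r}")
        nuclear = sum(_minmax(image.channels[ch]) for ch in type_channels)
        return {"membranous": var, "nuclear": _minmax(nuclear)}
    if mode == "patient":
        fluo = [ch for ch in image.channels if ch != brightfield]
        combined = sum(_minmax(image.channels[ch]) for ch in fluo) + _minmax(var)
        return {"combined": _minmax(combined)}
    raise ValueError("mode must be 'invitro' or 'patient'")


def builtin_segmenter(inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Otsu threshold + distance-transform watershed label image.

    A deliberately simple segmenter so the pipeline never needs an external
    model; any callable with the same contract can replace it.
    """
    combined = _minmax(sum(_minmax(ch) for ch in inputs.values()))
    try:
        thr = threshold_otsu(combined)
    except ValueError:  # constant image
        return np.zeros(combined.shape, dtype=np.int32)
    fg = ndimage.binary_fill_holes(combined > thr)
    if not fg.any():
        return np.zeros(combined.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    # seeds: local maxima of the smoothed distance map
    sm = ndimage.gaussian_filter(dist, 2.0)
    maxi = (sm == ndimage.maximum_filter(sm, size=9)) & (dist > 3)
    seeds, _ = ndimage.label(maxi)
    if seeds.max() == 0:
        seeds, _ = ndimage.label(fg)
    labels = watershed(-dist, seeds, mask=fg)
    return labels.astype(np.int32)


def contract_labels(labels: np.ndarray, px: int = 2) -> np.ndarray:
    """Erode every label by ``px`` pixels; labels vanishing are dropped."""
    out = np.zeros_like(labels)
    selem = disk(px)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        eroded = ndimage.binary_erosion(labels == lab, structure=selem)
        out[eroded] = lab
    return out


def segment_and_contract(
    inputs: dict[str, np.ndarray],
    segmenter=builtin_segmenter,
    contraction_px: int = 2,
) -> np.ndarray:
    """Run the plug-in segmenter, then contract each label by 2 pixels."""
    labels = np.asarray(segmenter(inputs))
    if labels.max() == 0:
        warnings.warn("empty segmentation", stacklevel=2)
        return labels.astype(np.int32)
    return contract_labels(labels.astype(np.int32), contraction_px)


def _cell_features(labels: np.ndarray, image: MultiChannelImage) -> list[CellRecord]:
    cells = []
    labs = [int(v) for v in np.unique(labels) if v != 0]
    for lab in labs:
        mask = labels == lab
        means = {ch: float(image.channels[ch][mask].mean()) for ch in image.channels}
        cells.append(CellRecord(label=lab, area_px=int(mask.sum()), channel_means=means))
    return cells


def classify_cells_kmeans(
    labels: np.ndarray,
    image: MultiChannelImage,
    type_markers: dict[str, str],
    k: int | None = None,
    seed: int = 0,
) -> list[CellRecord]:
    """Assign cell types by k-means on standardized channel means + area.

    Each k-means cluster gets the type whose marker channel has the highest
    cluster-average standardized intensity; ties break on the declared order
    of ``type_markers``.  Two clusters may map to the same type (a warning is
    logged for the degenerate mapping).
    """
    cells = _cell_features(labels, image)
    if k is None:
        k = len(type_markers)
    if len(cells) < k:
        raise ValueError(f"fewer cells ({len(cells)}) than k ({k})")
    channels = list(image.channels)
    feats = np.array(
        [[c.channel_means[ch] for ch in channels] + [c.area_px] for c in cells]
    )
    z = StandardScaler().fit_transform(feats)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)

    marker_ix = {t: channels.index(ch) for t, ch in type_markers.items()}
    types = list(type_markers)  # declared order = final tie-break order
    mapping: dict[int, str] = {}
    for c in range(k):
        zc = z[km.labels_ == c].mean(axis=0)
        scores = np.array([zc[marker_ix[t]] for t in types])
        if np.allclose(scores, scores[0]):
            # degenerate (e.g. k=1: all z-means are 0): fall back to the raw
            # cluster-average marker intensity
            raw = feats[km.labels_ == c].mean(axis=0)
            scores = np.array([raw[marker_ix[t]] for t in types])
        mapping[c] = types[int(np.argmax(scores))]
    if len(set(mapping.values())) < len(set(mapping)):
        warnings.warn("multiple k-means clusters mapped to the same type", stacklevel=2)
    for cell, kl in zip(cells, km.labels_):
        cell.cell_type = mapping[int(kl)]
    return cells


def _touching_pairs(labels: np.ndarray, touch_distance_px: int = 5) -> set[tuple[int, int]]:
    """Pairs of labels within Chebyshev distance ``touch_distance_px``.

    With the default 2-px label contraction, two cells whose original
    boundaries touched end up 2*2+1 = 5 px apart, hence the default; on
    uncontracted labels a distance of 1 reduces this to plain 8-connectivity
    adjacency.
    """
    pairs: set[tuple[int, int]] = set()
    size = 2 * touch_distance_px + 1
    struct = np.ones((size, size), dtype=bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        ring = ndimage.binary_dilation(labels == lab, structure=struct)
        neigh = np.unique(labels[ring])
        for other in neigh:
            if other not in (0, lab):
                pairs.add((min(lab, other), max(lab, other)))
    return pairs


def extract_doublets(
    labels: np.ndarray,
    cells: list[CellRecord],
    object_id: int = 0,
    touch_distance_px: int = 5,
) -> list[DoubletRecord]:
    """Keep only 1:1 clusters of two touching cells of different types.

    Builds the touching graph (labels within ``touch_distance_px``, which by
    default compensates for the 2-px contraction; see ``_touching_pairs``);
    connected components of exactly two cells of different types become
    doublets; singletons, components of size >= 3 and same-type pairs are
    excluded.
    """
    by_label = {c.label: c for c in cells}
    pairs = _touching_pairs(labels, touch_distance_px)
    adj: dict[int, set[int]] = {c.label: set() for c in cells}
    for a, b in pairs:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    doublets: list[DoubletRecord] = []
    for start in adj:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    stack.append(nb)
        if len(comp) != 2:
            continue
        a, b = sorted(comp)
        ta, tb = by_label[a].cell_type, by_label[b].cell_type
        if ta == tb:
            continue
        doublets.append(DoubletRecord(object_id=object_id, labels=(a, b), types=(ta, tb)))
    return doublets


def membrane_masks(
    labels: np.ndarray,
    lab: int,
    partner: int,
    membrane_width_px: int = 3,
    touch_distance_px: int = 5,
    raw_labels: np.ndarray | None = None,
    interface_reach_px: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """(interface, non-interface) membrane masks of cell ``lab``.

    Membrane = label minus its erosion by ``membrane_width_px``.  When the
    uncontracted segmentation is available (``raw_labels``), the interface is
    the membrane within Chebyshev distance ``interface_reach_px`` of the
    shared boundary line where the two raw labels touch -- the well-posed
    reading of a "touching region" once labels have been contracted.  Without
    raw labels the interface falls back to membrane pixels within
    ``touch_distance_px`` of the partner label (use 1 on uncontracted labels
    for plain adjacency).
    """
    mask = labels == lab
    selem = disk(membrane_width_px)
    membrane = mask & ~ndimage.binary_erosion(mask, structure=selem)
    if raw_labels is not None:
        line = shared_boundary_mask(raw_labels == lab, raw_labels == partner)
        size = 2 * interface_reach_px + 1
        near = ndimage.binary_dilation(line, structure=np.ones((size, size)))
    else:
        size = 2 * touch_distance_px + 1
        near = ndimage.binary_dilation(labels == partner, structure=np.ones((size, size)))
    return membrane & near, membrane & ~near


def interface_relocalization(
    doublets: list[DoubletRecord],
    labels_per_doublet: list[np.ndarray],
    images: list[MultiChannelImage],
    marker_channel: str,
    membrane_width_px: int = 3,
    touch_distance_px: int = 5,
    raw_labels_per_doublet: list[np.ndarray] | None = None,
    interface_reach_px: int = 6,
    scored_type: str | None = None,
    test: str = "wilcoxon",
) -> dict:
    """Interface vs non-interface membrane means for a marker, plus cohort test.

    For each doublet the scored cell's membrane is split into the interface
    arc (touching the partner) and the rest; the marker mean is computed on
    each region.  ``scored_type`` selects which member is scored (default: the
    first-listed type of each doublet).  The cohort test is a two-sided paired
    Wilcoxon signed-rank on (interface_mean - noninterface_mean); a paired
    t-test is available via ``test='ttest'``.  Pairs with an empty interface
    are flagged and excluded from the test.
    """
    if not doublets:
        raise ValueError("no doublets to score")
    raws = raw_labels_per_doublet or [None] * len(doublets)
    diffs = []
    for db, labs, raw, img in zip(doublets, labels_per_doublet, raws, images):
        if scored_type is not None and scored_type in db.types:
            ix = db.types.index(scored_type)
        else:
            ix = 0
        me, partner = db.labels[ix], db.labels[1 - ix]
        interface, noninterface = membrane_masks(
            labs, me, partner, membrane_width_px, touch_distance_px,
            raw_labels=raw, interface_reach_px=interface_reach_px,
        )
        if interface.sum() == 0 or noninterface.sum() == 0:
            db.excluded = True
            continue
        chan = img.channels[marker_channel]
        db.interface_mean = float(chan[interface].mean())
        db.noninterface_mean = float(chan[noninterface].mean())
        mass_int, mass_non = float(chan[interface].sum()), float(chan[noninterface].sum())
        db.interface_mass_fraction = mass_int / (mass_int + mass_non)
        db.interface_area_fraction = float(
            interface.sum() / (interface.sum() + noninterface.sum())
        )
        db.relocalized_fraction = (
            db.interface_mass_fraction - db.interface_area_fraction
        ) / (1.0 - db.interface_area_fraction)
        diffs.append(db.interface_mean - db.noninterface_mean)

    diffs = np.asarray(diffs)
    if len(diffs) == 0:
        raise ValueError("every doublet had an empty interface")
    if np.allclose(diffs, 0):
        p = 1.0
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    else:
        raise ValueError("test must be 'wilcoxon' or 'ttest'")

    scored = [d for d in doublets if not d.excluded]
    if not scored:
        raise ValueError("every doublet had an empty interface")
    ratio = np.array([d.interface_mean / d.noninterface_mean for d in scored])
    return {
        "n_scored": len(scored),
        "n_excluded": len(doublets) - len(scored),
        "mean_interface": float(np.mean([d.interface_mean for d in scored])),
        "mean_noninterface": float(np.mean([d.noninterface_mean for d in scored])),
        "mean_ratio": float(ratio.mean()),
        "mean_interface_mass_fraction": float(
            np.mean([d.interface_mass_fraction for d in scored])
        ),
        "mean_relocalized_fraction": float(
            np.mean([d.relocalized_fraction for d in scored])
        ),
        "p": p,
        "test": test,
    }


def analyze_synapse_cohort(
    images: list[MultiChannelImage],
    type_markers: dict[str, str] | None = None,
    marker_channel: str = "synapse_marker",
    mode: str = "invitro",
    segmenter=builtin_segmenter,
    scored_type: str | None = "T",
    membrane_width_px: int = 3,
    test: str = "wilcoxon",
    seed: int = 0,
) -> dict:
    """End-to-end relocalization scoring over a cohort of object images.

    Runs input preparation, segmentation + 2-px contraction, k-means cell
    typing and 1:1 doublet extraction per image, then pools all doublets into
    one interface-vs-rest comparison.  Images yielding no valid heterotypic
    doublet (failed segmentation, singlets, larger clusters) are skipped.
    """
    if type_markers is None:
        type_markers = {"T": "t_marker", "Tumour": "tumour_marker"}
    doublets: list[DoubletRecord] = []
    labels_list: list[np.ndarray] = []
    raw_list: list[np.ndarray] = []
    imgs_list: list[MultiChannelImage] = []
    for img in images:
        inputs = prepare_inputs(img, mode=mode, type_channels=tuple(type_markers.values()))
        raw = np.asarray(segmenter(inputs)).astype(np.int32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = contract_labels(raw, 2) if raw.max() else raw
        n_cells = int(len(np.unique(labels)) - (1 if (labels == 0).any() else 0))
        if n_cells < 2:
            continue
        cells = classify_cells_kmeans(
            labels, img, type_markers, k=min(len(type_markers), n_cells), seed=seed
        )
        for db in extract_doublets(labels, cells, object_id=img.object_id):
            doublets.append(db)
            labels_list.append(labels)
            raw_list.append(raw)
            imgs_list.append(img)
    result = interface_relocalization(
        doublets,
        labels_list,
        imgs_list,
        marker_channel,
        membrane_width_px=membrane_width_px,
        raw_labels_per_doublet=raw_list,
        scored_type=scored_type,
        test=test,
    )
    result["n_images"] = len(images)
    result["n_doublet_candidates"] = len(doublets)
    return result
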