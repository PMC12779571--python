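"""Readers and writers for the package's table and image formats.

Event and centroid tables round-trip through CSV; multichannel images through
multipage TIFF with a JSON sidecar naming channels and the pixel size;
single-cell datasets through MTX (genes x cells) plus TSV features, barcodes
and metadata; TCR chain tables and ligand-receptor networks through TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse

from .synthdata import MultiChannelImage

__all__ = [
    "write_table",
    "read_table",
    "write_images",
    "read_images",
    "write_sc_dataset",
    "read_sc_dataset",
    "write_tcr",
    "read_tcr",
    "write_lr",
    "read_lr",
]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_images(images: list[MultiChannelImage], directory) -> None:
    """One multipage TIFF per object (a page per channel) + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img in images:
        channels = list(img.channels)
        stack = np.stack([img.channels[c].astype(np.float32) for c in channels])
        base = directory / f"object_{img.object_id:05d}"
        tifffile.imwrite(base.with_suffix(".tiff"), stack, photometric="minisblack")
        sidecar = {
            "object_id": img.object_id,
            "channels": channels,
            "pixel_size_um": img.pixel_size_um,
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_images(directory) -> list[MultiChannelImage]:
    images = []
    for tiff_path in sorted(Path(directory).glob("object_*.tiff")):
        meta = json.loads(tiff_path.with_suffix(".json").read_text())
        stack = tifffile.imread(tiff_path)
        channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
        images.append(
            MultiChannelImage(
                channels=channels,
                pixel_size_um=meta["pixel_size_um"],
                object_id=meta["object_id"],
            )
        )
    return images


def write_sc_dataset(ds: ad.AnnData, directory) -> None:
    """MTX (genes x cells) + features/barcodes/metadata TSV + embedding TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = ds.X if sparse.issparse(ds.X) else sparse.csr_matrix(ds.X)
    sio.mmwrite(directory / "matrix.mtx", X.T.tocoo())  # genes x cells
    ds.var.reset_index(names="gene").to_csv(
        directory / "features.tsv", sep="\t", index=False
    )
    pd.Series(ds.obs_names, name="barcode").to_csv(
        directory / "barcodes.tsv", sep="\t", index=False
    )
    ds.obs.reset_index(names="barcode").to_csv(
        directory / "metadata.tsv", sep="\t", index=False
    )
    if "X_embed" in ds.obsm:
        pd.DataFrame(
            ds.obsm["X_embed"], columns=["embed_1", "embed_2"]
        ).to_csv(directory / "embedding.tsv", sep="\t", index=False)


def read_sc_dataset(directory) -> ad.AnnData:
    directory = Path(directory)
    X = sio.mmread(directory / "matrix.mtx").T.tocsr()
    var = pd.read_csv(directory / "features.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(directory / "metadata.tsv", sep="\t").set_index("barcode")
    obs.index = obs.index.astype(str)
    ds = ad.AnnData(X=X, obs=obs, var=var)
    emb_path = directory / "embedding.tsv"
    if emb_path.exists():
        ds.obsm["X_embed"] = pd.read_csv(emb_path, sep="\t").to_numpy()
    return ds


def write_tcr(tcr: pd.DataFrame, path) -> None:
    tcr.to_csv(path, sep="\t", index=False)


def read_tcr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_lr(db: pd.DataFrame, path) -> None:
    db.to_csv(path, sep="\t", index=False)


def read_lr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
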