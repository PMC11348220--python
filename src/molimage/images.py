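"""Multi-channel cellular images: data model, manifest I/O, normalization.

A :class:`CellImage` is a float stack of named fluorescence channels — by
default the five Cell Painting compartments DNA, ER, RNA, AGP (actin/Golgi/
plasma membrane) and Mito — tagged with the perturbing molecule, a view id
(one microscopy field of one well) and a batch id (plate/experiment, the
unit of systematic intensity drift).

Images live on disk as NPZ stacks (key ``pixels``, C x H x W) or as
per-channel PNG/TIFF files with ``_DNA`` / ``_ER`` / ... filename suffixes;
a TSV manifest maps molecule ids to image references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CHANNELS",
    "CellImage",
    "ImageRef",
    "ImageManifest",
    "load_images",
    "save_image_npz",
    "normalize",
]

DEFAULT_CHANNELS = ("DNA", "ER", "RNA", "AGP", "Mito")
MIN_SIZE = 8


@dataclass
class CellImage:
    pixels: np.ndarray  # (C, H, W) float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    molecule_id: str = ""
    view_id: int = 0
    batch_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be C x H x W, got {self.pixels.shape}")
        c, h, w = self.pixels.shape
        if c != len(self.channel_names):
            raise ValueError(
                f"{c} channels but {len(self.channel_names)} channel names")
        if h < MIN_SIZE or w < MIN_SIZE:
            raise ValueError(f"image too small ({h}x{w}); minimum {MIN_SIZE}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")

    @property
    def num_channels(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ImageRef:
    path: str
    view_id: int
    batch_id: int


@dataclass
class ImageManifest:
    """Ordered mapping molecule_id -> image references."""

    records: dict[str, list[ImageRef]] = field(default_factory=dict)
    max_views: int | None = 30  # balance cap, mirroring typical HCI curation

    def add(self, molecule_id: str, ref: ImageRef) -> None:
        refs = self.records.setdefault(molecule_id, [])
        if self.max_views is not None and len(refs) >= self.max_views:
            raise ValueError(
                f"molecule {molecule_id!r} already has {self.max_views} views")
        refs.append(ref)

    def __len__(self) -> int:
        return sum(len(v) for v in self.records.values())

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.records)

    def validate_against(self, molecule_ids: Iterable[str]) -> None:
        known = set(molecule_ids)
        missing = [m for m in self.records if m not in known]
        if missing:
            raise ValueError(f"manifest molecules without graphs: {missing[:5]}")
        empty = [m for m, refs in self.records.items() if not refs]
        if empty:
            raise ValueError(f"molecules with zero views: {empty[:5]}")

    # -- TSV round trip -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [(m, r.path, r.view_id, r.batch_id)
                for m, refs in self.records.items() for r in refs]
        pd.DataFrame(rows, columns=["molecule_id", "path", "view_id",
                                    "batch_id"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, max_views: int | None = 30
                 ) -> "ImageManifest":
        df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str})
        man = cls(max_views=max_views)
        for row in df.itertuples(index=False):
            man.add(str(row.molecule_id),
                    ImageRef(str(row.path), int(row.view_id), int(row.batch_id)))
        return man


def _read_stack(path: Path, channel_names: Sequence[str]) -> np.ndarray:
    """Read one C x H x W stack from NPZ, or per-channel PNG/TIFF by suffix."""
    if path.suffix == ".npz":
        with np.load(path) as npz:
            if "pixels" not in npz:
                raise ValueError(f"{path}: NPZ stack missing 'pixels' key")
            arr = np.asarray(npz["pixels"], dtype=np.float64)
        return arr
    # per-channel images: path is the basename; channels appended as _DNA etc.
    channels = []
    for name in channel_names:
        cpath = path.with_name(f"{path.stem}_{name}{path.suffix}")
        if not cpath.exists():
            raise FileNotFoundError(cpath)
        if path.suffix in {".tif", ".tiff"}:
            import tifffile
            channels.append(np.asarray(tifffile.imread(cpath), dtype=np.float64))
        else:
            from PIL import Image
            channels.append(np.asarray(Image.open(cpath), dtype=np.float64))
    return np.stack(channels)


def load_images(manifest: ImageManifest, root: str | Path = ".",
                channel_names: Sequence[str] = DEFAULT_CHANNELS
                ) -> Iterator[CellImage]:
    """Yield images in manifest order, dtype promoted to float64."""
    root = Path(root)
    for molecule_id, refs in manifest.records.items():
        for ref in refs:
            path = root / ref.path
            if path.suffix == ".npz" and not path.exists():
                raise FileNotFoundError(path)
            arr = _read_stack(path, channel_names)
            if arr.ndim != 3 or arr.shape[0] != len(channel_names):
                raise ValueError(
                    f"{path}: expected {len(channel_names)} x H x W, "
                    f"got shape {arr.shape}")
            yield CellImage(arr, tuple(channel_names), molecule_id,
                            ref.view_id, ref.batch_id)


def save_image_npz(image_or_pixels, path: str | Path) -> None:
    pixels = image_or_pixels.pixels if isinstance(image_or_pixels, CellImage) \
        else np.asarray(image_or_pixels)
    np.savez(path, pixels=pixels)


def normalize(image: CellImage, method: str = "per_channel_zscore") -> CellImage:
    """Per-channel standardization.

    ``per_channel_zscore``: each channel to mean 0 / sd 1 (constant channels
    map to all zeros). ``unit_range``: each channel to [0, 1] (constant
    channels map to zeros).
    """
    px = image.pixels
    if method == "per_channel_zscore":
        mu = px.mean(axis=(1, 2), keepdims=True)
        sd = px.std(axis=(1, 2), keepdims=True)
        out = np.where(sd > 0, (px - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif method == "unit_range":
        lo = px.min(axis=(1, 2), keepdims=True)
        hi = px.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (px - lo) / np.where(span > 0, span, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return CellImage(out, image.channel_names, image.molecule_id,
                     image.view_id, image.batch_id)
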