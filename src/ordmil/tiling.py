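"""Whole-slide access, tissue masking, and tile extraction.

Slides are exposed through a small pyramid interface (level 0 is full
resolution, downsample factors increase with level), with three
backends: an in-memory array (synthetic slides, tests), a pyramidal
multi-page TIFF read via :mod:`tifffile`, and a directory of PNG tiles
with a JSON sidecar for pipelines whose tiling was done elsewhere.

Tissue is detected on a downsampled level by thresholding the HSV
saturation channel: stained tissue (pink eosin background, dark
haematoxylin nuclei) is saturated, glass background is not.  The
threshold is Otsu's, computed on saturation values clipped to an upper
limit so that strongly stained nuclei cannot drag the split into the
middle of the tissue itself; small specks are removed and small holes
filled.  Tiles are taken from the non-overlapping level-0 grid and kept
when their tissue fraction reaches a threshold (default 1.0 — tiles of
pure tissue).  A slide where no tile qualifies keeps its single best
tile, flagged, so every slide remains classifiable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.transform import downscale_local_mean

from .ordinal import ContractViolation

__all__ = [
    "SlideImage",
    "ArraySlide",
    "TiffSlide",
    "TileDirectorySlide",
    "TissueMask",
    "TileRef",
    "TileManifest",
    "compute_tissue_mask",
    "tile_grid",
    "tissue_fraction",
    "extract_tiles",
    "write_pyramidal_tiff",
]

#: Long-side cap for the automatically chosen mask level.
MASK_MAX_SIDE = 4096
#: Prefer the coarsest level that still has this much detail: local-mean
#: downsampling suppresses pixel noise before the saturation threshold.
MASK_MIN_SIDE = 96
#: Connected components / holes smaller than this (mask px) are cleaned up.
MIN_OBJECT_PX = 64
#: Saturation clip applied before Otsu so nuclei cannot dominate the split.
SAT_CLIP = 0.25
#: Saturation floor below which a pixel is never tissue.
SAT_FLOOR = 0.02


class SlideReadError(IOError):
    """A slide or tile image could not be read."""


@dataclass(frozen=True)
class TileRef:
    """One tile: slide, level-0 offsets (0-based, half-open), size, tissue fraction."""

    slide_id: str
    x: int
    y: int
    size_px: int = 512
    tissue_fraction: float = 1.0
    fallback: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ContractViolation("tissue_fraction must lie in [0, 1]")
        if self.size_px <= 0 or self.x < 0 or self.y < 0:
            raise ContractViolation("tile geometry must be non-negative with positive size")


class SlideImage:
    """Pyramidal slide interface: ordered levels plus a rectangle reader."""

    slide_id: str
    #: list of (width_px, height_px, downsample_factor), level 0 first
    levels: list[tuple[int, int, float]]

    def read_region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        raise NotImplementedError

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        w, h, _ = self.levels[0]
        return w, h

    def read_tile(self, tile: TileRef) -> np.ndarray:
        return self.read_region(0, tile.x, tile.y, tile.size_px, tile.size_px)

    def _check_level(self, level: int) -> None:
        if not 0 <= level < len(self.levels):
            raise ContractViolation(f"slide {self.slide_id!r} has no level {level}")


def _build_pyramid(image: np.ndarray, n_levels: int) -> list[np.ndarray]:
    levels = [image]
    for _ in range(1, n_levels):
        prev = levels[-1]
        if min(prev.shape[:2]) < 2:
            break
        down = downscale_local_mean(prev.astype(float), (2, 2, 1))
        levels.append(np.clip(np.round(down), 0, 255).astype(np.uint8))
    return levels


class ArraySlide(SlideImage):
    """In-memory slide; the pyramid is built by 2x local-mean downsampling."""

    def __init__(self, slide_id: str, image: np.ndarray, n_levels: int = 3):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ContractViolation("slide image must be H x W x 3")
        self.slide_id = slide_id
        self._levels_px = _build_pyramid(np.asarray(image, dtype=np.uint8), n_levels)
        self.levels = [
            (lv.shape[1], lv.shape[0], float(2**i)) for i, lv in enumerate(self._levels_px)
        ]

    def read_region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        self._check_level(level)
        img = self._levels_px[level]
        if x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
            raise ContractViolation(
                f"region ({x},{y},{w},{h}) outside level {level} of slide {self.slide_id!r}"
            )
        return img[y : y + h, x : x + w].copy()


class TiffSlide(ArraySlide):
    """Pyramidal (multi-page) TIFF slide; pages are levels, largest first."""

    def __init__(self, path: str | Path):
        path = Path(path)
        try:
            with tifffile.TiffFile(path) as tf:
                pages = [p.asarray() for p in tf.pages]
        except (OSError, ValueError, tifffile.TiffFileError) as exc:
            raise SlideReadError(f"cannot read slide {path}: {exc}") from exc
        if not pages:
            raise SlideReadError(f"slide {path} contains no images")
        pages.sort(key=lambda a: -a.shape[0] * a.shape[1])
        self.slide_id = path.stem
        self._levels_px = [np.asarray(p, dtype=np.uint8) for p in pages]
        w0, h0 = self._levels_px[0].shape[1], self._levels_px[0].shape[0]
        self.levels = [(p.shape[1], p.shape[0], round(w0 / p.shape[1], 4)) for p in self._levels_px]


def write_pyramidal_tiff(path: str | Path, image: np.ndarray, n_levels: int = 3) -> None:
    """Write a multi-page pyramidal TIFF (level ``i`` downsampled by ``2**i``)."""
    levels = _build_pyramid(np.asarray(image, dtype=np.uint8), n_levels)
    with tifffile.TiffWriter(path) as tw:
        for lv in levels:
            tw.write(lv, photometric="rgb", compression="zlib")


class TileDirectorySlide(ArraySlide):
    """Slide reassembled from a directory of PNG tiles plus a JSON sidecar.

    The sidecar (``manifest.json``) gives slide id, level-0 dimensions,
    tile size and the (x, y) offset of each tile file; regions not
    covered by any tile read as white (glass background).
    """

    def __init__(self, directory: str | Path):
        directory = Path(directory)
        sidecar = directory / "manifest.json"
        try:
            meta = json.loads(sidecar.read_text())
        except OSError as exc:
            raise SlideReadError(f"cannot read tile-directory sidecar {sidecar}: {exc}") from exc
        canvas = np.full((meta["height"], meta["width"], 3), 255, dtype=np.uint8)
        size = meta["tile_size"]
        for entry in meta["tiles"]:
            tile_path = directory / entry["file"]
            try:
                tile = np.asarray(Image.open(tile_path).convert("RGB"))
            except OSError as exc:
                raise SlideReadError(f"cannot read tile {tile_path}: {exc}") from exc
            x, y = entry["x"], entry["y"]
            canvas[y : y + size, x : x + size] = tile
        super().__init__(meta["slide_id"], canvas)


@dataclass
class TissueMask:
    """Binary tissue raster at ``downsample`` x reduction relative to level 0."""

    mask: np.ndarray  # bool, H x W at the mask level
    downsample: float

    @property
    def tissue_px(self) -> int:
        return int(self.mask.sum())


def _auto_mask_level(slide: SlideImage) -> int:
    """Coarsest level that keeps the long side >= MASK_MIN_SIDE (capped at
    MASK_MAX_SIDE where possible); level 0 only for very small slides."""
    best = 0
    for level, (w, h, _) in enumerate(slide.levels):
        if max(w, h) >= MASK_MIN_SIDE:
            best = level
    return best


def compute_tissue_mask(
    slide: SlideImage,
    mask_level: int | None = None,
    sat_clip: float = SAT_CLIP,
    min_object_px: int = MIN_OBJECT_PX,
) -> TissueMask:
    """Saturation-threshold tissue mask on a downsampled level.

    Deterministic for fixed input and parameters.  Degenerate
    (near-uniform) images short-circuit Otsu: uniformly saturated means
    all tissue, uniformly unsaturated means none.
    """
    if mask_level is None:
        mask_level = _auto_mask_level(slide)
    slide._check_level(mask_level)
    w, h, ds = slide.levels[mask_level]
    rgb = slide.read_region(mask_level, 0, 0, w, h)
    sat = rgb2hsv(rgb)[..., 1]
    clipped = np.clip(sat, 0.0, sat_clip)
    if clipped.max() - clipped.min() < 0.05:
        mask = np.full(sat.shape, bool(sat.mean() > 0.05))
    else:
        thr = max(float(threshold_otsu(clipped)), SAT_FLOOR)
        # hysteresis: pixels above the Otsu split seed tissue regions, which
        # then absorb connected pixels whose saturation noise dips below the
        # split but stays clearly above glass background
        low = max(0.25 * thr, SAT_FLOOR)
        mask = apply_hysteresis_threshold(sat, low, thr)
        if min_object_px > 0:
            mask = remove_small_objects(mask, max_size=min_object_px - 1)
            mask = remove_small_holes(mask, max_size=min_object_px - 1)
    return TissueMask(mask=mask, downsample=float(ds))


def tile_grid(slide: SlideImage, size_px: int, stride_px: int | None = None) -> list[TileRef]:
    """Candidate tiles on the level-0 grid, row-major, fully inside bounds.

    The default stride equals the tile size (non-overlapping grid).  A
    slide smaller than one tile yields an empty list.
    """
    if size_px <= 0:
        raise ContractViolation("size_px must be positive")
    if stride_px is None:
        stride_px = size_px
    if stride_px <= 0:
        raise ContractViolation("stride_px must be positive")
    w, h = slide.dimensions
    return [
        TileRef(slide.slide_id, x, y, size_px, tissue_fraction=0.0)
        for y in range(0, h - size_px + 1, stride_px)
        for x in range(0, w - size_px + 1, stride_px)
    ]


def tissue_fraction(tile: TileRef, mask: TissueMask) -> float:
    """Fraction of mask pixels inside the tile footprint labelled tissue."""
    ds = mask.downsample
    y0 = int(np.floor(tile.y / ds))
    y1 = int(np.ceil((tile.y + tile.size_px) / ds))
    x0 = int(np.floor(tile.x / ds))
    x1 = int(np.ceil((tile.x + tile.size_px) / ds))
    footprint = mask.mask[y0 : min(y1, mask.mask.shape[0]), x0 : min(x1, mask.mask.shape[1])]
    if footprint.size == 0:
        raise ContractViolation("tile footprint lies outside the mask")
    return float(footprint.mean())


@dataclass
class TileManifest:
    """Ordered tiles per slide plus the parameters that produced them."""

    tiles: list[TileRef] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for t in self.tiles:
            key = (t.slide_id, t.x, t.y)
            if key in seen:
                raise ContractViolation(f"duplicate tile {key} in manifest")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def slide_ids(self) -> list[str]:
        out: list[str] = []
        for t in self.tiles:
            if not out or out[-1] != t.slide_id:
                out.append(t.slide_id)
        return out

    def for_slide(self, slide_id: str) -> list[TileRef]:
        return [t for t in self.tiles if t.slide_id == slide_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slide_id": t.slide_id,
                    "x": t.x,
                    "y": t.y,
                    "size_px": t.size_px,
                    "tissue_fraction": t.tissue_fraction,
                    "fallback": t.fallback,
                }
                for t in self.tiles
            ],
            columns=["slide_id", "x", "y", "size_px", "tissue_fraction", "fallback"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TileManifest":
        df = pd.read_csv(path)
        tiles = [
            TileRef(
                str(r.slide_id),
                int(r.x),
                int(r.y),
                int(r.size_px),
                float(r.tissue_fraction),
                bool(r.fallback),
            )
            for r in df.itertuples()
        ]
        return cls(tiles=tiles)

    def extend(self, other: "TileManifest") -> "TileManifest":
        return TileManifest(
            tiles=self.tiles + other.tiles, provenance={**self.provenance, **other.provenance}
        )


def extract_tiles(
    slide: SlideImage,
    threshold: float = 1.0,
    size_px: int = 512,
    stride_px: int | None = None,
    mask_level: int | None = None,
) -> TileManifest:
    """Tissue-filtered tile manifest for one slide.

    Keeps grid tiles whose tissue fraction reaches ``threshold``
    (default 1.0: tiles of pure tissue).  If no tile qualifies, the
    single highest-fraction tile is kept with ``fallback=True`` so the
    slide still forms a non-empty MIL bag.
    """
    if not 0 <= threshold <= 1.0:
        raise ContractViolation("threshold must lie in [0, 1]")
    mask = compute_tissue_mask(slide, mask_level=mask_level)
    candidates = tile_grid(slide, size_px, stride_px)
    scored = [
        TileRef(t.slide_id, t.x, t.y, t.size_px, tissue_fraction(t, mask)) for t in candidates
    ]
    kept = [t for t in scored if t.tissue_fraction >= threshold]
    fallback = False
    if not kept and scored:
        best = max(range(len(scored)), key=lambda i: (scored[i].tissue_fraction, -i))
        t = scored[best]
        kept = [TileRef(t.slide_id, t.x, t.y, t.size_px, t.tissue_fraction, fallback=True)]
        fallback = True
    return TileManifest(
        tiles=kept,
        provenance={
            "slide_id": slide.slide_id,
            "size_px": size_px,
            "stride_px": stride_px or size_px,
            "threshold": threshold,
            "mask_downsample": mask.downsample,
            "fallback": fallback,
        },
    )


def save_tiles(slide: SlideImage, manifest: TileManifest, directory: str | Path) -> list[Path]:
    """Write manifest tiles as ``{slide_id}_{x}_{y}.png``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in manifest.tiles:
        img = slide.read_tile(t)
        p = directory / f"{t.slide_id}_{t.x}_{t.y}.png"
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths
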