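"""On-disk dataset layout.

A dataset directory holds one sub-directory per slide with its tile
PNGs and a JSON sidecar (the tile-directory slide format that
:mod:`ordmil.tiling` can re-read), a slide manifest CSV
(slide_id, label, split, annotated), region annotations as GeoJSON,
and a provenance record with the generation parameters and seed::

    dataset/
      manifest.csv
      annotations.geojson
      provenance.json
      slides/<slide_id>/manifest.json
      slides/<slide_id>/<slide_id>_<x>_<y>.png
      slides/<slide_id>.tiff            (optional assembled pyramid)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .mil import MILDataset, SlideBag
from .ordinal import OrdinalLabelSpace
from .regions import read_geojson, write_geojson
from .tiling import SlideReadError, TileRef, write_pyramidal_tiff

__all__ = ["write_dataset", "load_dataset"]


def write_dataset(dataset: MILDataset, directory: str | Path, pyramids: bool = False,
                  provenance: dict | None = None) -> Path:
    """Write bags, labels and annotations; returns the dataset root."""
    root = Path(directory)
    (root / "slides").mkdir(parents=True, exist_ok=True)
    for bag in dataset.bags:
        slide_dir = root / "slides" / bag.slide_id
        slide_dir.mkdir(exist_ok=True)
        sidecar = {
            "slide_id": bag.slide_id,
            "tile_size": bag.tiles[0].size_px,
            "width": max(t.x + t.size_px for t in bag.tiles),
            "height": max(t.y + t.size_px for t in bag.tiles),
            "tiles": [],
        }
        for i, t in enumerate(bag.tiles):
            name = f"{bag.slide_id}_{t.x}_{t.y}.png"
            Image.fromarray(bag.image(i)).save(slide_dir / name)
            sidecar["tiles"].append({"x": t.x, "y": t.y, "file": name})
        (slide_dir / "manifest.json").write_text(json.dumps(sidecar, indent=1))
        if pyramids:
            size = bag.tiles[0].size_px
            cols = sidecar["width"] // size
            canvas = np.full((sidecar["height"], sidecar["width"], 3), 255, dtype=np.uint8)
            for i, t in enumerate(bag.tiles):
                canvas[t.y : t.y + size, t.x : t.x + size] = bag.image(i)
            write_pyramidal_tiff(root / "slides" / f"{bag.slide_id}.tiff", canvas)
    dataset.manifest().to_csv(root / "manifest.csv", index=False)
    write_geojson(root / "annotations.geojson", dataset.annotations)
    record = {
        "space": {"names": list(dataset.space.names), "values": list(dataset.space.values)},
        **(provenance or {}),
    }
    (root / "provenance.json").write_text(json.dumps(record, indent=1, default=str))
    return root


def _tile_loader(root: Path):
    def load(tile: TileRef) -> np.ndarray:
        path = root / "slides" / tile.slide_id / f"{tile.slide_id}_{tile.x}_{tile.y}.png"
        try:
            return np.asarray(Image.open(path).convert("RGB"))
        except OSError as exc:
            raise SlideReadError(f"cannot read tile {path}: {exc}") from exc

    return load


def load_dataset(directory: str | Path) -> MILDataset:
    """Re-read a dataset directory into lazily-loading bags."""
    root = Path(directory)
    try:
        manifest = pd.read_csv(root / "manifest.csv")
    except OSError as exc:
        raise SlideReadError(f"cannot read dataset manifest in {root}: {exc}") from exc
    prov = json.loads((root / "provenance.json").read_text())
    space = OrdinalLabelSpace(
        tuple(prov["space"]["names"]), tuple(prov["space"]["values"])
    )
    loader = _tile_loader(root)
    bags = []
    for row in manifest.itertuples():
        sid = str(row.slide_id)
        sidecar = json.loads((root / "slides" / sid / "manifest.json").read_text())
        tiles = [
            TileRef(sid, e["x"], e["y"], sidecar["tile_size"]) for e in sidecar["tiles"]
        ]
        bags.append(
            SlideBag(
                slide_id=sid,
                tiles=tiles,
                label=int(row.label),
                split=str(row.split),
                annotated=bool(row.annotated),
                loader=loader,
            )
        )
    ann_path = root / "annotations.geojson"
    annotations = read_geojson(ann_path) if ann_path.exists() else []
    return MILDataset(bags=bags, space=space, annotations=annotations)
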