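"""Region annotations (polygons with class tags) and their reduction to
tile-level labels for supervised pre-training.

Pathologists outline regions on the slide and tag each with a class:
one of the diagnostic grades, or a non-diagnostic tag such as
``lymphocytes`` or ``fulguration``.  Supervised pre-training needs
labels per tile, so polygons are reduced to tiles by area overlap:

* a tile takes a diagnostic class when regions of that class cover at
  least half of the tile footprint (``COVER_MIN``);
* if several diagnostic classes each reach the coverage bar, the most
  severe wins — consistent with the ordinal MIL premise that severity
  dominates;
* non-diagnostic tags never assign a label, and tiles covered only by
  them are excluded from pre-training.

Annotations are serialised as a GeoJSON FeatureCollection whose
features carry a ``class`` property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from shapely.geometry import Polygon, box, shape

from .ordinal import ContractViolation, OrdinalLabelSpace
from .tiling import TileRef

__all__ = ["RegionAnnotation", "NON_DIAGNOSTIC_TAGS", "tile_labels_from_regions",
           "read_geojson", "write_geojson"]

#: Annotation tags that carry no diagnostic grade.
NON_DIAGNOSTIC_TAGS = ("lymphocytes", "fulguration")

#: Minimum fraction of a tile's area a diagnostic class must cover.
COVER_MIN = 0.5


@dataclass(frozen=True)
class RegionAnnotation:
    """A polygon region on a slide with a class tag (level-0 coordinates)."""

    slide_id: str
    polygon: Polygon
    class_tag: str

    def __post_init__(self) -> None:
        poly = self.polygon
        if not poly.is_valid:
            poly = poly.buffer(0)  # standard cleaning of self-intersections
            object.__setattr__(self, "polygon", poly)
        if poly.is_empty or poly.area <= 0:
            raise ContractViolation(f"degenerate annotation polygon on slide {self.slide_id!r}")

    def is_diagnostic(self, space: OrdinalLabelSpace) -> bool:
        return self.class_tag in space.names

    def class_index(self, space: OrdinalLabelSpace) -> int:
        if self.class_tag in space.names:
            return space.index_of(self.class_tag)
        if self.class_tag in NON_DIAGNOSTIC_TAGS:
            raise ContractViolation(f"tag {self.class_tag!r} carries no diagnostic class")
        raise ContractViolation(f"unknown annotation class tag {self.class_tag!r}")


def tile_labels_from_regions(
    tiles: Sequence[TileRef],
    annotations: Iterable[RegionAnnotation],
    space: OrdinalLabelSpace,
    cover_min: float = COVER_MIN,
) -> dict[int, int]:
    """Map tile index -> diagnostic class from polygon overlap.

    Coverage is accumulated per class over all regions of that class on
    the tile's slide; ties in coverage are resolved in favour of the
    more severe class.  Tiles where no diagnostic class reaches
    ``cover_min`` receive no label.
    """
    by_slide: dict[str, list[RegionAnnotation]] = {}
    for ann in annotations:
        by_slide.setdefault(ann.slide_id, []).append(ann)
    labels: dict[int, int] = {}
    for i, tile in enumerate(tiles):
        anns = by_slide.get(tile.slide_id)
        if not anns:
            continue
        footprint = box(tile.x, tile.y, tile.x + tile.size_px, tile.y + tile.size_px)
        cover = [0.0] * space.n_classes
        for ann in anns:
            if not ann.is_diagnostic(space):
                continue
            inter = footprint.intersection(ann.polygon).area
            if inter > 0:
                cover[ann.class_index(space)] += inter / footprint.area
        # most severe class reaching the bar wins
        for c in reversed(range(space.n_classes)):
            if cover[c] >= cover_min:
                labels[i] = c
                break
    return labels


def write_geojson(path: str | Path, annotations: Sequence[RegionAnnotation]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": ann.polygon.__geo_interface__,
            "properties": {"slide_id": ann.slide_id, "class": ann.class_tag},
        }
        for ann in annotations
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_geojson(path: str | Path) -> list[RegionAnnotation]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        out.append(
            RegionAnnotation(
                slide_id=props["slide_id"],
                polygon=shape(feat["geometry"]),
                class_tag=props["class"],
            )
        )
    return out
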