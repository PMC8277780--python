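"""Dataset statistics and experiment result tables.

Cohort comparisons in slide-level studies report, per dataset, the
slide count, total extracted tile count, and mean tiles per slide —
a quantity that varies enormously between cancer types because tissue
area drives how many pure-tissue tiles a slide yields.  The helpers
here compute those statistics and the pairwise ratios exactly as such
tables print them: means rounded half-up to two decimals, mean-tile
and tile-count ratios to the nearest integer, slide-count ratios
truncated to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ordinal import ContractViolation
from .tiling import TileManifest

__all__ = ["DatasetStats", "dataset_stats", "dataset_stats_from_counts", "results_table"]


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _truncate(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return int(x * scale) / scale


@dataclass(frozen=True)
class DatasetRow:
    name: str
    n_slides: int
    n_tiles: int

    @property
    def mean_tiles(self) -> float:
        """Mean tiles per slide, rounded half-up to 2 decimals."""
        return _round_half_up(self.n_tiles / self.n_slides)


@dataclass
class DatasetStats:
    """Per-dataset counts plus the pairwise ratios the tables print."""

    rows: list[DatasetRow]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": r.name,
                    "n_slides": r.n_slides,
                    "n_tiles": r.n_tiles,
                    "mean_tiles_per_slide": r.mean_tiles,
                }
                for r in self.rows
            ]
        )

    def _row(self, name: str) -> DatasetRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise ContractViolation(f"no dataset named {name!r}")

    def mean_tiles_ratio(self, a: str, b: str) -> float:
        """Raw ratio of mean tiles per slide (a over b)."""
        return self._row(a).mean_tiles / self._row(b).mean_tiles

    def mean_tiles_ratio_rounded(self, a: str, b: str) -> int:
        """Nearest-integer ratio, the '82x higher' phrasing."""
        return int(_round_half_up(self.mean_tiles_ratio(a, b), 0))

    def tiles_ratio_rounded(self, a: str, b: str) -> int:
        return int(_round_half_up(self._row(a).n_tiles / self._row(b).n_tiles, 0))

    def slides_ratio_truncated(self, a: str, b: str) -> float:
        """Slide-count ratio truncated to one decimal ('8.6x more slides')."""
        return _truncate(self._row(a).n_slides / self._row(b).n_slides)

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)

    def format_text(self) -> str:
        return self.frame().to_string(index=False)


def dataset_stats_from_counts(counts: Mapping[str, tuple[int, int]]) -> DatasetStats:
    """Statistics from (n_slides, n_tiles) pairs keyed by dataset name."""
    rows = []
    for name, (n_slides, n_tiles) in counts.items():
        if n_slides <= 0:
            raise ContractViolation(f"dataset {name!r} has no slides")
        if n_tiles < 0:
            raise ContractViolation(f"dataset {name!r} has a negative tile count")
        rows.append(DatasetRow(name, int(n_slides), int(n_tiles)))
    if not rows:
        raise ContractViolation("no datasets given")
    return DatasetStats(rows)


def dataset_stats(manifests: Mapping[str, TileManifest]) -> DatasetStats:
    """Statistics computed from named tile-manifest collections."""
    counts = {}
    for name, manifest in manifests.items():
        if len(manifest) == 0:
            raise ContractViolation(f"manifest collection {name!r} is empty")
        slides = {t.slide_id for t in manifest.tiles}
        counts[name] = (len(slides), len(manifest))
    return dataset_stats_from_counts(counts)


def results_table(evaluations: Sequence[Mapping], sort_by: str = "size") -> pd.DataFrame:
    """Uniform experiment-results table with the best row flagged.

    Rows are dictionaries of metrics (QWK, accuracy, ...), sorted
    ascending by ``sort_by`` when present; the row with maximal QWK is
    marked in a ``best`` column.
    """
    if not evaluations:
        raise ContractViolation("results_table needs at least one evaluation")
    df = pd.DataFrame(list(evaluations))
    if sort_by in df.columns:
        df = df.sort_values(sort_by, kind="stable").reset_index(drop=True)
    if "qwk" in df.columns:
        df["best"] = False
        df.loc[df["qwk"].idxmax(), "best"] = True
    return df


def format_results_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False)
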