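"""Spatial agreement between a derived and a reference regionalization.

Both classifications are brought onto the same grid (polygon references
are rasterized by cell-center containment) and compared sub-region by
sub-region: each reference sub-region is matched to the derived region
covering the plurality of its cells, its agreement count is the number of
cells falling in that matched region, and the overall agreement is the
summed agreement over the summed sub-region cell counts, as a percentage.
A strict mode instead credits a sub-region only when it lies wholly inside
one derived region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .clustering import RegionClassification
from .occurrence_grid import GridSpec

__all__ = ["OverlapReport", "rasterize_reference", "overlap_agreement",
           "read_reference_polygons", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    """Per-sub-region matches and the overall percentage agreement."""

    per_subregion: pd.DataFrame  # reference label, n_cells, matched, agreement
    confusion: pd.DataFrame      # reference x derived cell counts
    overall_agreement: float     # percent in [0, 100]
    mode: str = "plurality"


def read_reference_polygons(path) -> list[tuple[str, object]]:
    """Read labelled polygons from text: one ``label<TAB>WKT`` per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            label, wkt = line.split("\t", 1)
            out.append((label, shapely.from_wkt(wkt)))
    if not out:
        raise ValueError(f"no polygons in {path}")
    return out


def rasterize_reference(reference, grid: GridSpec) -> RegionClassification:
    """Convert a reference scheme to cell labels on ``grid``.

    ``reference`` is either an already-gridded :class:`RegionClassification`
    (validated against the grid extent and passed through) or a list of
    ``(label, polygon)`` pairs in projected coordinates: each cell takes
    the label of the polygon containing its center, later-listed polygons
    win overlaps (with a logged warning), and cells whose center lies in
    no polygon stay unlabeled.
    """
    if isinstance(reference, RegionClassification):
        for cell in reference.labels:
            r, c = cell
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"reference cell {cell} outside grid extent")
        return reference
    labels: dict = {}
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                             indexing="ij")
    cx, cy = grid.cell_center(rows.ravel(), cols.ravel())
    celllist = list(zip(rows.ravel().tolist(), cols.ravel().tolist()))
    for label, geom in reference:
        inside = shapely.intersects_xy(geom, cx, cy)
        for cell, hit in zip(celllist, inside):
            if hit:
                if cell in labels and labels[cell] != label:
                    logger.warning("cell %s covered by %s and %s; keeping %s",
                                   cell, labels[cell], label, label)
                labels[cell] = label
    if not labels:
        raise ValueError("no grid cell centers fall inside the reference polygons "
                         "(extent or CRS mismatch?)")
    return RegionClassification(labels=labels, k=len(set(labels.values())),
                                provenance="rasterized")


def overlap_agreement(derived: RegionClassification, reference: RegionClassification,
                      mode: str = "plurality") -> OverlapReport:
    """Score agreement between two classifications of the same grid.

    Comparison is restricted to cells labeled (not -1) in both schemes.
    Plurality mode matches every reference sub-region to its modal derived
    region (ties broken toward the larger derived region, then by label
    order) and credits the matched cells; strict mode credits all-or-none
    on whole containment.  The overall percentage is invariant to any
    bijective relabeling of either side.
    """
    if mode not in ("plurality", "strict"):
        raise ValueError("mode must be 'plurality' or 'strict'")
    common = [c for c, lab in reference.labels.items()
              if lab != -1 and derived.labels.get(c, -1) != -1]
    if not common:
        raise ValueError("classifications share no labeled cells")
    ref = pd.Series({c: reference.labels[c] for c in common})
    der = pd.Series({c: derived.labels[c] for c in common})
    confusion = pd.crosstab(ref, der)
    confusion.index.name = "reference"
    confusion.columns.name = "derived"
    derived_sizes = der.value_counts()

    rows = []
    total = 0
    agree = 0
    for ref_label, counts in confusion.iterrows():
        n_cells = int(counts.sum())
        best = counts.max()
        tied = counts[counts == best].index
        matched = sorted(tied, key=lambda d: (-derived_sizes[d], str(d)))[0]
        if mode == "plurality":
            agreement = int(best)
        else:
            agreement = n_cells if int(best) == n_cells else 0
        rows.append({"reference": ref_label, "n_cells": n_cells,
                     "matched": matched, "agreement": agreement})
        total += n_cells
        agree += agreement
    per_subregion = pd.DataFrame(rows)
    overall = 100.0 * agree / total
    return OverlapReport(per_subregion=per_subregion, confusion=confusion,
                         overall_agreement=overall, mode=mode)


def write_report(report: OverlapReport, path, confusion_path=None) -> None:
    report.per_subregion.assign(overall_agreement=report.overall_agreement) \
        .to_csv(path, index=False)
    if confusion_path is not None:
        report.confusion.to_csv(confusion_path)
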