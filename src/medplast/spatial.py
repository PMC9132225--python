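"""Layer-resolved spatial maps, channel counts, and edge flags.

Each grid cell of a slice gets exactly one category:

* ``stimulation`` -- the stimulating electrode,
* ``plasticity`` -- activated channel whose last-window call crossed the
  potentiation/depression threshold,
* ``silenced`` -- activated channel whose response collapsed after LFS,
* ``activated_only`` -- activated, no plasticity call,
* ``recruited`` -- silent at baseline, supra-threshold after TBS,
* ``inactive`` -- everything else.

A recruited cell is an *edge* cell when at least one of its 8 grid
neighbors (counting off-grid sides as outside) is not baseline-activated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridLayout
from .plasticity import LABEL_UNCHANGED
from .qc import QCReport, STATUS_INACTIVE

CAT_INACTIVE = "inactive"
CAT_ACTIVATED_ONLY = "activated_only"
CAT_PLASTICITY = "plasticity"
CAT_RECRUITED = "recruited"
CAT_SILENCED = "silenced"
CAT_STIMULATION = "stimulation"
CATEGORIES = (CAT_INACTIVE, CAT_ACTIVATED_ONLY, CAT_PLASTICITY,
              CAT_RECRUITED, CAT_SILENCED, CAT_STIMULATION)


@dataclass
class SpatialMap:
    """Exclusive per-cell categories for one slice on its grid layout."""

    slice_id: str
    layout: GridLayout
    cells: pd.DataFrame   # channel_id, row, col, layer, category, activated

    def category_of(self, channel_id: int) -> str:
        return self.cells.set_index("channel_id").loc[channel_id, "category"]

    def to_dict(self) -> dict:
        return {
            "slice_id": self.slice_id,
            "layout": self.layout.to_dict(),
            "cells": self.cells.to_dict(orient="records"),
        }


def build_spatial_map(calls: pd.DataFrame | None,
                      recruitment: pd.DataFrame | None,
                      qc: QCReport,
                      layout: GridLayout,
                      slice_id: str | None = None) -> SpatialMap:
    """Combine QC, plasticity calls and recruitment calls into one map.

    ``calls`` may be None (no plasticity analysis); ``recruitment`` may be
    None (no recruitment/silencing analysis).  Raises a consistency error if
    a channel is simultaneously recruited and baseline-activated.
    """
    slice_id = slice_id or qc.slice_id
    activated = {
        int(r.channel_id): r.status != STATUS_INACTIVE
        for r in qc.channels.itertuples()
    }
    label_of: dict[int, str] = {}
    if calls is not None:
        label_of = {int(r.channel_id): r.label for r in calls.itertuples()}
    recruited, silenced = set(), set()
    if recruitment is not None:
        recruited = {int(r.channel_id) for r in recruitment.itertuples() if r.recruited}
        silenced = {int(r.channel_id) for r in recruitment.itertuples() if r.silenced}

    stim = layout.stim_channel_id
    rows = []
    for ch in range(1, layout.n_channels + 1):
        r, c = layout.rc(ch)
        is_act = bool(activated.get(ch, False))
        if ch in recruited and is_act:
            raise ValueError(
                f"channel {ch}: recruited but also baseline-activated "
                "(inconsistent inputs)")
        if ch in silenced and not is_act:
            raise ValueError(
                f"channel {ch}: silenced but never baseline-activated "
                "(inconsistent inputs)")
        if ch == stim:
            cat = CAT_STIMULATION
        elif ch in recruited:
            cat = CAT_RECRUITED
        elif ch in silenced:
            cat = CAT_SILENCED
        elif is_act and label_of.get(ch, LABEL_UNCHANGED) != LABEL_UNCHANGED:
            cat = CAT_PLASTICITY
        elif is_act:
            cat = CAT_ACTIVATED_ONLY
        else:
            cat = CAT_INACTIVE
        rows.append({
            "channel_id": ch, "row": r, "col": c,
            "layer": layout.layer_of_channel(ch),
            "category": cat, "activated": is_act and ch != stim,
        })
    return SpatialMap(slice_id, layout, pd.DataFrame(rows))


def count_by_layer(spatial_map: SpatialMap) -> pd.DataFrame:
    """Per-layer channel counts with the conservation invariant.

    ``n_with_plasticity`` counts channels whose response changed
    (``plasticity`` cells plus ``silenced`` cells, which are maximally
    depressed); ``n_without_plasticity`` the remaining activated channels,
    so ``n_with + n_without = n_active`` per layer.  Recruited and silenced
    cells are also counted separately.
    """
    cells = spatial_map.cells
    out = []
    for layer in ("superficial", "deep", "outside"):
        sub = cells.loc[cells.layer == layer]
        n_with = int(((sub.category == CAT_PLASTICITY)
                      | (sub.category == CAT_SILENCED)).sum())
        n_active = int(sub.activated.sum())
        out.append({
            "slice_id": spatial_map.slice_id,
            "layer": layer,
            "n_active": n_active,
            "n_with_plasticity": n_with,
            "n_without_plasticity": n_active - n_with,
            "n_recruited": int((sub.category == CAT_RECRUITED).sum()),
            "n_silenced": int((sub.category == CAT_SILENCED).sum()),
        })
    return pd.DataFrame(out)


def flag_edge_channels(spatial_map: SpatialMap,
                       connectivity: int = 8) -> pd.DataFrame:
    """Edge flags for recruited cells, plus the fraction at the edge.

    A recruited cell is *edge* iff at least one of its neighbors (8- or
    4-connected; off-grid sides count as outside) is not in the
    baseline-activated set.  Returns the recruited rows with an ``edge``
    column; ``df.attrs['edge_fraction']`` holds the summary fraction
    (NaN when nothing was recruited).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    layout = spatial_map.layout
    cells = spatial_map.cells
    active_ids = set(cells.loc[cells.activated, "channel_id"].astype(int))
    rec = cells.loc[cells.category == CAT_RECRUITED].copy()

    def _is_edge(ch: int) -> bool:
        row, col = layout.rc(ch)
        if layout.on_border(ch):
            return True
        for nb in layout.neighbors8(ch):
            nr, nc = layout.rc(nb)
            if connectivity == 4 and abs(nr - row) + abs(nc - col) != 1:
                continue
            if nb not in active_ids:
                return True
        return False

    rec["edge"] = [_is_edge(int(ch)) for ch in rec.channel_id]
    rec.attrs["edge_fraction"] = float(rec.edge.mean()) if len(rec) else float("nan")
    return rec
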