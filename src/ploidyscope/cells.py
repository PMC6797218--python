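"""Grouping nuclei into cells, marker-based typing and viability filtering.

Cells are delineated either by a supplied label mask (e.g. the generator's
ground-truth mask) or by thresholding the two marker channels and labelling
connected components. Each nucleus is assigned to the cell label containing
its centroid. A cell is typed CM when its cardiomyocyte-marker mean exceeds
both the marker threshold and the endothelial-marker mean (EC symmetrically,
otherwise "other"), and is alive when its live/dead mean is below that
channel's threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .synth import ImageStack

__all__ = ["CellTyper", "group_and_type_cells", "filter_viable",
           "robust_channel_threshold"]

log = logging.getLogger(__name__)

CELL_COLUMNS = ["cell_id", "type", "alive", "nucleation", "nucleation_binned",
                "cm_marker_mean", "ec_marker_mean", "livedead_mean", "area"]


def robust_channel_threshold(channel: np.ndarray) -> float:
    """Foreground threshold for a marker/live-dead channel.

    Otsu's threshold, floored at background median + 6 robust sigmas (MAD
    based). The floor keeps a channel with little or no lit area — e.g. the
    live/dead channel of an all-alive scene, where Otsu just splits camera
    noise — from declaring background pixels as signal.
    """
    channel = np.asarray(channel, dtype=np.float64)
    med = float(np.median(channel))
    sigma = 1.4826 * float(np.median(np.abs(channel - med)))
    floor = med + 6.0 * max(sigma, 1e-6)
    if np.ptp(channel) == 0:
        return floor
    return max(float(threshold_otsu(channel)), floor)


def _label_cells_from_markers(stack: ImageStack, thresholds: dict[str, float],
                              min_area: float) -> np.ndarray:
    """Label connected components of the union of thresholded marker channels."""
    union = np.zeros(stack.shape, dtype=bool)
    for name in ("cm_marker", "ec_marker"):
        union |= stack.channels[name].astype(np.float64) > thresholds[name]
    labels, _ = ndi.label(union)
    if labels.max():
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        if small.size:
            labels[np.isin(labels, small[small > 0])] = 0
    return labels.astype(np.int32)


class CellTyper(BaseEstimator):
    """Assign nuclei to cells and type cells by their marker intensities.

    Parameters
    ----------
    marker_thresholds : "auto" or dict
        Per-channel absolute thresholds for ``cm_marker``, ``ec_marker`` and
        ``livedead``; ``"auto"`` derives each with
        :func:`robust_channel_threshold`.
    min_cell_area : float
        Marker-derived components smaller than this are dropped (debris).
    """

    def __init__(self, marker_thresholds="auto", min_cell_area: float = 50.0):
        self.marker_thresholds = marker_thresholds
        self.min_cell_area = min_cell_area

    def fit(self, X=None, y=None):
        """No-op; typing is stateless."""
        return self

    def assign(self, nuclei: pd.DataFrame, stack: ImageStack,
               cell_mask: np.ndarray | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return ``(cells, nuclei)``; nuclei gain their ``cell_id``.

        Nuclei whose centroid falls in no cell keep ``cell_id`` NA and are
        excluded from cell records (count logged). Cells containing no
        nucleus are excluded likewise.
        """
        if self.marker_thresholds == "auto":
            thresholds = {name: robust_channel_threshold(stack.channels[name])
                          for name in ("cm_marker", "ec_marker", "livedead")}
        else:
            thresholds = dict(self.marker_thresholds)
        if cell_mask is None:
            cell_mask = _label_cells_from_markers(stack, thresholds,
                                                  self.min_cell_area)
        cell_mask = np.asarray(cell_mask)

        nuclei = nuclei.copy()
        if len(nuclei):
            iy = np.clip(np.rint(nuclei["cy"]).astype(int), 0,
                         cell_mask.shape[0] - 1)
            ix = np.clip(np.rint(nuclei["cx"]).astype(int), 0,
                         cell_mask.shape[1] - 1)
            owner = cell_mask[iy, ix]
            nuclei["cell_id"] = pd.array(
                np.where(owner > 0, owner, -1), dtype="Int64")
            nuclei.loc[nuclei["cell_id"] == -1, "cell_id"] = pd.NA
            n_orphan = int(nuclei["cell_id"].isna().sum())
            if n_orphan:
                log.info("%d nuclei fell outside every cell mask", n_orphan)
        else:
            nuclei["cell_id"] = pd.array([], dtype="Int64")

        ids = np.unique(cell_mask)
        ids = ids[ids > 0]
        counts = (nuclei.dropna(subset=["cell_id"])
                  .groupby("cell_id").size() if len(nuclei) else pd.Series(dtype=int))
        areas_all = np.bincount(cell_mask.ravel(),
                                minlength=int(ids.max()) + 1 if ids.size else 1)
        channel_means = {
            name: ndi.mean(stack.channels[name].astype(np.float64),
                           labels=cell_mask, index=ids) if ids.size else []
            for name in ("cm_marker", "ec_marker", "livedead")}
        records = []
        n_empty = 0
        for k, cid in enumerate(ids):
            n_nuc = int(counts.get(cid, 0))
            if n_nuc == 0:
                n_empty += 1
                continue
            area = int(areas_all[cid])
            means = {name: float(channel_means[name][k])
                     for name in ("cm_marker", "ec_marker", "livedead")}
            cm, ec = means["cm_marker"], means["ec_marker"]
            if cm > thresholds["cm_marker"] and cm >= ec:
                ctype = "CM"
            elif ec > thresholds["ec_marker"] and ec > cm:
                ctype = "EC"
            else:
                ctype = "other"
            alive = means["livedead"] < thresholds["livedead"]
            records.append((int(cid), ctype, bool(alive), n_nuc,
                            min(n_nuc, 4), cm, ec, means["livedead"], area))
        if n_empty:
            log.info("excluded %d cells containing no nucleus", n_empty)
        cells = pd.DataFrame(records, columns=CELL_COLUMNS)
        return cells, nuclei


def group_and_type_cells(nuclei: pd.DataFrame, stack: ImageStack,
                         cell_mask: np.ndarray | None = None,
                         marker_thresholds="auto",
                         **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`CellTyper.assign`."""
    typer = CellTyper(marker_thresholds=marker_thresholds, **kwargs)
    return typer.assign(nuclei, stack, cell_mask=cell_mask)


def filter_viable(cells: pd.DataFrame) -> pd.DataFrame:
    """Keep live cells only; the removed count is logged.

    Mirrors counting only live cells for nucleation scoring.
    """
    out = cells[cells["alive"]].reset_index(drop=True)
    removed = len(cells) - len(out)
    if removed:
        log.info("filter_viable: removed %d dead cells", removed)
    return out
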