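"""Synthetic fluorescence scenes of fixed ventricular single-cell suspensions.

The generator draws a population of cardiomyocytes (1-4 nuclei each, nuclear
DNA signal proportional to ploidy class with multiplicative lognormal noise)
and diploid mononuclear endothelial reference cells, places them without
overlap, and renders four channels: DNA stain, CM marker, EC marker and a
live/dead stain lit over dead cells. Ground truth (per-cell and per-nucleus
tables plus label masks) is recorded for every drawn quantity, so each
downstream stage of the quantification can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .config import CHANNELS, PLOIDY_CLASSES, PLOIDY_COPY, SceneConfig

__all__ = [
    "ImageStack",
    "GroundTruth",
    "PlacementError",
    "sample_truth",
    "generate_scene",
    "write_scene",
    "read_scene",
]

#: Minimum clear distance (px) between the rendered disks of two cells.
CELL_GAP = 6.0
#: Minimum clear distance (px) between two nuclei of the same cell.
NUCLEUS_GAP = 2.0


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails at the requested density."""


@dataclass
class ImageStack:
    """Named 2D channels of 16-bit intensities plus pixel-size metadata."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.5
    saturated: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class GroundTruth:
    """Truth record of a synthetic scene.

    ``cells`` columns: cell_id, type (CM/EC), alive, nucleation, cy, cx,
    radius. ``nuclei`` columns: nucleus_id, cell_id, ploidy_class,
    drawn_intensity, cy, cx, radius. Label masks use the same integer ids;
    0 is background.
    """

    cells: pd.DataFrame
    nuclei: pd.DataFrame
    cell_mask: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None


_CELL_COLUMNS = ["cell_id", "type", "alive", "nucleation", "cy", "cx", "radius"]
_NUC_COLUMNS = ["nucleus_id", "cell_id", "ploidy_class", "drawn_intensity",
                "cy", "cx", "radius"]


def _draw_intensity(rng: np.random.Generator, ploidy_class: str,
                    base_2n: float, cv: float) -> float:
    """Integrated DNA signal: (copy/2) * base * lognormal with mean 1, CV cv."""
    scale = PLOIDY_COPY[ploidy_class] / 2.0
    if cv == 0:
        return scale * base_2n
    sigma = math.sqrt(math.log1p(cv * cv))
    return scale * base_2n * rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma)


def sample_truth(config: SceneConfig,
                 rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw cell types, viability, nucleation, ploidy and intensities.

    Geometry (positions, masks) is not sampled here; this is the fast path
    used for composition statistics and for large replicate simulations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cm, n_ec = config.n_cardiomyocytes, config.n_endothelial
    n_total = n_cm + n_ec
    cell_ids = np.arange(1, n_total + 1)
    types = np.where(cell_ids <= n_cm, "CM", "EC")

    nucleation = np.ones(n_total, dtype=int)
    if n_cm:
        nucleation[:n_cm] = rng.choice(
            4, size=n_cm, p=config.nucleation_probs) + 1
    alive = rng.random(n_total) >= config.dead_fraction

    owner = np.repeat(cell_ids, nucleation)
    is_cm_nuc = owner <= n_cm
    mono_nuc = np.repeat(nucleation == 1, nucleation)
    n_nuc = len(owner)
    class_idx = np.zeros(n_nuc, dtype=int)  # EC nuclei stay 2N
    sel_mono = is_cm_nuc & mono_nuc
    sel_multi = is_cm_nuc & ~mono_nuc
    if sel_mono.any():
        class_idx[sel_mono] = rng.choice(
            3, size=int(sel_mono.sum()), p=config.mono_ploidy_probs)
    if sel_multi.any():
        class_idx[sel_multi] = rng.choice(
            3, size=int(sel_multi.sum()), p=config.multi_ploidy_probs)
    classes = np.asarray(PLOIDY_CLASSES)[class_idx]
    copy = np.array([PLOIDY_COPY[c] for c in PLOIDY_CLASSES])[class_idx]

    noise = np.ones(n_nuc)
    if config.intensity_cv > 0 and n_nuc:
        sigma = math.sqrt(math.log1p(config.intensity_cv ** 2))
        noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma,
                              size=n_nuc)
    intensity = (copy / 2.0) * config.base_2n_intensity * noise

    nan = np.full(n_total, np.nan)
    cells_df = pd.DataFrame({
        "cell_id": cell_ids, "type": types, "alive": alive,
        "nucleation": nucleation, "cy": nan, "cx": nan, "radius": nan})
    nan_n = np.full(n_nuc, np.nan)
    nuclei_df = pd.DataFrame({
        "nucleus_id": np.arange(1, n_nuc + 1), "cell_id": owner,
        "ploidy_class": classes, "drawn_intensity": intensity,
        "cy": nan_n, "cx": nan_n, "radius": nan_n})
    return GroundTruth(cells=cells_df, nuclei=nuclei_df)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _min_cell_radius(nucleation: int, nucleus_radius: float) -> float:
    """Smallest cell disk that fits `nucleation` nuclei on the placement ring."""
    if nucleation == 1:
        return nucleus_radius + 2.0
    spacing = 2.0 * nucleus_radius + NUCLEUS_GAP
    ring = spacing / (2.0 * math.sin(math.pi / nucleation))
    return ring + nucleus_radius + 1.0


def _place_cells(config: SceneConfig, radii: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping rejection sampling of cell centres on a grid index."""
    n = len(radii)
    h, w = config.image_shape
    centers = np.empty((n, 2))
    if n == 0:
        return centers
    max_r = float(radii.max())
    bin_size = 2.0 * max_r + CELL_GAP
    grid: dict[tuple[int, int], list[int]] = {}
    max_attempts = 300 * n
    attempts = 0
    for i in range(n):
        r = radii[i]
        lo_y, hi_y = r + 1, h - r - 1
        lo_x, hi_x = r + 1, w - r - 1
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementError(
                f"cell radius {r:.1f}px does not fit image {config.image_shape}")
        while True:
            attempts += 1
            if attempts > max_attempts:
                density = (math.pi * float((radii ** 2).sum())) / (h * w)
                raise PlacementError(
                    f"failed to place {n} non-overlapping cells after "
                    f"{max_attempts} attempts (areal density {density:.2f}); "
                    "enlarge image_shape or reduce cell count/radius")
            y = rng.uniform(lo_y, hi_y)
            x = rng.uniform(lo_x, hi_x)
            gy, gx = int(y // bin_size), int(x // bin_size)
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for j in grid.get((gy + dy, gx + dx), ()):
                        d = math.hypot(y - centers[j, 0], x - centers[j, 1])
                        if d < r + radii[j] + CELL_GAP:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[i] = (y, x)
                grid.setdefault((gy, gx), []).append(i)
                break
    return centers


def _nucleus_positions(center: np.ndarray, nucleation: int,
                       nucleus_radius: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Nucleus centres: jittered centre for 1, a rotated ring for 2-4."""
    cy, cx = center
    if nucleation == 1:
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, 1.0)
        return np.array([[cy + rad * math.sin(ang), cx + rad * math.cos(ang)]])
    spacing = 2.0 * nucleus_radius + NUCLEUS_GAP
    ring = spacing / (2.0 * math.sin(math.pi / nucleation))
    phase = rng.uniform(0, 2 * math.pi)
    angles = phase + 2 * math.pi * np.arange(nucleation) / nucleation
    return np.stack([cy + ring * np.sin(angles),
                     cx + ring * np.cos(angles)], axis=1)


def _paint_disk(img: np.ndarray, cy: float, cx: float, radius: float,
                value: float, label_img: np.ndarray | None = None,
                label: int = 0) -> int:
    """Add `value` per pixel over a disk; optionally set labels. Returns area."""
    h, w = img.shape
    y0, y1 = max(0, int(cy - radius - 1)), min(h, int(cy + radius + 2))
    x0, x1 = max(0, int(cx - radius - 1)), min(w, int(cx + radius + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    img[y0:y1, x0:x1][disk] += value
    if label_img is not None:
        label_img[y0:y1, x0:x1][disk] = label
    return int(disk.sum())


def _disk_area(img_shape, cy, cx, radius) -> int:
    h, w = img_shape
    y0, y1 = max(0, int(cy - radius - 1)), min(h, int(cy + radius + 2))
    x0, x1 = max(0, int(cx - radius - 1)), min(w, int(cx + radius + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return int(((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2).sum())


def generate_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a full synthetic scene with ground-truth masks and tables.

    Each nucleus is rendered as a uniform disk whose summed DNA-stain signal
    equals its drawn integrated intensity, then the whole channel is blurred
    with a Gaussian PSF (sum-preserving away from borders) and camera
    background plus Gaussian noise is added. Marker channels are lit over the
    corresponding cell masks; the live/dead channel over dead cells.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_truth(config, rng)
    cells, nuclei = truth.cells, truth.nuclei
    h, w = config.image_shape
    n_cells = len(cells)

    # geometry: per-cell radius (clipped so its nuclei fit), per-nucleus radius
    nuc_radius = np.clip(
        rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd,
                   len(nuclei)),
        max(2.0, config.nucleus_radius_mean - 3 * config.nucleus_radius_sd - 1),
        None)
    nuclei["radius"] = nuc_radius
    max_nuc_r = nuclei.groupby("cell_id")["radius"].max() if len(nuclei) else None
    cell_radius = np.clip(
        rng.normal(config.cell_radius_mean, config.cell_radius_sd, n_cells),
        2.0, None)
    if n_cells:
        need = np.array([
            _min_cell_radius(int(nuc), float(max_nuc_r.loc[cid]))
            for cid, nuc in zip(cells["cell_id"], cells["nucleation"])])
        cell_radius = np.maximum(cell_radius, need)
    cells["radius"] = cell_radius
    centers = _place_cells(config, cell_radius, rng)
    cells[["cy", "cx"]] = centers

    dapi = np.zeros((h, w))
    cm_marker = np.zeros((h, w))
    ec_marker = np.zeros((h, w))
    livedead = np.zeros((h, w))
    cell_mask = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), dtype=np.int32)

    nuc_by_cell = dict(iter(nuclei.groupby("cell_id"))) if len(nuclei) else {}
    for i, row in cells.iterrows():
        target = cm_marker if row["type"] == "CM" else ec_marker
        _paint_disk(target, row.cy, row.cx, row.radius,
                    config.marker_intensity, cell_mask, int(row.cell_id))
        if not row.alive:
            _paint_disk(livedead, row.cy, row.cx, row.radius,
                        config.livedead_intensity)
        sub = nuc_by_cell[row.cell_id]
        r_nuc = float(sub["radius"].max())
        pos = _nucleus_positions(centers[i], int(row.nucleation), r_nuc, rng)
        for (ny, nx), (_, nrow) in zip(pos, sub.iterrows()):
            area = _disk_area((h, w), ny, nx, nrow.radius)
            _paint_disk(dapi, ny, nx, nrow.radius,
                        nrow.drawn_intensity / max(area, 1),
                        nucleus_mask, int(nrow.nucleus_id))
            nuclei.loc[nrow.name, ["cy", "cx"]] = (ny, nx)

    channels_f = {"dapi": dapi, "cm_marker": cm_marker,
                  "ec_marker": ec_marker, "livedead": livedead}
    out: dict[str, np.ndarray] = {}
    saturated: dict[str, bool] = {}
    for name in config.channels:
        img = channels_f[name]
        if config.psf_sigma > 0:
            img = ndi.gaussian_filter(img, config.psf_sigma)
        img = img + config.background_level
        if config.background_noise_sd > 0:
            img = img + rng.normal(0.0, config.background_noise_sd, img.shape)
        saturated[name] = bool((img > 65535).any())
        out[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth.cell_mask = cell_mask
    truth.nucleus_mask = nucleus_mask
    stack = ImageStack(channels=out, pixel_size_um=config.pixel_size_um,
                       saturated=saturated)
    return stack, truth


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------

def write_scene(out_dir, stack: ImageStack, truth: GroundTruth,
                config: SceneConfig | None = None) -> None:
    """Write images.tif, label masks, truth tables and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(stack.channels)
    meta = {"channels": names, "pixel_size_um": stack.pixel_size_um,
            "saturated": stack.saturated}
    tifffile.imwrite(out / "images.tif",
                     np.stack([stack.channels[n] for n in names]),
                     photometric="minisblack",
                     description=json.dumps(meta))
    if truth.cell_mask is not None:
        tifffile.imwrite(out / "cell_mask.tif", truth.cell_mask)
    if truth.nucleus_mask is not None:
        tifffile.imwrite(out / "nucleus_mask.tif", truth.nucleus_mask)
    truth.cells.to_csv(out / "truth_cells.csv", index=False)
    truth.nuclei.to_csv(out / "truth_nuclei.csv", index=False)
    if config is not None:
        config.to_yaml(out / "config.resolved.yaml")


def read_scene(in_dir) -> tuple[ImageStack, GroundTruth]:
    """Read back what :func:`write_scene` wrote."""
    src = Path(in_dir)
    with tifffile.TiffFile(src / "images.tif") as tf:
        pages = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    channels = {n: pages[i] for i, n in enumerate(meta["channels"])}
    stack = ImageStack(channels=channels,
                       pixel_size_um=meta.get("pixel_size_um", 0.5),
                       saturated=meta.get("saturated", {}))
    cell_mask = nucleus_mask = None
    if (src / "cell_mask.tif").exists():
        cell_mask = tifffile.imread(src / "cell_mask.tif")
    if (src / "nucleus_mask.tif").exists():
        nucleus_mask = tifffile.imread(src / "nucleus_mask.tif")
    cells = pd.read_csv(src / "truth_cells.csv")
    nuclei = pd.read_csv(src / "truth_nuclei.csv")
    return stack, GroundTruth(cells=cells, nuclei=nuclei,
                              cell_mask=cell_mask, nucleus_mask=nucleus_mask)
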