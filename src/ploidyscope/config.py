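"""Scene configuration for synthetic ventricular single-cell suspensions.

A :class:`SceneConfig` is a parametric description of one imaged field of a
fixed ventricular suspension: how many cardiomyocytes (CMs) and endothelial
cells (ECs) it contains, the nucleation distribution of the CMs, the nuclear
ploidy distributions, the optics (PSF, background) and the camera geometry.
Presets package the compositions reported for particular strains/species.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SceneConfig",
    "preset_config",
    "available_presets",
    "plan_image_shape",
    "PLOIDY_CLASSES",
    "CHANNELS",
]

#: Nuclear DNA-content classes modelled by the generator. The quantification
#: reports 2N vs >=4N; mass beyond 4N is carried by the 8N class.
PLOIDY_CLASSES = ("2N", "4N", "8N")

#: Copy number of each class relative to haploid (2N diploid = 2, ...).
PLOIDY_COPY = {"2N": 2, "4N": 4, "8N": 8}

#: Canonical channel order: DNA stain, cardiomyocyte marker (cTnT-like),
#: endothelial marker (CD31-like), fixable live/dead stain.
CHANNELS = ("dapi", "cm_marker", "ec_marker", "livedead")

_PROB_TOL = 1e-9


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ValueError(f"{name} must have {n} entries, got {len(probs)}")
    if any(p < 0 for p in probs):
        raise ValueError(f"{name} has negative entries: {probs}")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} must sum to 1 (got {sum(probs)!r})")
    return probs


@dataclass(frozen=True)
class SceneConfig:
    """Parametric description of one synthetic suspension scene.

    Parameters
    ----------
    n_cardiomyocytes, n_endothelial
        Cell counts. Endothelial cells are always mononuclear and diploid;
        their nuclei provide the diploid intensity standard downstream.
    nucleation_probs
        Probability of a CM carrying 1, 2, 3 or 4 nuclei.
    mono_ploidy_probs, multi_ploidy_probs
        Probability of each nuclear class (2N, 4N, 8N) for the nucleus of a
        mononuclear CM, and for each nucleus of a multinucleated CM.
    base_2n_intensity
        Expected integrated DNA-stain signal of one diploid nucleus
        (arbitrary fluorescence counts). A 4N nucleus draws twice this in
        expectation, an 8N nucleus four times.
    intensity_cv
        Coefficient of variation of the multiplicative lognormal noise on
        per-nucleus integrated signal (dimensionless).
    nucleus_radius_mean, nucleus_radius_sd, cell_radius_mean, cell_radius_sd
        Rendered disk geometry in pixels.
    psf_sigma
        Gaussian point-spread sigma in pixels applied to every channel.
    background_level, background_noise_sd
        Additive camera background (counts) and its Gaussian noise.
    dead_fraction
        Probability that a cell (CM or EC) is dead; dead cells are lit in
        the live/dead channel but are otherwise morphologically normal.
    image_shape
        (rows, cols) in pixels.
    marker_intensity, livedead_intensity
        Per-pixel amplitude of the lit marker / live-dead signal (counts).
    seed
        Seed for the scene's random stream.
    """

    n_cardiomyocytes: int = 100
    n_endothelial: int = 30
    nucleation_probs: tuple[float, ...] = (0.05, 0.93, 0.015, 0.005)
    mono_ploidy_probs: tuple[float, ...] = (0.5, 0.5, 0.0)
    multi_ploidy_probs: tuple[float, ...] = (0.95, 0.05, 0.0)
    base_2n_intensity: float = 6000.0
    intensity_cv: float = 0.15
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.4
    cell_radius_mean: float = 13.0
    cell_radius_sd: float = 1.5
    psf_sigma: float = 1.0
    background_level: float = 100.0
    background_noise_sd: float = 5.0
    dead_fraction: float = 0.1
    image_shape: tuple[int, int] = (768, 768)
    marker_intensity: float = 1500.0
    livedead_intensity: float = 2000.0
    channels: tuple[str, ...] = CHANNELS
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cardiomyocytes < 0 or self.n_endothelial < 0:
            raise ValueError("cell counts must be >= 0")
        object.__setattr__(
            self, "nucleation_probs",
            _check_probs("nucleation_probs", self.nucleation_probs, 4))
        object.__setattr__(
            self, "mono_ploidy_probs",
            _check_probs("mono_ploidy_probs", self.mono_ploidy_probs, 3))
        object.__setattr__(
            self, "multi_ploidy_probs",
            _check_probs("multi_ploidy_probs", self.multi_ploidy_probs, 3))
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if self.base_2n_intensity <= 0:
            raise ValueError("base_2n_intensity must be > 0")
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError("dead_fraction must be in [0, 1]")
        shape = tuple(int(s) for s in self.image_shape)
        if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
            raise ValueError(f"image_shape must be 2D and positive, got {shape}")
        object.__setattr__(self, "image_shape", shape)
        if sorted(self.channels) != sorted(CHANNELS):
            raise ValueError(f"channels must be a permutation of {CHANNELS}")
        if self.nucleus_radius_mean <= 0 or self.cell_radius_mean <= 0:
            raise ValueError("radii must be positive")

    def replace(self, **changes) -> "SceneConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nucleation_probs"] = list(self.nucleation_probs)
        d["mono_ploidy_probs"] = list(self.mono_ploidy_probs)
        d["multi_ploidy_probs"] = list(self.multi_ploidy_probs)
        d["image_shape"] = list(self.image_shape)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SceneConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("nucleation_probs", "mono_ploidy_probs",
                    "multi_ploidy_probs", "channels"):
            if key in d:
                d[key] = tuple(d[key])
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Presets
#
# Compositions mirror reported ventricular CM compositions:
#   - naked mole-rat (H. glaber): 30% mononuclear / 70% binucleated CMs;
#     77% of mononuclear CM nuclei are >=4N and 23% diploid, so the
#     mononuclear-diploid level is ~7%.
#   - C57BL/6J mouse: 95% binucleated; mononuclear-diploid ~2%.
#   - A/J mouse: the high end of inbred strains, mononuclear-diploid ~10%.
# Nuclei of multinucleated CMs are predominantly diploid in all presets.
# ---------------------------------------------------------------------------

_PRESETS: dict[str, dict] = {
    "hglaber": dict(
        nucleation_probs=(0.30, 0.70, 0.0, 0.0),
        mono_ploidy_probs=(0.23, 0.77, 0.0),
        multi_ploidy_probs=(0.95, 0.05, 0.0),
    ),
    "c57bl6j": dict(
        nucleation_probs=(0.04, 0.95, 0.008, 0.002),
        mono_ploidy_probs=(0.50, 0.50, 0.0),
        multi_ploidy_probs=(0.95, 0.05, 0.0),
    ),
    "aj": dict(
        nucleation_probs=(0.12, 0.855, 0.02, 0.005),
        # 12% mononuclear x 83.33% diploid -> 10% mononuclear-diploid
        mono_ploidy_probs=(10.0 / 12.0, 2.0 / 12.0, 0.0),
        multi_ploidy_probs=(0.95, 0.05, 0.0),
    ),
}


def available_presets() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))


def preset_config(name: str, **overrides) -> SceneConfig:
    """Return the packaged :class:`SceneConfig` for a strain/species key.

    Keys: ``hglaber`` (naked mole-rat), ``c57bl6j``, ``aj`` (A/J mouse).
    Additional keyword arguments override any config field (e.g. cell
    counts, image shape, seed).
    """
    key = name.strip().lower().replace("/", "").replace("_", "").replace("-", "")
    if key not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available presets: "
            f"{', '.join(available_presets())}")
    params = dict(_PRESETS[key])
    params.update(overrides)
    return SceneConfig(**params)


def plan_image_shape(config: SceneConfig, packing: float = 0.22) -> tuple[int, int]:
    """Square image shape giving roughly `packing` areal cell density.

    Rejection-sampled non-overlapping placement is reliable and fast up to
    ~30% packing; the default leaves headroom for the inter-cell gap the
    renderer enforces.
    """
    n = config.n_cardiomyocytes + config.n_endothelial
    if n == 0:
        return config.image_shape
    area = n * math.pi * (config.cell_radius_mean + 3.0) ** 2 / packing
    side = int(np.ceil(math.sqrt(area)))
    return (side, side)
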