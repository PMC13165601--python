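"""Quantized speed-of-sound phantoms.

The imaging targets are per-pixel speed-of-sound (SoS) maps over a square
region of interest (ROI).  Inversion is posed as classification: SoS values
are quantized onto a small ordered grid of levels, label 0 being the water
background (1500 m/s) and labels 1..C-1 the tissue levels in ascending
order.  Two phantom families are generated:

* disc phantoms — a large water-speed primary disc defining the ROI with
  1-4 smaller discs of random quantized SoS inside, optionally warped by a
  smooth random grid distortion (variants: original / distorted / mixed);
* layered brain-like phantoms — nested deformed ellipses emulating skin,
  fat, cortical and cancellous skull, CSF, gray and white matter, with
  pixel-wise SoS drawn uniformly from per-tissue ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.interpolate import RectBivariateSpline

__all__ = [
    "QuantizationScheme", "SoSMap", "DiscPhantomConfig", "BrainPhantomSpec",
    "DEFAULT_SCHEME", "DEFAULT_BRAIN_SPEC",
    "quantize_sos", "labels_to_sos", "labels_to_onehot",
    "make_disc_phantom", "apply_grid_distortion", "make_dataset",
    "make_brain_phantom",
]


@dataclass(frozen=True)
class QuantizationScheme:
    """Ordered discrete SoS levels with a dedicated water class (label 0)."""

    class_values: tuple[float, ...] = (900., 1125., 1350., 1575., 1800., 2025., 2250.)
    water_value: float = 1500.0

    def __post_init__(self):
        vals = np.asarray(self.class_values, dtype=float)
        if vals.ndim != 1 or len(vals) < 1:
            raise ValueError("class_values must be a non-empty 1D sequence")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("class_values must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.class_values) + 1

    @property
    def representatives(self) -> np.ndarray:
        """Representative SoS per label: water first, then the class grid."""
        return np.asarray((self.water_value,) + tuple(self.class_values))

    @property
    def sos_range(self) -> float:
        reps = self.representatives
        return float(reps.max() - reps.min())


DEFAULT_SCHEME = QuantizationScheme()


@dataclass
class SoSMap:
    """Ground-truth SoS grid with its class-label grid."""

    sos: np.ndarray               # H x W, m/s
    labels: np.ndarray            # H x W, int in [0, C)
    scheme: QuantizationScheme = DEFAULT_SCHEME
    pixel_size_mm: float = 0.25
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sos = np.asarray(self.sos, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.sos.shape != self.labels.shape:
            raise ValueError("sos and labels must have the same shape")
        if not np.all(np.isfinite(self.sos)) or np.any(self.sos <= 0):
            raise ValueError("SoS values must be finite and positive")

    @property
    def shape(self):
        return self.sos.shape


def quantize_sos(values, scheme: QuantizationScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Map SoS values to the nearest representative level's label.

    Ties are broken toward the lower label index.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantize_sos requires finite SoS values")
    reps = scheme.representatives                        # (C,)
    dist = np.abs(arr[..., None] - reps)                 # (..., C)
    labels = np.argmin(dist, axis=-1)                    # argmin -> lowest index on ties
    return labels.astype(np.uint8)


def labels_to_sos(labels, scheme: QuantizationScheme = DEFAULT_SCHEME) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() >= scheme.n_classes:
        raise ValueError(f"labels outside [0, {scheme.n_classes})")
    return scheme.representatives[arr].astype(np.float32)


def labels_to_onehot(labels, n_classes: int) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() >= n_classes:
        raise ValueError(f"labels outside [0, {n_classes})")
    out = np.zeros(arr.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, arr[..., None].astype(np.int64), 1.0, axis=-1)
    return out


# -- disc phantoms ---------------------------------------------------------

@dataclass(frozen=True)
class DiscPhantomConfig:
    size: int = 153
    roi_radius: float = 70.0
    n_discs_range: tuple[int, int] = (1, 4)
    disc_radius_range: tuple[float, float] = (6.0, 25.0)
    scheme: QuantizationScheme = DEFAULT_SCHEME
    pixel_size_mm: float = 0.25

    def __post_init__(self):
        if self.disc_radius_range[1] >= self.roi_radius:
            raise ValueError("inner disc radius range exceeds the ROI disc")
        if self.roi_radius >= self.size / 2 + 1:
            raise ValueError("ROI disc does not fit in the grid")
        lo, hi = self.n_discs_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid disc count range")


def _disc_mask(size: int, center, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def make_disc_phantom(rng_seed: int, config: DiscPhantomConfig = DiscPhantomConfig()
                      ) -> SoSMap:
    """Water background, one primary ROI disc, 1-4 quantized inner discs.

    Later discs paint over earlier ones, so nested/contour structures are
    produced naturally.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(rng_seed)
    scheme = config.scheme
    size = config.size
    sos = np.full((size, size), scheme.water_value, dtype=np.float32)
    center = (size / 2 - 0.5, size / 2 - 0.5)
    roi = _disc_mask(size, center, config.roi_radius)
    # the primary disc carries a randomly chosen class level as its base
    levels = np.asarray(scheme.class_values)
    sos[roi] = rng.choice(levels)

    n_discs = int(rng.integers(config.n_discs_range[0], config.n_discs_range[1] + 1))
    discs = []
    for _ in range(n_discs):
        radius = float(rng.uniform(*config.disc_radius_range))
        # keep the disc fully inside the ROI disc
        max_off = config.roi_radius - radius
        angle = rng.uniform(0, 2 * np.pi)
        dist = max_off * np.sqrt(rng.uniform())
        c = (center[0] + dist * np.sin(angle), center[1] + dist * np.cos(angle))
        value = float(rng.choice(levels))
        sos[_disc_mask(size, c, radius)] = value
        discs.append({"center": c, "radius": radius, "sos": value})

    labels = quantize_sos(sos, scheme)
    return SoSMap(sos, labels, scheme, config.pixel_size_mm,
                  meta={"kind": "disc", "seed": int(rng_seed), "n_discs": n_discs,
                        "roi_radius": config.roi_radius, "discs": discs,
                        "distorted": False})


def apply_grid_distortion(sos_map: SoSMap, rng_seed: int, strength: float = 4.0,
                          lattice: int = 5) -> SoSMap:
    """Warp a phantom with a smooth random displacement field.

    A coarse ``lattice x lattice`` grid of control points is perturbed
    uniformly in [-strength, strength] pixels per axis, interpolated to a
    dense displacement field with a bicubic spline, and applied with
    nearest-neighbour resampling so labels stay on the quantization grid.
    """
    if strength < 0:
        raise ValueError("distortion strength must be >= 0")
    if strength == 0:
        return SoSMap(sos_map.sos.copy(), sos_map.labels.copy(), sos_map.scheme,
                      sos_map.pixel_size_mm, dict(sos_map.meta))
    rng = np.random.default_rng(rng_seed)
    H, W = sos_map.shape
    ctrl_r = np.linspace(0, H - 1, lattice)
    ctrl_c = np.linspace(0, W - 1, lattice)
    disp = rng.uniform(-strength, strength, size=(2, lattice, lattice))
    rows, cols = np.arange(H), np.arange(W)
    k = min(3, lattice - 1)
    dr = RectBivariateSpline(ctrl_r, ctrl_c, disp[0], kx=k, ky=k)(rows, cols)
    dc = RectBivariateSpline(ctrl_r, ctrl_c, disp[1], kx=k, ky=k)(rows, cols)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    coords = np.stack([rr + dr, cc + dc])
    warped_sos = map_coordinates(sos_map.sos, coords, order=0, mode="nearest")
    warped_lab = map_coordinates(sos_map.labels, coords, order=0, mode="nearest")
    meta = dict(sos_map.meta)
    meta.update(distorted=True, distortion_seed=int(rng_seed),
                distortion_strength=float(strength))
    return SoSMap(warped_sos, warped_lab, sos_map.scheme, sos_map.pixel_size_mm, meta)


def make_dataset(variant: str, n: int, rng_seed: int,
                 config: DiscPhantomConfig = DiscPhantomConfig(),
                 distortion_strength: float = 4.0) -> list[SoSMap]:
    """Generate a disc-phantom dataset variant.

    ``original``: undistorted; ``distorted``: every sample warped;
    ``mixed``: each sample independently warped with probability 1/2.
    """
    if variant not in ("original", "distorted", "mixed"):
        raise ValueError(f"unknown variant {variant!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(rng_seed)
    seeds = master.integers(0, 2 ** 31 - 1, size=(n, 2))
    coin = master.uniform(size=n)
    out = []
    for i in range(n):
        m = make_disc_phantom(int(seeds[i, 0]), config)
        warp = variant == "distorted" or (variant == "mixed" and coin[i] < 0.5)
        if warp:
            m = apply_grid_distortion(m, int(seeds[i, 1]), distortion_strength)
        m.meta["variant"] = variant
        out.append(m)
    return out


# -- layered brain-like phantoms ------------------------------------------

#: per-tissue SoS ranges (m/s); cortical skull is the stiffest, intracranial
#: tissues (CSF / gray / white) have deliberately low mutual contrast.
DEFAULT_TISSUE_RANGES: dict[str, tuple[float, float]] = {
    "water":            (1500.0, 1500.0),
    "skin":             (1600.0, 1650.0),
    "fat":              (1430.0, 1470.0),
    "skull_cortical":   (2800.0, 2900.0),
    "skull_cancellous": (2200.0, 2400.0),
    "csf":              (1500.0, 1520.0),
    "gray_matter":      (1530.0, 1550.0),
    "white_matter":     (1550.0, 1570.0),
}

#: outer-to-inner anatomical order of the layered geometry
BRAIN_LAYER_ORDER = ("skin", "fat", "skull_cortical", "skull_cancellous",
                     "csf", "gray_matter", "white_matter")


@dataclass(frozen=True)
class BrainPhantomSpec:
    size: int = 153
    outer_radius: float = 70.0
    # fractional radial thickness of each shell, outer to inner (rest = white)
    thickness: tuple[float, ...] = (0.05, 0.05, 0.07, 0.06, 0.10, 0.22)
    tissue_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_RANGES))
    eccentricity: float = 0.85      # ellipse aspect (cols vs rows)
    wobble: float = 0.06            # relative radial boundary perturbation
    pixel_size_mm: float = 0.25

    def __post_init__(self):
        names = ("water",) + BRAIN_LAYER_ORDER
        missing = [n for n in names if n not in self.tissue_ranges]
        if missing:
            raise ValueError(f"missing tissue ranges: {missing}")
        for name, (lo, hi) in self.tissue_ranges.items():
            if lo > hi:
                raise ValueError(f"inverted SoS range for {name}")
        if len(self.thickness) != len(BRAIN_LAYER_ORDER) - 1:
            raise ValueError("one thickness per shell (innermost tissue fills the rest)")
        if sum(self.thickness) >= 1.0:
            raise ValueError("shell thicknesses must sum to < 1")


DEFAULT_BRAIN_SPEC = BrainPhantomSpec()

#: label assignment for the 8 brain classes (0 = water background)
BRAIN_LABELS = {name: i for i, name in enumerate(("water",) + BRAIN_LAYER_ORDER)}


def make_brain_phantom(rng_seed: int, spec: BrainPhantomSpec = DEFAULT_BRAIN_SPEC
                       ) -> SoSMap:
    """Nested deformed-ellipse head phantom with 8 tissue classes.

    The outer boundary and each internal interface are ellipses with a
    smooth random angular wobble; pixel-wise SoS is drawn uniformly from
    the tissue's range, so re-binning the continuous map by those ranges
    recovers the labels exactly.
    """
    rng = np.random.default_rng(rng_seed)
    size = spec.size
    center = (size / 2 - 0.5, size / 2 - 0.5)
    rr, cc = np.mgrid[0:size, 0:size]
    dr = (rr - center[0])
    dc = (cc - center[1]) / spec.eccentricity
    radius = np.sqrt(dr ** 2 + dc ** 2)
    theta = np.arctan2(dc, dr)

    # smooth angular wobble shared by all interfaces (low-order harmonics)
    n_harm = 4
    amp = rng.normal(0, spec.wobble / np.sqrt(n_harm), size=(2, n_harm))
    wob = np.zeros_like(theta)
    for h in range(n_harm):
        wob += amp[0, h] * np.cos((h + 2) * theta) + amp[1, h] * np.sin((h + 2) * theta)
    r_outer = spec.outer_radius * (1.0 + wob)

    labels = np.zeros((size, size), dtype=np.uint8)
    frac = np.concatenate([[0.0], np.cumsum(spec.thickness)])
    # shells outer->inner: each layer occupies [r_outer*(1-f_hi), r_outer*(1-f_lo))
    for i, name in enumerate(BRAIN_LAYER_ORDER[:-1]):
        hi = r_outer * (1.0 - frac[i])
        lo = r_outer * (1.0 - frac[i + 1])
        labels[(radius < hi) & (radius >= lo)] = BRAIN_LABELS[name]
    labels[radius < r_outer * (1.0 - frac[-1])] = BRAIN_LABELS["white_matter"]

    # carve gray-matter pockets and CSF ventricles into the white interior
    interior = labels == BRAIN_LABELS["white_matter"]
    for _ in range(3):
        c = (center[0] + rng.uniform(-0.25, 0.25) * spec.outer_radius,
             center[1] + rng.uniform(-0.25, 0.25) * spec.outer_radius)
        rad = rng.uniform(0.10, 0.22) * spec.outer_radius
        pocket = _disc_mask(size, c, rad) & interior
        labels[pocket] = BRAIN_LABELS["gray_matter"]
    for _ in range(2):
        c = (center[0] + rng.uniform(-0.15, 0.15) * spec.outer_radius,
             center[1] + rng.uniform(-0.15, 0.15) * spec.outer_radius)
        rad = rng.uniform(0.05, 0.10) * spec.outer_radius
        vent = _disc_mask(size, c, rad) & (labels >= BRAIN_LABELS["csf"])
        labels[vent] = BRAIN_LABELS["csf"]

    sos = np.empty((size, size), dtype=np.float32)
    for name, lab in BRAIN_LABELS.items():
        lo, hi = spec.tissue_ranges[name]
        mask = labels == lab
        sos[mask] = rng.uniform(lo, hi, size=int(mask.sum())).astype(np.float32)

    return SoSMap(sos, labels, DEFAULT_SCHEME, spec.pixel_size_mm,
                  meta={"kind": "brain", "seed": int(rng_seed),
                        "tissue_ranges": {k: tuple(v) for k, v in
                                          spec.tissue_ranges.items()}})
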