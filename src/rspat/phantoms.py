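"""Synthetic 2D digital phantoms for ring-array photoacoustic simulation.

Three generators mirror the study scenarios: a calibration phantom of
side-by-side tubes of purified probe at known concentrations (10 nM - 10 uM
scale), an abdominal cross-section with probe-bearing organs over a
hemoglobin vessel background, and a pregnant-abdomen phantom with several
probe-expressing embryos at 1-7 mm depth inside a maternal body.

Coordinate convention: the grid is square with its origin at the center,
x increasing rightward along columns and y increasing downward along rows;
all positions and sizes are in mm.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
from scipy import ndimage

from .errors import ConfigError, GeometryError

__all__ = [
    "Phantom",
    "make_tube_phantom",
    "make_crosssection_phantom",
    "make_embryo_phantom",
    "apply_motion",
]

#: Default grid: 256 x 256 pixels at 0.1 mm, a 25.6 mm field matching a
#: mouse trunk cross-section.
DEFAULT_SHAPE = (256, 256)
DEFAULT_PIXEL_MM = 0.1

#: Physiological vessel blood: 2.3 mM total heme-equivalent hemoglobin at
#: 80% oxygen saturation.
HB_TOTAL_M = 2.3e-3
HB_SO2 = 0.80


@dataclass
class Phantom:
    """Concentration maps, labeled region masks and grid metadata.

    ``maps`` holds per-species molar concentration images (keys from
    {"HbO2", "HbR", "BphP1"}); ``masks`` holds boolean region images.  The
    mask named ``background`` marks pixels outside the imaged object and is
    disjoint from all object masks.
    """

    pixel_size_mm: float
    maps: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return next(iter(self.maps.values())).shape

    def coords_mm(self):
        """(y, x) pixel-center coordinate grids in mm, origin at center."""
        n_y, n_x = self.shape
        y = (np.arange(n_y) - (n_y - 1) / 2.0) * self.pixel_size_mm
        x = (np.arange(n_x) - (n_x - 1) / 2.0) * self.pixel_size_mm
        return np.meshgrid(y, x, indexing="ij")

    def object_masks(self) -> dict:
        """All labeled masks except background/support helpers."""
        skip = {"background", "body"}
        return {k: v for k, v in self.masks.items() if k not in skip}

    def total_probe_mass(self) -> float:
        """Integral of the BphP1 map over area, in mol * mm^2 / L."""
        return float(self.maps["BphP1"].sum()) * self.pixel_size_mm ** 2

    def save_h5(self, path):
        with h5py.File(path, "w") as fh:
            fh.attrs["pixel_size_mm"] = self.pixel_size_mm
            if self.seed is not None:
                fh.attrs["seed"] = int(self.seed)
            for key, value in self.meta.items():
                fh.attrs[f"meta_{key}"] = value
            gm = fh.create_group("maps")
            for name, arr in self.maps.items():
                gm.create_dataset(name, data=arr.astype(np.float64))
            gk = fh.create_group("masks")
            for name, arr in self.masks.items():
                gk.create_dataset(name, data=arr.astype(np.uint8))

    @classmethod
    def load_h5(cls, path) -> "Phantom":
        with h5py.File(path, "r") as fh:
            maps = {k: fh["maps"][k][()] for k in fh["maps"]}
            masks = {k: fh["masks"][k][()].astype(bool) for k in fh["masks"]}
            meta = {k[5:]: fh.attrs[k] for k in fh.attrs if k.startswith("meta_")}
            seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
            return cls(pixel_size_mm=float(fh.attrs["pixel_size_mm"]),
                       maps=maps, masks=masks, seed=seed, meta=meta)

    def export_tiff(self, path, species: str = "BphP1"):
        tifffile.imwrite(path, self.maps[species].astype(np.float32))


def _grids(shape, pixel_size_mm):
    n_y, n_x = shape
    y = (np.arange(n_y) - (n_y - 1) / 2.0) * pixel_size_mm
    x = (np.arange(n_x) - (n_x - 1) / 2.0) * pixel_size_mm
    return np.meshgrid(y, x, indexing="ij")

def _disk(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2

def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

def _empty(shape):
    return np.zeros(shape, dtype=float)


def make_tube_phantom(concentrations,
                      tube_radius_mm: float = 3.0,
                      ring_radius_mm: float = 6.0,
                      shape=DEFAULT_SHAPE,
                      pixel_size_mm: float = DEFAULT_PIXEL_MM,
                      seed: int = 0) -> Phantom:
    """Calibration phantom: probe-filled tubes, zero hemoglobin.

    Disk-shaped tube cross-sections are placed side by side on a circle of
    radius ``ring_radius_mm`` (a single tube goes at the center).  Tube
    masks are labeled ``tube_0 .. tube_{n-1}`` in input order.
    """
    concentrations = [float(c) for c in concentrations]
    for c in concentrations:
        if not 0.0 < c <= 100e-6:
            raise ConfigError(f"tube concentration {c} M outside (0, 100 uM]")
    yy, xx = _grids(shape, pixel_size_mm)
    half_extent = min(shape) / 2.0 * pixel_size_mm
    n = len(concentrations)
    bphp1 = _empty(shape)
    masks = {}
    support = np.zeros(shape, dtype=bool)
    if n == 1:
        centers = [(0.0, 0.0)]
    else:
        angles = 2 * np.pi * np.arange(n) / max(n, 1)
        centers = [(ring_radius_mm * np.sin(a), ring_radius_mm * np.cos(a))
                   for a in angles]
    for k, (conc, (cy, cx)) in enumerate(zip(concentrations, centers)):
        if np.hypot(cy, cx) + tube_radius_mm > half_extent:
            raise GeometryError(f"tube_{k} does not fit within the grid")
        disk = _disk(yy, xx, cy, cx, tube_radius_mm)
        if (support & disk).any():
            raise GeometryError(
                f"tube_{k} overlaps a previous tube; reduce tube_radius_mm "
                f"or increase ring_radius_mm")
        support |= disk
        masks[f"tube_{k}"] = disk
        bphp1[disk] = conc
    # Background for noise estimation: away from every tube.
    margin_px = int(np.ceil(2.0 / pixel_size_mm))
    dilated = ndimage.binary_dilation(support, iterations=margin_px) if n else support
    masks["background"] = ~dilated
    return Phantom(pixel_size_mm=pixel_size_mm,
                   maps={"BphP1": bphp1, "HbO2": _empty(shape), "HbR": _empty(shape)},
                   masks=masks, seed=seed,
                   meta={"kind": "tubes", "n_tubes": n})


#: Organ layout for the cross-section phantom: (cy, cx, ry, rx) in mm.
#: Chosen disjoint inside a 10 x 8 mm semi-axis body ellipse.
_ORGAN_LAYOUT = {
    "liver": (-0.5, -4.2, 2.4, 3.2),
    "spleen": (-2.2, 4.8, 2.0, 1.3),
    "stomach": (-3.0, 1.2, 1.5, 1.9),
    "intestine": (3.4, 0.8, 1.9, 2.8),
}
_BODY_SEMI_AXES = (8.0, 10.0)   # (ry, rx) mm


def _place_vessels(rng, yy, xx, body, exclude, n_vessels, radius_range):
    """Random disk vessels inside the body avoiding ``exclude`` regions."""
    vessel = np.zeros(body.shape, dtype=bool)
    placed = 0
    for _ in range(200 * max(n_vessels, 1)):
        if placed >= n_vessels:
            break
        r = rng.uniform(*radius_range)
        cy = rng.uniform(yy.min(), yy.max())
        cx = rng.uniform(xx.min(), xx.max())
        disk = _disk(yy, xx, cy, cx, r)
        if not disk.any():
            continue
        if not body[disk].all():
            continue
        if (disk & exclude).any():
            continue
        vessel |= disk
        placed += 1
    if placed < n_vessels:
        raise GeometryError(f"placed only {placed}/{n_vessels} vessels")
    return vessel


def make_crosssection_phantom(organ_levels: dict,
                              n_vessels: int = 12,
                              vessel_radius_mm=(0.25, 0.5),
                              hb_total_m: float = HB_TOTAL_M,
                              hb_so2: float = HB_SO2,
                              tissue_hb_total_m: float = 0.0,
                              organ_hb_total_m: float = 0.0,
                              tissue_hb_so2: float = 0.7,
                              shape=DEFAULT_SHAPE,
                              pixel_size_mm: float = DEFAULT_PIXEL_MM,
                              seed: int = 0) -> Phantom:
    """Abdominal cross-section: organs carrying probe, vessels carrying blood.

    ``organ_levels`` maps organ names from {liver, spleen, stomach,
    intestine} to BphP1 concentrations in M (the in vivo scale is ~100 nM).
    Vessels are random disks inside the elliptical body outline, disjoint
    from the organ regions, carrying whole blood at ``hb_total_m`` total
    heme with oxygenation ``hb_so2`` and zero probe.  Soft tissue and organ
    parenchyma are perfused: they carry diffuse hemoglobin at
    ``tissue_hb_total_m`` / ``organ_hb_total_m`` heme-equivalent (capillary
    blood volume fractions of a few percent), co-located with the probe as
    in real organs; the in vivo hemoglobin content is not pinned down, so
    these are configuration values.
    """
    unknown = set(organ_levels) - set(_ORGAN_LAYOUT)
    if unknown:
        raise ConfigError(f"unknown organs: {sorted(unknown)}")
    for organ, level in organ_levels.items():
        if level < 0:
            raise ConfigError(f"organ level for {organ} must be >= 0")
    if n_vessels < 0:
        raise ConfigError("vessel count must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = _grids(shape, pixel_size_mm)
    body = _ellipse(yy, xx, 0.0, 0.0, *_BODY_SEMI_AXES)
    masks = {"body": body, "background": ~body}
    bphp1 = _empty(shape)
    organ_union = np.zeros(shape, dtype=bool)
    for organ, (cy, cx, ry, rx) in _ORGAN_LAYOUT.items():
        region = _ellipse(yy, xx, cy, cx, ry, rx) & body
        if (region & organ_union).any():
            raise GeometryError(f"organ layout overlap at {organ}")
        organ_union |= region
        masks[organ] = region
        bphp1[region] = float(organ_levels.get(organ, 0.0))
    hbo2, hbr = _empty(shape), _empty(shape)
    hbo2[body] = tissue_hb_total_m * tissue_hb_so2
    hbr[body] = tissue_hb_total_m * (1.0 - tissue_hb_so2)
    hbo2[organ_union] = organ_hb_total_m * tissue_hb_so2
    hbr[organ_union] = organ_hb_total_m * (1.0 - tissue_hb_so2)
    if n_vessels > 0:
        vessel = _place_vessels(rng, yy, xx, body, organ_union, n_vessels,
                                vessel_radius_mm)
        masks["vessel"] = vessel
        hbo2[vessel] = hb_total_m * hb_so2
        hbr[vessel] = hb_total_m * (1.0 - hb_so2)
    else:
        masks["vessel"] = np.zeros(shape, dtype=bool)
    return Phantom(pixel_size_mm=pixel_size_mm,
                   maps={"BphP1": bphp1, "HbO2": hbo2, "HbR": hbr},
                   masks=masks, seed=seed,
                   meta={"kind": "crosssection", "n_vessels": n_vessels})


def make_embryo_phantom(n_embryos: int = 7,
                        depth_range_mm=(1.0, 7.0),
                        embryo_radius_mm=(1.0, 2.0),
                        embryo_bphp1_m: float = 5e-7,
                        n_vessels: int = 10,
                        hb_total_m: float = HB_TOTAL_M,
                        hb_so2: float = HB_SO2,
                        tissue_hb_total_m: float = 0.0,
                        embryo_hb_total_m: float = 0.0,
                        tissue_hb_so2: float = 0.7,
                        shape=DEFAULT_SHAPE,
                        pixel_size_mm: float = DEFAULT_PIXEL_MM,
                        seed: int = 0,
                        max_tries: int = 500) -> Phantom:
    """Pregnant-abdomen phantom: probe-bearing embryos in a maternal body.

    Embryos are disks at depths (distance from the body outline toward the
    interior) sampled within ``depth_range_mm``; only the embryos carry
    BphP1, while maternal vessels carry hemoglobin.  Placement uses bounded
    rejection sampling and raises :class:`GeometryError` on failure.
    """
    if n_embryos < 0:
        raise ConfigError("n_embryos must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = _grids(shape, pixel_size_mm)
    body = _ellipse(yy, xx, 0.0, 0.0, 9.0, 11.0)
    # Depth of every interior pixel = distance to the body boundary, in mm.
    depth = ndimage.distance_transform_edt(body) * pixel_size_mm
    masks = {"body": body, "background": ~body}
    bphp1 = _empty(shape)
    embryo_union = np.zeros(shape, dtype=bool)
    lo, hi = depth_range_mm
    for k in range(n_embryos):
        for _ in range(max_tries):
            r = rng.uniform(*embryo_radius_mm)
            cy = rng.uniform(yy.min(), yy.max())
            cx = rng.uniform(xx.min(), xx.max())
            iy = int(round((cy - yy[0, 0]) / pixel_size_mm))
            ix = int(round((cx - xx[0, 0]) / pixel_size_mm))
            if not (0 <= iy < shape[0] and 0 <= ix < shape[1]):
                continue
            if not body[iy, ix] or not lo <= depth[iy, ix] <= hi:
                continue
            disk = _disk(yy, xx, cy, cx, r)
            if not body[disk].all():
                continue
            if (disk & embryo_union).any():
                continue
            embryo_union |= disk
            masks[f"embryo_{k}"] = disk
            bphp1[disk] = embryo_bphp1_m
            break
        else:
            raise GeometryError(
                f"could not place embryo {k} after {max_tries} tries")
    hbo2, hbr = _empty(shape), _empty(shape)
    hbo2[body] = tissue_hb_total_m * tissue_hb_so2
    hbr[body] = tissue_hb_total_m * (1.0 - tissue_hb_so2)
    hbo2[embryo_union] = embryo_hb_total_m * tissue_hb_so2
    hbr[embryo_union] = embryo_hb_total_m * (1.0 - tissue_hb_so2)
    if n_vessels > 0:
        vessel = _place_vessels(rng, yy, xx, body, embryo_union, n_vessels,
                                (0.25, 0.5))
        masks["vessel"] = vessel
        hbo2[vessel] = hb_total_m * hb_so2
        hbr[vessel] = hb_total_m * (1.0 - hb_so2)
    else:
        masks["vessel"] = np.zeros(shape, dtype=bool)
    return Phantom(pixel_size_mm=pixel_size_mm,
                   maps={"BphP1": bphp1, "HbO2": hbo2, "HbR": hbr},
                   masks=masks, seed=seed,
                   meta={"kind": "embryo", "n_embryos": n_embryos})


def apply_motion(phantom: Phantom, amplitude_mm: float, period_s: float,
                 t_s: float, axis: int = 0) -> Phantom:
    """Rigid sinusoidal translation emulating breathing motion.

    All maps and masks shift by ``amplitude * sin(2 pi t / period)`` mm
    along ``axis`` (0 = vertical).  Maps use bilinear interpolation, masks
    nearest-neighbour, both zero-filled at the edges.  Zero amplitude is the
    identity.
    """
    if amplitude_mm < 0:
        raise ConfigError("motion amplitude must be >= 0")
    displacement = amplitude_mm * np.sin(2.0 * np.pi * t_s / period_s)
    if displacement == 0.0:
        return Phantom(pixel_size_mm=phantom.pixel_size_mm,
                       maps={k: v.copy() for k, v in phantom.maps.items()},
                       masks={k: v.copy() for k, v in phantom.masks.items()},
                       seed=phantom.seed, meta=dict(phantom.meta))
    shift_px = displacement / phantom.pixel_size_mm
    vec = [0.0, 0.0]
    vec[axis] = shift_px
    maps = {k: ndimage.shift(v, vec, order=1, mode="constant", cval=0.0)
            for k, v in phantom.maps.items()}
    masks = {}
    for k, v in phantom.masks.items():
        cval = bool(k == "background")
        shifted = ndimage.shift(v.astype(float), vec, order=0, mode="constant",
                                cval=float(cval))
        masks[k] = shifted > 0.5
    meta = dict(phantom.meta)
    meta["motion_displacement_mm"] = float(displacement)
    return Phantom(pixel_size_mm=phantom.pixel_size_mm, maps=maps,
                   masks=masks, seed=phantom.seed, meta=meta)
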