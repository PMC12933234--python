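"""Synthetic CT phantom generator (LUNA16-shaped, desk scale).

Generates volumes that mimic the *structure* of thoracic CT for pipeline
testing: an elliptical body at soft-tissue density over an air background,
two low-density lung fields, bright tubular vessels and bright spherical
nodules inside the lungs, plus Gaussian HU noise.  Annotations are emitted
in world millimetres (seriesuid / coordX / coordY / coordZ / diameter_mm),
exactly the dialect the preprocessing module consumes.

The default densities (air -1000 HU, lung -800, body +40, nodules/vessels
in the -100..+100 band, noise sd 20) are chosen so the standard -320 HU
lung/air binarization threshold is exercised realistically.  ``difficulty``
presets provide the hard cases of interest for tiny-object detection:
3-5 px nodules and near-wall placement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lung_prep import CTVolume, LungMask, NoduleAnnotation, write_mhd

__all__ = [
    "PhantomSpec", "GenerationError", "generate_phantom", "generate_dataset",
    "easy_spec", "tiny_nodule_spec",
]


class GenerationError(RuntimeError):
    """Raised when nodule placement fails after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom volume; ``seed`` fixes all randomness."""

    dims: tuple[int, int, int] = (32, 128, 128)          # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (sz, sy, sx) mm
    n_nodules: int = 3
    diameter_range: tuple[float, float] = (8.0, 16.0)    # mm
    nodule_hu: float = 30.0
    lung_hu: float = -800.0
    body_hu: float = 40.0
    air_hu: float = -1000.0
    vessel_hu: float = 60.0
    vessel_count: int = 3
    vessel_radius: tuple[float, float] = (1.0, 2.0)      # voxels (in-plane)
    noise_sd: float = 20.0
    wall_margin: float = 0.25   # min. distance of nodule centers from the
                                # lung surface, as a fraction of lung radius
    seed: int = 0

    def __post_init__(self):
        if min(self.spacing) <= 0 or min(self.dims) < 1:
            raise ValueError("dims must be >= 1 and spacing positive")
        max_d_vox = self.diameter_range[1] / min(self.spacing[1:])
        if max_d_vox > 0.3 * min(self.dims[1:]):
            raise ValueError("nodule diameters do not fit inside the lung fields")


def easy_spec(**overrides) -> PhantomSpec:
    """Large, well-separated nodules and sparse thin vessels."""
    return replace(PhantomSpec(n_nodules=2, diameter_range=(10.0, 16.0),
                               vessel_count=2, vessel_radius=(1.0, 1.5)),
                   **overrides)


def tiny_nodule_spec(**overrides) -> PhantomSpec:
    """3-5 px nodules, nearer the lung wall: the hard tiny-object case."""
    return replace(PhantomSpec(n_nodules=3, diameter_range=(3.0, 5.0),
                               vessel_count=3, wall_margin=0.10),
                   **overrides)


def _lung_geometry(dims):
    """Centers and semi-axes (voxels, (z, y, x)) of the two lung ellipsoids."""
    nz, ny, nx = dims
    semi = np.array([0.46 * nz, 0.30 * ny, 0.17 * nx])
    left = np.array([nz / 2, ny / 2, nx / 2 - 0.21 * nx])
    right = np.array([nz / 2, ny / 2, nx / 2 + 0.21 * nx])
    return [(left, semi), (right, semi)]


def _ellipsoid_mask(dims, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: dims[0], : dims[1], : dims[2]]
    q = ((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 \
        + ((xx - center[2]) / semi[2]) ** 2
    return q <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns ``(CTVolume, annotations, lung_mask)`` where ``lung_mask`` is the
    ground-truth union of the two lung ellipsoids.  Identical specs produce
    voxelwise-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.dims
    vox = np.full(spec.dims, spec.air_hu, np.float32)

    body = _ellipsoid_mask(spec.dims, (nz / 2, ny / 2, nx / 2),
                           (0.7 * nz, 0.42 * ny, 0.46 * nx))
    vox[body] = spec.body_hu

    lungs = _lung_geometry(spec.dims)
    lung_mask = np.zeros(spec.dims, bool)
    for c, s in lungs:
        lung_mask |= _ellipsoid_mask(spec.dims, c, s)
    vox[lung_mask] = spec.lung_hu

    # vessels: per-lung polylines, mostly axial, rasterized as in-plane disks
    yy, xx = np.mgrid[:ny, :nx]
    for _ in range(spec.vessel_count):
        c, s = lungs[rng.integers(len(lungs))]
        y0 = c[1] + rng.uniform(-0.4, 0.4) * s[1]
        x0 = c[2] + rng.uniform(-0.4, 0.4) * s[2]
        drift = rng.uniform(-0.6, 0.6, size=2)
        r = rng.uniform(*spec.vessel_radius)
        z_lo = int(c[0] - 0.8 * s[0])
        z_hi = int(c[0] + 0.8 * s[0])
        for z in range(max(z_lo, 0), min(z_hi, nz)):
            t = z - z_lo
            cy, cx = y0 + drift[0] * t, x0 + drift[1] * t
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            sl = vox[z]
            sl[disk & lung_mask[z]] = spec.vessel_hu

    # nodules: spheres in world mm, fully interior to a lung ellipsoid
    spacing = np.asarray(spec.spacing)
    origin = np.array([-nz * spacing[0] / 2, -ny * spacing[1] / 2,
                       -nx * spacing[2] / 2])
    series_id = f"synthetic.{spec.seed}"
    annotations: list[NoduleAnnotation] = []
    zzv, yyv, xxv = np.ogrid[:nz, :ny, :nx]
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_nodules):
        ok = False
        for _attempt in range(200):
            d_mm = rng.uniform(*spec.diameter_range)
            c, s = lungs[rng.integers(len(lungs))]
            # sample inside the ellipsoid, away from the wall
            u = rng.uniform(-1, 1, size=3)
            if (u ** 2).sum() > 1:
                continue
            r_vox = d_mm / 2 / spacing  # per-axis radius in voxels
            shrink = 1.0 - spec.wall_margin - r_vox / s
            if np.any(shrink <= 0):
                continue
            center = c + u * s * shrink
            if any(np.linalg.norm((center - p) * spacing) < (d_mm + pd_) / 2 + 2
                   for p, pd_ in placed):
                continue
            q = ((zzv - center[0]) / r_vox[0]) ** 2 \
                + ((yyv - center[1]) / r_vox[1]) ** 2 \
                + ((xxv - center[2]) / r_vox[2]) ** 2
            vox[q <= 1.0] = spec.nodule_hu
            world = origin + center * spacing  # (z, y, x) mm
            annotations.append(NoduleAnnotation(
                series_id=series_id, world_x=float(world[2]),
                world_y=float(world[1]), world_z=float(world[0]),
                diameter=float(d_mm)))
            placed.append((center, d_mm))
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place nodule {len(placed) + 1} after 200 attempts")

    if spec.noise_sd > 0:
        vox += rng.normal(0.0, spec.noise_sd, size=vox.shape).astype(np.float32)

    vol = CTVolume(voxels=vox, spacing=tuple(spacing), origin=tuple(origin),
                   series_id=series_id)
    return vol, annotations, LungMask(lung_mask.astype(np.uint8))


def generate_dataset(n_volumes: int, spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write ``n_volumes`` phantoms (.mhd/.raw) plus one annotations.csv.

    Per-volume seeds are spawned from ``spec.seed``; the returned DataFrame
    is the annotation table in LUNA16 dialect.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(spec.seed).spawn(n_volumes)
    rows = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        sub = replace(spec, seed=sub_seed)
        vol, anns, _mask = generate_phantom(sub)
        sid = f"synthetic.{spec.seed}.{i:04d}"
        vol = CTVolume(vol.voxels, vol.spacing, vol.origin, series_id=sid)
        write_mhd(vol, out_dir / f"{sid}.mhd")
        for a in anns:
            rows.append({"seriesuid": sid, "coordX": a.world_x,
                         "coordY": a.world_y, "coordZ": a.world_z,
                         "diameter_mm": a.diameter})
    df = pd.DataFrame(rows, columns=["seriesuid", "coordX", "coordY",
                                     "coordZ", "diameter_mm"])
    df.to_csv(out_dir / "annotations.csv", index=False)
    return df
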