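"""Synthetic whole-testis image volumes with planted germ-cell nests.

Germ cells are modelled as solid spheres (~20 µm diameter) sitting on
seminiferous-tubule paths, grouped into nests whose members are chained at
surface gaps below the nest-calling cutoff while distinct groups are kept
apart by a much larger gap.  Two channels are rendered on an anisotropic
voxel grid (1 µm in-plane, 5 µm optical sections by default): an eGFP
reporter channel with Bright/Mid intensity classes plus interstitial
autofluorescent blobs, and a tdTomato lineage-label channel carrying every
germ cell but no blobs.  No point-spread function is applied — nest calling
consumes centroids, volumes and mean intensities, not texture.

Tubule paths run along x at a constant (y, z), so all cells of a nest share
one optical depth; partial-depth imaging (``imaged_depth_fraction``) then
includes or excludes whole nests rather than slicing through them, matching
how nests sit along tubules at a common depth in a cleared testis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..volumes import ImageVolume

__all__ = [
    "VolumeSimConfig",
    "VolumeSimResult",
    "PlacementError",
    "simulate_testis_volume",
    "default_class_boundaries",
    "truth_gap_stats",
]


class PlacementError(RuntimeError):
    """Raised when the requested geometry cannot be placed under the
    separation constraints within the retry budget."""


@dataclass
class VolumeSimConfig:
    """Geometry, intensity and acquisition settings for one simulated testis.

    Distances are µm.  ``intensity_params`` maps each eGFP class to
    ``(log-median, log-sd)`` of a log-normal intensity distribution;
    ``intra_nest_gap_um`` is the maximum surface-to-surface gap between
    chained nest neighbours and must stay below ``inter_nest_min_gap_um``,
    the minimum gap separating distinct groups, for the configuration to be
    well separated with respect to a cutoff between the two.
    """

    volume_shape_um: tuple[float, float, float] = (400.0, 400.0, 200.0)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 5.0)
    n_tubules: int = 10
    tubule_radius_um: float = 20.0
    n_nests_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"Bright": 8, "Mid": 3}
    )
    nest_size_distribution: int | Mapping[int, float] = field(
        default_factory=lambda: {3: 0.3, 4: 0.3, 5: 0.2, 6: 0.2}
    )
    intra_nest_gap_um: float = 8.0
    intra_nest_gap_min_um: float = 3.0
    inter_nest_min_gap_um: float = 35.0
    n_singletons: int = 6
    cell_diameter_um: tuple[float, float] = (20.0, 1.0)  # mean, sd
    intensity_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Bright": (np.log(250.0), 0.15),
            "Mid": (np.log(80.0), 0.15),
        }
    )
    tdtomato_level: float = 150.0
    n_autofluor_blobs: int = 5
    autofluor_intensity: tuple[float, float] = (np.log(150.0), 0.3)
    autofluor_radius_um: tuple[float, float] = (5.0, 12.0)
    noise_sd: float = 2.0
    imaged_depth_fraction: float = 1.0
    placement_retry_cap: int = 10_000

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.volume_shape_um):
            raise ValueError("volume extents must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0 < self.imaged_depth_fraction <= 1:
            raise ValueError("imaged_depth_fraction must lie in (0, 1]")
        if not self.intra_nest_gap_min_um <= self.intra_nest_gap_um:
            raise ValueError("intra-nest gap range inverted")
        if not self.intra_nest_gap_um < self.inter_nest_min_gap_um:
            raise ValueError(
                "well-separated configuration requires "
                "intra_nest_gap_um < inter_nest_min_gap_um"
            )
        if isinstance(self.nest_size_distribution, Mapping):
            if any(k < 3 for k in self.nest_size_distribution):
                raise ValueError("nest sizes must be >= 3")
        elif self.nest_size_distribution < 3:
            raise ValueError("nest sizes must be >= 3")
        if self.cell_diameter_um[0] <= 0:
            raise ValueError("cell diameter must be positive")


@dataclass
class VolumeSimResult:
    egfp: ImageVolume
    tdtomato: ImageVolume
    truth: pd.DataFrame  # one row per planted cell or blob


def mean_d_for_spacing(config: VolumeSimConfig) -> float:
    return config.cell_diameter_um[0]


def _sample_nest_size(config: VolumeSimConfig, rng: np.random.Generator) -> int:
    d = config.nest_size_distribution
    if isinstance(d, Mapping):
        sizes = sorted(d)
        probs = np.array([d[s] for s in sizes], dtype=float)
        return int(rng.choice(sizes, p=probs / probs.sum()))
    return int(d)


def _border_dist(p: np.ndarray, r: float, q: np.ndarray, rq: np.ndarray) -> np.ndarray:
    return np.linalg.norm(q - p, axis=-1) - r - rq


def _place_groups(config: VolumeSimConfig, rng: np.random.Generator):
    """Place nests and singletons on tubule paths by rejection sampling."""
    X, Y, Z = config.volume_shape_um
    margin = config.cell_diameter_um[0] / 2 + 3 * config.cell_diameter_um[1] + 1
    if Y <= 2 * margin or Z <= 2 * margin or X <= 2 * margin:
        raise PlacementError("volume too small for the configured cell size")
    # Tubule paths run along x at a constant (y, z).  Spacing them at least
    # one inter-group gap plus two cell diameters apart (best effort) makes
    # cross-tubule placements nearly always admissible.
    tubule_min_dist = config.inter_nest_min_gap_um + 2 * mean_d_for_spacing(config)
    placed_t: list[np.ndarray] = []
    for _ in range(config.n_tubules):
        cand = None
        for _ in range(200):
            cand = np.array([rng.uniform(margin, Y - margin),
                             rng.uniform(margin, Z - margin)])
            if not placed_t or min(
                np.linalg.norm(cand - t) for t in placed_t
            ) >= tubule_min_dist:
                break
        placed_t.append(cand)
    tubules = np.vstack(placed_t)  # (y, z) per tubule

    # Group plan: nests per class (sizes drawn up front), then singletons.
    plan: list[tuple[str, int]] = []
    for cls in sorted(config.n_nests_per_class):
        for _ in range(config.n_nests_per_class[cls]):
            plan.append((cls, _sample_nest_size(config, rng)))
    classes = sorted(config.n_nests_per_class) or ["Bright", "Mid"]
    for _ in range(config.n_singletons):
        plan.append((str(rng.choice(classes)), 1))

    placed_xyz: list[np.ndarray] = []
    placed_r: list[float] = []
    rows: list[dict] = []
    nest_id = 0
    mean_d, sd_d = config.cell_diameter_um
    for cls, size in plan:
        ok = False
        for _ in range(config.placement_retry_cap):
            t = rng.integers(config.n_tubules)
            y, z = tubules[t]
            # Diameters are truncated at +-2 sd: germ cells are uniformly
            # sized, and an unbounded tail would let a single large cell
            # read as a doublet under equivalent-sphere cell counting.
            radii = np.clip(rng.normal(mean_d, sd_d, size),
                            mean_d - 2 * sd_d, mean_d + 2 * sd_d) / 2.0
            gaps = rng.uniform(config.intra_nest_gap_min_um, config.intra_nest_gap_um,
                               max(size - 1, 0))
            xs = np.empty(size)
            xs[0] = rng.uniform(margin, X - margin)
            for i in range(1, size):
                xs[i] = xs[i - 1] + radii[i - 1] + gaps[i - 1] + radii[i]
            if xs[-1] + radii[-1] > X - 1:
                continue
            centers = np.column_stack([xs, np.full(size, y), np.full(size, z)])
            if placed_xyz:
                prev = np.vstack(placed_xyz)
                prev_r = np.asarray(placed_r)
                gap_ok = True
                for c, r in zip(centers, radii):
                    if _border_dist(c, r, prev, prev_r).min() < config.inter_nest_min_gap_um:
                        gap_ok = False
                        break
                if not gap_ok:
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place a {cls} group of {size} cells with "
                f"inter_nest_min_gap_um={config.inter_nest_min_gap_um} "
                f"within {config.placement_retry_cap} retries"
            )
        this_nest = nest_id if size >= 3 else -1
        if size >= 3:
            nest_id += 1
        for c, r in zip(centers, radii):
            placed_xyz.append(c)
            placed_r.append(float(r))
            rows.append(
                dict(kind="cell", class_label=cls, nest_id=this_nest,
                     x_um=float(c[0]), y_um=float(c[1]), z_um=float(c[2]),
                     radius_um=float(r))
            )
    return rows, tubules


def _place_blobs(config: VolumeSimConfig, rng: np.random.Generator,
                 tubules: np.ndarray, cells: list[dict]) -> list[dict]:
    X, Y, Z = config.volume_shape_um
    rows: list[dict] = []
    if config.n_autofluor_blobs == 0:
        return rows
    cell_xyz = np.array([[c["x_um"], c["y_um"], c["z_um"]] for c in cells]) if cells else None
    cell_r = np.array([c["radius_um"] for c in cells]) if cells else None
    placed: list[np.ndarray] = []
    placed_r: list[float] = []
    for _ in range(config.n_autofluor_blobs):
        ok = False
        for _ in range(config.placement_retry_cap):
            r = rng.uniform(*config.autofluor_radius_um)
            p = np.array([rng.uniform(r + 1, X - r - 1),
                          rng.uniform(r + 1, Y - r - 1),
                          rng.uniform(r + 1, Z - r - 1)])
            # Interstitial: outside every tubule (distance in the y-z plane).
            d_tub = np.linalg.norm(tubules - p[1:], axis=1)
            if (d_tub < config.tubule_radius_um + r).any():
                continue
            if cell_xyz is not None and len(cell_xyz):
                if _border_dist(p, r, cell_xyz, cell_r).min() < config.inter_nest_min_gap_um:
                    continue
            if placed:
                prev, prev_r = np.vstack(placed), np.asarray(placed_r)
                if _border_dist(p, r, prev, prev_r).min() < 5.0:
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                "could not place an interstitial blob outside tubules within "
                f"{config.placement_retry_cap} retries"
            )
        placed.append(p)
        placed_r.append(float(r))
        rows.append(dict(kind="autofluor", class_label="autofluor", nest_id=-1,
                         x_um=float(p[0]), y_um=float(p[1]), z_um=float(p[2]),
                         radius_um=float(r)))
    return rows


def _render_sphere(grid: np.ndarray, voxel: tuple[float, float, float],
                   center: tuple[float, float, float], radius: float,
                   value: float) -> None:
    """Max-composite a solid sphere onto a (z, y, x) grid.

    Voxel centres sit at ``(i + 0.5) * voxel_size``; a voxel belongs to the
    sphere when its centre lies within the radius.
    """
    dx, dy, dz = voxel
    cx, cy, cz = center
    nz, ny, nx = grid.shape
    x0 = max(int(np.floor((cx - radius) / dx - 0.5)), 0)
    x1 = min(int(np.ceil((cx + radius) / dx - 0.5)) + 1, nx)
    y0 = max(int(np.floor((cy - radius) / dy - 0.5)), 0)
    y1 = min(int(np.ceil((cy + radius) / dy - 0.5)) + 1, ny)
    z0 = max(int(np.floor((cz - radius) / dz - 0.5)), 0)
    z1 = min(int(np.ceil((cz + radius) / dz - 0.5)) + 1, nz)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) + 0.5) * dx - cx
    ys = (np.arange(y0, y1) + 0.5) * dy - cy
    zs = (np.arange(z0, z1) + 0.5) * dz - cz
    mask = (zs[:, None, None] ** 2 + ys[None, :, None] ** 2
            + xs[None, None, :] ** 2) <= radius**2
    sub = grid[z0:z1, y0:y1, x0:x1]
    np.maximum(sub, np.where(mask, value, 0.0), out=sub)


def simulate_testis_volume(
    config: VolumeSimConfig, seed: int
) -> VolumeSimResult:
    """Render one seeded two-channel testis volume plus its ground truth.

    Returns the eGFP and tdTomato :class:`~nestkin.volumes.ImageVolume`
    (cropped to the imaged depth) and a truth table with one row per planted
    cell or blob: position, radius, class, nest id (-1 for singletons and
    blobs), eGFP intensity and whether the object lies within the imaged
    depth.  Identical config and seed reproduce the output bit for bit.
    """
    rng = np.random.default_rng(seed)
    cell_rows, tubules = _place_groups(config, rng)
    blob_rows = _place_blobs(config, rng, tubules, cell_rows)

    for row in cell_rows:
        mu, sd = config.intensity_params[row["class_label"]]
        row["egfp_intensity"] = float(rng.lognormal(mu, sd))
    for row in blob_rows:
        row["egfp_intensity"] = float(rng.lognormal(*config.autofluor_intensity))

    X, Y, Z = config.volume_shape_um
    dx, dy, dz = config.voxel_size_um
    shape = (int(round(Z / dz)), int(round(Y / dy)), int(round(X / dx)))
    egfp = np.zeros(shape, dtype=np.float32)
    tdt = np.zeros(shape, dtype=np.float32)
    for row in cell_rows:
        c = (row["x_um"], row["y_um"], row["z_um"])
        _render_sphere(egfp, config.voxel_size_um, c, row["radius_um"],
                       row["egfp_intensity"])
        _render_sphere(tdt, config.voxel_size_um, c, row["radius_um"],
                       config.tdtomato_level)
    for row in blob_rows:
        c = (row["x_um"], row["y_um"], row["z_um"])
        _render_sphere(egfp, config.voxel_size_um, c, row["radius_um"],
                       row["egfp_intensity"])
    if config.noise_sd > 0:
        egfp += rng.normal(0.0, config.noise_sd, shape).astype(np.float32)
        tdt += rng.normal(0.0, config.noise_sd, shape).astype(np.float32)
        np.clip(egfp, 0.0, None, out=egfp)
        np.clip(tdt, 0.0, None, out=tdt)

    truth = pd.DataFrame(cell_rows + blob_rows)
    truth.insert(0, "cell_id", np.arange(len(truth)))
    z_max = config.imaged_depth_fraction * Z
    truth["in_imaged_depth"] = truth["z_um"] < z_max

    egfp_vol = ImageVolume(egfp, config.voxel_size_um, "eGFP")
    tdt_vol = ImageVolume(tdt, config.voxel_size_um, "tdTomato")
    if config.imaged_depth_fraction < 1.0:
        egfp_vol = egfp_vol.crop_z(z_max)
        tdt_vol = tdt_vol.crop_z(z_max)
    return VolumeSimResult(egfp=egfp_vol, tdtomato=tdt_vol, truth=truth)


def default_class_boundaries(config: VolumeSimConfig) -> tuple[float, float]:
    """Intensity boundaries (below/Mid, Mid/Bright) implied by the config's
    class intensity distributions: the lower boundary sits well below the
    Mid median (above background), the upper at the geometric midpoint of
    the Mid and Bright medians."""
    med = {cls: float(np.exp(mu)) for cls, (mu, _) in config.intensity_params.items()}
    b2 = float(np.sqrt(med["Mid"] * med["Bright"])) if {"Mid", "Bright"} <= med.keys() else max(med.values())
    b1 = min(med.values()) / 2.5
    return (b1, b2)


def truth_gap_stats(truth: pd.DataFrame) -> tuple[float, float]:
    """(max intra-nest nearest-neighbour surface gap, min inter-group
    surface gap) over planted cells — the quantities that make a planted
    configuration well separated with respect to a clustering cutoff."""
    cells = truth[truth["kind"] == "cell"]
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy()
    radii = cells["radius_um"].to_numpy()
    nest = cells["nest_id"].to_numpy()
    # Treat each singleton as its own group.
    group = np.where(nest >= 0, nest, -1 - np.arange(len(nest)))
    diff = xyz[:, None, :] - xyz[None, :, :]
    border = np.sqrt((diff**2).sum(-1)) - radii[:, None] - radii[None, :]
    same = group[:, None] == group[None, :]
    eye = np.eye(len(xyz), dtype=bool)
    max_intra = 0.0
    for g in np.unique(group[group >= 0]):
        m = group == g
        sub = border[np.ix_(m, m)].copy()
        np.fill_diagonal(sub, np.inf)
        # Chain criterion: each member's nearest same-nest neighbour.
        max_intra = max(max_intra, float(sub.min(axis=1).max()))
    inter = border[~same & ~eye]
    min_inter = float(inter.min()) if inter.size else np.inf
    return max_intra, min_inter
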