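"""3D cell placement for the cerebellar scaffold.

Most populations are placed with a bounded self-avoiding random walk: each
layer is split into thin sublayers (height = 1.5 x soma diameter), cells are
laid out in 2D within a sublayer — each new soma one soma-diameter plus a
density-derived scatter term away from the previous one, along a random
direction — and a vertical coordinate is then drawn uniformly inside the
sublayer.  Purkinje cells are placed on a jittered planar grid whose pitch
keeps their flat parasagittal dendritic slabs from overlapping; deep-nuclei
cells are few and placed by rejection sampling.

Somata never overlap within a population, in full 3D: the vertical draw is
rejected against already-placed cells of the same population (cross-type
overlap is deliberately not prevented).  Placement quality is validated by
kernel density estimation (KDE) of pair-wise inter-soma distances: a
homogeneous population yields a single KDE maximum, the Purkinje grid yields
several.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .config import ScaffoldConfig, ConfigError, NEURON_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "PlacementTable",
    "Sublayer",
    "KdeResult",
    "compute_epsilon",
    "plan_sublayers",
    "random_walk_place_2d",
    "assign_vertical",
    "place_purkinje",
    "sample_aa_heights",
    "place_population",
    "place_all",
    "kde_pairwise_distances",
    "pairwise_distance_sample",
]

# placement-order of populations; cell ids are contiguous in this order
PLACEMENT_ORDER = ("GoC", "Glom", "GrC", "PC", "BC", "SC", "DCNC")

# retry policy of the walk: candidate re-draws around the current anchor
# before restarting from a fresh point, and free-region draws per restart
# before the sublayer is declared saturated
CANDIDATE_TRIES = 50
RESTART_TRIES = 400


@dataclass
class Sublayer:
    """One horizontal slice of a layer; height = 1.5 x soma diameter."""
    y_lo: float
    y_hi: float

    @property
    def height(self) -> float:
        return self.y_hi - self.y_lo


@dataclass
class KdeResult:
    """Gaussian KDE of a pair-wise distance distribution."""
    grid: np.ndarray          # evaluation points, um
    density: np.ndarray       # estimated density, integrates to ~1
    maxima: np.ndarray        # positions of local maxima, um (descending density)
    bandwidth: float          # Gaussian kernel sd, um


@dataclass
class PlacementTable:
    """Soma positions of all placed cells.

    ``cell_id`` is globally unique and contiguous; ``type_code`` follows the
    configuration's 1-7 coding; ``aa_height`` holds, for every granule cell,
    the length of its ascending axon (which is also the height at which its
    parallel fiber runs).
    """

    cell_id: np.ndarray       # (N,) int64
    type_code: np.ndarray     # (N,) int64
    xyz: np.ndarray           # (N, 3) float64, um
    aa_height: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    # (n_GrC, 2): [grc_id, height um]
    type_names: dict = field(default_factory=dict)   # name -> type_code
    seed: int = 0

    def __len__(self) -> int:
        return len(self.cell_id)

    def code_of(self, name: str) -> int:
        return self.type_names[name]

    def ids_of(self, name: str) -> np.ndarray:
        return self.cell_id[self.type_code == self.code_of(name)]

    def positions_of(self, name: str) -> np.ndarray:
        return self.xyz[self.type_code == self.code_of(name)]

    def counts(self) -> dict:
        return {name: int(np.sum(self.type_code == code))
                for name, code in self.type_names.items()}

    def aa_height_by_id(self) -> dict:
        return {int(i): float(h) for i, h in self.aa_height}


def compute_epsilon(density: float, soma_radius: float) -> float:
    """Scatter term of the walk: difference between the radius of the
    per-cell "compound sphere" implied by the density and the soma radius.

    epsilon = (3 / (4 pi density))^(1/3) - soma_radius
    """
    if density <= 0:
        raise ConfigError("density must be > 0 to compute epsilon")
    eps = (3.0 / (4.0 * math.pi * density)) ** (1.0 / 3.0) - soma_radius
    if eps <= 0:
        raise ConfigError(
            f"density {density} too high for soma radius {soma_radius} "
            f"(epsilon = {eps:.3g} <= 0)")
    return eps


def plan_sublayers(layer_height: float, soma_radius: float) -> list[Sublayer]:
    """Split a layer bottom-up into full sublayers of height 3 x radius
    (= 1.5 x soma diameter); a trailing sliver shorter than one sublayer is
    left unused."""
    h = 3.0 * soma_radius
    n = int(layer_height // h)
    return [Sublayer(k * h, (k + 1) * h) for k in range(n)]


def _sample_step(rng: np.random.Generator, eps: float) -> float:
    """Scatter distance: normal centered on epsilon, truncated to
    [0.75 eps, 1.25 eps] (sd eps/8 puts the bounds at 2 sd)."""
    lo, hi = 0.75 * eps, 1.25 * eps
    for _ in range(16):
        s = rng.normal(eps, eps / 8.0)
        if lo <= s <= hi:
            return s
    return float(np.clip(s, lo, hi))


class _Grid2D:
    """Uniform-grid spatial hash for O(1) neighbourhood overlap queries."""

    def __init__(self, cell: float):
        self.cell = cell
        self.buckets: dict[tuple[int, int], list[int]] = {}
        self.pts: list[tuple[float, float]] = []

    def _key(self, x: float, z: float) -> tuple[int, int]:
        return (int(math.floor(x / self.cell)), int(math.floor(z / self.cell)))

    def add(self, x: float, z: float) -> None:
        idx = len(self.pts)
        self.pts.append((x, z))
        self.buckets.setdefault(self._key(x, z), []).append(idx)

    def neighbors_within(self, x: float, z: float, r: float) -> list[int]:
        out = []
        span = int(math.ceil(r / self.cell))
        kx, kz = self._key(x, z)
        r2 = r * r
        for i in range(kx - span, kx + span + 1):
            for j in range(kz - span, kz + span + 1):
                for idx in self.buckets.get((i, j), ()):
                    px, pz = self.pts[idx]
                    if (px - x) ** 2 + (pz - z) ** 2 < r2:
                        out.append(idx)
        return out

    def any_within(self, x: float, z: float, r: float) -> bool:
        span = int(math.ceil(r / self.cell))
        kx, kz = self._key(x, z)
        r2 = r * r
        for i in range(kx - span, kx + span + 1):
            for j in range(kz - span, kz + span + 1):
                for idx in self.buckets.get((i, j), ()):
                    px, pz = self.pts[idx]
                    if (px - x) ** 2 + (pz - z) ** 2 < r2:
                        return True
        return False


class _FreeCells:
    """Tracks which fine grid cells of the region may still hold a new soma
    center, so restart points can be drawn uniformly from the remaining free
    region instead of by rejection over the whole rectangle (the same
    distribution, reached in far fewer draws near saturation)."""

    def __init__(self, region, d_min, rng):
        self.x0, self.x1, self.z0, self.z1 = region
        # cell small enough that a single placed soma can fully block it
        self.c = 0.45 * d_min
        self.nx = max(int(math.ceil((self.x1 - self.x0) / self.c)), 1)
        self.nz = max(int(math.ceil((self.z1 - self.z0) / self.c)), 1)
        self.free = np.ones(self.nx * self.nz, dtype=bool)
        self.n_free = self.nx * self.nz
        # block radius: any cell whose center is nearer than this to a soma
        # center lies entirely within the exclusion disc
        self.r_block = d_min - self.c * math.sqrt(2.0) / 2.0
        self.rng = rng

    def block_around(self, x: float, z: float) -> None:
        span = int(math.ceil(self.r_block / self.c))
        ci = int((x - self.x0) / self.c)
        cj = int((z - self.z0) / self.c)
        r2 = self.r_block ** 2
        for i in range(max(ci - span, 0), min(ci + span + 1, self.nx)):
            cx = self.x0 + (i + 0.5) * self.c
            dx2 = (cx - x) ** 2
            if dx2 > r2:
                continue
            for j in range(max(cj - span, 0), min(cj + span + 1, self.nz)):
                cz = self.z0 + (j + 0.5) * self.c
                k = i * self.nz + j
                if self.free[k] and dx2 + (cz - z) ** 2 <= r2:
                    self.free[k] = False
                    self.n_free -= 1

    def sample(self) -> tuple[float, float] | None:
        """A uniform point inside a uniformly chosen free cell (lazy-deleting
        list of free cell indices, amortized O(1) per draw)."""
        if not hasattr(self, "_pool"):
            self._pool = list(range(self.nx * self.nz))
        pool = self._pool
        while pool:
            p = int(self.rng.integers(len(pool)))
            k = pool[p]
            if not self.free[k]:
                pool[p] = pool[-1]
                pool.pop()
                continue
            i, j = divmod(k, self.nz)
            x = self.x0 + (i + self.rng.random()) * self.c
            z = self.z0 + (j + self.rng.random()) * self.c
            return (min(x, self.x1), min(z, self.z1))
        return None


def random_walk_place_2d(region: tuple[float, float, float, float],
                         n_target: int, soma_radius: float, eps: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Bounded self-avoiding random walk in a rectangle.

    The first cell is uniform-random; each next cell sits at distance
    ``2 r + s`` from the previous one along a uniform-random angle, with the
    scatter ``s`` drawn from a truncated normal around ``eps``.  A candidate
    overlapping any placed soma (closer than ``2 r``) or leaving the region
    is re-drawn; after ``CANDIDATE_TRIES`` failures the walk restarts from a
    fresh random point of the still-free region.  When restarts stop finding
    room, the remaining free cells are swept until no further soma fits
    (saturation) and the partial result is returned with a warning.

    Parameters
    ----------
    region : (x_lo, x_hi, z_lo, z_hi)

    Returns
    -------
    (n, 2) array of (x, z); n == n_target unless the region saturates.
    """
    x0, x1, z0, z1 = region
    if x1 - x0 < 2 * soma_radius or z1 - z0 < 2 * soma_radius:
        raise ConfigError("region too small for a single soma")
    from ._walkfill import walk_fill
    pts = walk_fill(region, 2.0 * soma_radius, eps, int(n_target), rng)
    if len(pts) < n_target:
        logger.warning("random walk saturated: placed %d of %d (r=%.3g)",
                       len(pts), n_target, soma_radius)
    return pts


def assign_vertical(points_2d: np.ndarray, sublayer: Sublayer,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform-random vertical coordinate within the sublayer, per cell.

    Returns (n, 3) positions ordered (x, y, z).
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    y = rng.uniform(sublayer.y_lo, sublayer.y_hi, size=len(pts)) \
        if sublayer.height > 0 else np.full(len(pts), sublayer.y_lo)
    return np.column_stack([pts[:, 0], y, pts[:, 1]])


def _assign_vertical_nonoverlap(points_2d: np.ndarray, sublayer: Sublayer,
                                soma_radius: float, below: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Uniform vertical draw that additionally avoids 3D overlap with the
    already-positioned cells of the sublayer below.

    Cells in the same sublayer are at least one soma diameter apart in the
    plane, so only the sublayer below (closer than 2 r vertically) can
    conflict.  For each cell the forbidden vertical intervals implied by its
    near-below neighbours are removed from the band and y is drawn uniformly
    from what remains; a cell with no free vertical room keeps the most
    distant feasible y (logged — in practice this does not occur at the
    reference densities).
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    d_min = 2.0 * soma_radius
    out = np.empty((len(pts), 3))
    out[:, 0] = pts[:, 0]
    out[:, 2] = pts[:, 1]
    bgrid = _Grid2D(cell=d_min)
    by = []
    for (bx, byy, bz) in below:
        bgrid.add(bx, bz)
        by.append(byy)
    by = np.asarray(by)
    y_lo, y_hi = sublayer.y_lo, sublayer.y_hi
    for i, (x, z) in enumerate(pts):
        nb = bgrid.neighbors_within(x, z, d_min) if len(by) else []
        if not nb:
            out[i, 1] = rng.uniform(y_lo, y_hi)
            continue
        # forbidden |y - y_n| < sqrt(d_min^2 - dxz^2) per neighbour
        segs = []
        for idx in nb:
            px, pz = bgrid.pts[idx]
            dxz2 = (px - x) ** 2 + (pz - z) ** 2
            half = math.sqrt(max(d_min * d_min - dxz2, 0.0))
            segs.append((max(by[idx] - half, y_lo), min(by[idx] + half, y_hi)))
        segs.sort()
        allowed = []
        cur = y_lo
        for a, b in segs:
            if a > cur:
                allowed.append((cur, a))
            cur = max(cur, b)
        if cur < y_hi:
            allowed.append((cur, y_hi))
        total = sum(b - a for a, b in allowed)
        if total <= 0:
            logger.warning("no overlap-free vertical room; keeping top of band")
            out[i, 1] = y_hi
            continue
        u = rng.uniform(0.0, total)
        for a, b in allowed:
            if u <= b - a:
                out[i, 1] = a + u
                break
            u -= b - a
    return out


def place_population(cfg: ScaffoldConfig, name: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Place one walk-population (GoC, Glom, GrC, BC, SC) in its layer.

    Returns (n, 3) soma positions; n can fall short of the density target
    when the layer saturates (granule cells do at the reference density).
    """
    spec = cfg.neurons[name]
    y0, y1 = cfg.volume.layer_bounds(spec.layer)
    region = cfg.volume.layer_base(spec.layer)
    subs = plan_sublayers(y1 - y0, spec.soma_radius)
    if not subs:
        raise ConfigError(
            f"layer {spec.layer!r} shorter than one sublayer for {name}")
    n_total = int(round(spec.density * cfg.volume.layer_volume(spec.layer)))
    eps = compute_epsilon(spec.density, spec.soma_radius)
    # spread the layer target over the sublayers as evenly as possible
    base, extra = divmod(n_total, len(subs))
    targets = [base + (1 if k < extra else 0) for k in range(len(subs))]
    below = np.empty((0, 3))
    chunks = []
    for sub, n_k in zip(subs, targets):
        pts2 = random_walk_place_2d(region, n_k, spec.soma_radius, eps, rng)
        pos = _assign_vertical_nonoverlap(pts2, Sublayer(sub.y_lo + y0,
                                                         sub.y_hi + y0),
                                          spec.soma_radius, below, rng)
        chunks.append(pos)
        below = pos
    return np.concatenate(chunks, axis=0) if chunks else np.empty((0, 3))


def place_purkinje(cfg: ScaffoldConfig, rng: np.random.Generator,
                   tree_radius: float = 150.0, tree_width: float = 30.0,
                   shift_deg: float = 5.0) -> np.ndarray:
    """Purkinje somata on a jittered planar grid in the PC layer.

    The planar density fixes the cell count; the grid is near-square with
    both pitches at least ``tree_width`` so adjacent parasagittal dendritic
    slabs (extending +-``tree_radius`` in x, ``tree_width`` thick in z) do
    not overlap between neighbouring sagittal planes.  Alternate rows are
    offset in x so the mean angular shift between adjacent cells is about
    ``shift_deg`` degrees, plus a small positional jitter and vertical noise
    inside the 30 um layer.
    """
    spec = cfg.neurons["PC"]
    x0, x1, z0, z1 = cfg.volume.layer_base(spec.layer)
    y_lo, y_hi = cfg.volume.layer_bounds(spec.layer)
    bx, bz = x1 - x0, z1 - z0
    n_target = max(int(round(spec.density * bx * bz)), 1)
    n_z = max(int(round(math.sqrt(n_target * bz / bx))), 1)
    n_x = max(int(math.ceil(n_target / n_z)), 1)
    pitch_x, pitch_z = bx / n_x, bz / n_z
    if pitch_z < tree_width:
        n_z = max(int(bz // tree_width), 1)
        pitch_z = bz / n_z
        n_x = max(int(math.ceil(n_target / n_z)), 1)
        pitch_x = bx / n_x
    row_offset = math.tan(math.radians(shift_deg)) * pitch_z
    jitter = min(pitch_x, pitch_z) * 0.05
    pos = []
    placed = 0
    for j in range(n_z):
        for i in range(n_x):
            if placed >= n_target:
                break
            x = x0 + (i + 0.5) * pitch_x + (j % 2) * row_offset \
                + rng.uniform(-jitter, jitter)
            z = z0 + (j + 0.5) * pitch_z + rng.uniform(-jitter, jitter)
            y = rng.uniform(y_lo + 0.25 * (y_hi - y_lo),
                            y_hi - 0.25 * (y_hi - y_lo))
            pos.append((x % bx + x0, y, z))
            placed += 1
    return np.asarray(pos)


def place_uniform(cfg: ScaffoldConfig, name: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Uniform random placement with soma non-overlap by rejection.

    Used for glomeruli (mossy-fiber terminals scatter homogeneously in the
    granular layer; they are not somata migrating along a walk) and for the
    handful of DCN cells.
    """
    spec = cfg.neurons[name]
    x0, x1, z0, z1 = cfg.volume.layer_base(spec.layer)
    y0, y1 = cfg.volume.layer_bounds(spec.layer)
    n = int(round(spec.density * cfg.volume.layer_volume(spec.layer)))
    d_min = 2 * spec.soma_radius
    d2 = d_min * d_min
    cell = d_min
    buckets: dict[tuple[int, int, int], list[int]] = {}
    pos: list[tuple[float, float, float]] = []

    def key(p):
        return (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))

    def clear(p):
        ki, kj, kk = key(p)
        for i in (ki - 1, ki, ki + 1):
            for j in (kj - 1, kj, kj + 1):
                for k in (kk - 1, kk, kk + 1):
                    for idx in buckets.get((i, j, k), ()):
                        q = pos[idx]
                        if ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                                + (p[2] - q[2]) ** 2) < d2:
                            return False
        return True

    tries = 0
    while len(pos) < n and tries < 200 * max(n, 1):
        tries += 1
        p = (rng.uniform(x0, x1), rng.uniform(y0, y1), rng.uniform(z0, z1))
        if clear(p):
            buckets.setdefault(key(p), []).append(len(pos))
            pos.append(p)
    if len(pos) < n:
        logger.warning("uniform placement saturated: %d of %d %s",
                       len(pos), n, name)
    return np.asarray(pos).reshape(-1, 3)


def sample_aa_heights(n: int, soma_y: np.ndarray, y_top: float,
                      rng: np.random.Generator,
                      mean: float = 181.0, sd: float = 66.0) -> np.ndarray:
    """Ascending-axon heights: Gaussian(mean, sd) truncated to
    (0, y_top - soma_y] — the axon cannot extend above the pial surface.

    The returned height, added to the soma y, is also the vertical
    coordinate at which the cell's parallel fiber runs.
    """
    soma_y = np.asarray(soma_y, dtype=float)
    h = rng.normal(mean, sd, size=n)
    cap = y_top - soma_y
    bad = (h <= 0) | (h > cap)
    for _ in range(200):
        if not bad.any():
            break
        h[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (h <= 0) | (h > cap)
    return np.clip(h, np.finfo(float).tiny, cap)


def place_all(cfg: ScaffoldConfig, seed: int | None = None) -> PlacementTable:
    """Place all seven populations; one master seed expands into independent
    per-population child streams, so any population is reproducible on its
    own."""
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = {name: np.random.default_rng(s)
                for name, s in zip(PLACEMENT_ORDER,
                                   ss.spawn(len(PLACEMENT_ORDER)))}
    aa_rng = np.random.default_rng(ss.spawn(1)[0])
    blocks, codes = [], []
    for name in PLACEMENT_ORDER:
        if name == "PC":
            pos = place_purkinje(cfg, children[name])
        elif name in ("Glom", "DCNC"):
            pos = place_uniform(cfg, name, children[name])
        else:
            pos = place_population(cfg, name, children[name])
        blocks.append(pos)
        codes.append(np.full(len(pos), cfg.neurons[name].type_code,
                             dtype=np.int64))
        logger.info("placed %6d %s", len(pos), name)
    xyz = np.concatenate(blocks, axis=0)
    type_code = np.concatenate(codes)
    cell_id = np.arange(len(xyz), dtype=np.int64)
    table = PlacementTable(cell_id=cell_id, type_code=type_code, xyz=xyz,
                           type_names={n: cfg.neurons[n].type_code
                                       for n in NEURON_TYPES},
                           seed=seed)
    grc_ids = table.ids_of("GrC")
    grc_y = table.positions_of("GrC")[:, 1]
    y_top = cfg.volume.cortical_height
    heights = sample_aa_heights(len(grc_ids), grc_y, y_top, aa_rng)
    table.aa_height = np.column_stack([grc_ids.astype(float), heights])
    return table


# ---------------------------------------------------------------------------
# KDE validation of pair-wise distances
# ---------------------------------------------------------------------------

# fixed Gaussian bandwidth (um) for the Purkinje population: the PC lattice
# is multimodal and Silverman's rule on only ~2.5k pair distances
# oversmooths its maxima into one; the large homogeneous populations use
# Silverman's rule (bandwidth=None)
PC_KDE_BANDWIDTH = 8.0

def pairwise_distance_sample(positions: np.ndarray, max_pairs: int | None,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """All C(n,2) 3D pair-wise distances, or a uniform random sample of
    ``max_pairs`` of them for large populations."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least two positions")
    n_pairs = n * (n - 1) // 2
    if max_pairs is None or n_pairs <= max_pairs:
        from scipy.spatial.distance import pdist
        return pdist(pos)
    rng = np.random.default_rng(0) if rng is None else rng
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)
    return np.linalg.norm(pos[i] - pos[j], axis=1)


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def kde_pairwise_distances(positions: np.ndarray,
                           bandwidth: float | None = None,
                           max_pairs: int | None = 200_000,
                           rng: np.random.Generator | None = None,
                           grid_points: int = 1024) -> KdeResult:
    """Gaussian KDE of the 3D pair-wise inter-soma distance distribution.

    The kernel bandwidth is fixed per population (Silverman's rule on the
    distance sample unless given).  The estimate is evaluated on a regular
    grid (a fine histogram convolved with the Gaussian kernel, which is the
    KDE restricted to the grid) and local maxima are reported.
    """
    d = pairwise_distance_sample(positions, max_pairs, rng)
    bw = _silverman_bandwidth(d) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        bw = max(float(np.std(d)), 1e-6)
    lo = max(d.min() - 4 * bw, 0.0)
    hi = d.max() + 4 * bw
    grid = np.linspace(lo, hi, grid_points)
    dx = grid[1] - grid[0]
    hist, _ = np.histogram(d, bins=grid_points,
                           range=(lo - dx / 2, hi + dx / 2))
    dens = gaussian_filter1d(hist.astype(float), sigma=bw / dx,
                             mode="constant")
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    peaks, props = find_peaks(dens, prominence=0.02 * dens.max())
    order = np.argsort(dens[peaks])[::-1]
    maxima = grid[peaks][order]
    return KdeResult(grid=grid, density=dens, maxima=maxima, bandwidth=bw)
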