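"""Connectome construction by intersection-connection rules.

Each of the sixteen connection types is built in two steps.  First,
*geometric candidate generation*: every (pre, post) pair whose axonal and
dendritic fields intersect — spheres for granule-cell dendrites, cylinders
for Golgi dendritic fields, boxes for axonal plexi, lines for parallel
fibers, thin slabs for Purkinje trees — becomes a candidate.  Second,
*pruning*: where the literature prescribes a convergence (afferents per
post cell) or divergence (efferents per pre cell) ratio, candidates are
sampled without replacement down to that ratio with a probability that
decays with distance as an anisotropic Gaussian (per-axis decay lengths
from the rule).  Rules without a ratio pass their candidates through.

The Golgi-to-granule inhibition is not built geometrically: the reference
rule fuses Golgi-to-glomerulus edges with glomerulus-to-granule edges, so
a Golgi cell inhibits exactly the granule cells driven by the glomeruli
its axon reaches.

Every edge stores the 3D inter-soma distance of its pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .config import ScaffoldConfig, ConnectionRule, CONNECTION_TYPES
from .placement import PlacementTable

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "RatioReport",
    "geometric_candidates",
    "prune_candidates",
    "fuse_goc_glom_grc",
    "build_connectome",
    "ratio_report",
    "orthogonal_plexus_rules",
]

# build order: the fused rule needs its two parents first
BUILD_ORDER = (
    "glomerulus_to_granule",
    "glomerulus_to_golgi",
    "golgi_to_glomerulus",
    "golgi_to_granule",
    "golgi_to_golgi",
    "ascending_axon_to_golgi",
    "parallel_fiber_to_golgi",
    "stellate_to_stellate",
    "basket_to_basket",
    "parallel_fiber_to_stellate",
    "parallel_fiber_to_basket",
    "stellate_to_purkinje",
    "basket_to_purkinje",
    "ascending_axon_to_purkinje",
    "parallel_fiber_to_purkinje",
    "purkinje_to_dcn",
    "glomerulus_to_dcn",
)


@dataclass
class Connectome:
    """Edge lists per connection type: (E, 3) arrays [pre_id, post_id,
    inter-soma distance um]."""

    edges: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.edges[name]

    def __contains__(self, name: str) -> bool:
        return name in self.edges

    def names(self):
        return list(self.edges)

    def n_edges(self) -> int:
        return int(sum(len(e) for e in self.edges.values()))


@dataclass
class RatioReport:
    """Model vs configured convergence/divergence ratios."""

    convergence: dict[str, tuple[float, float, float]]  # name -> (mean, sd, target)
    divergence: dict[str, tuple[float, float, float]]
    slope: float | None
    r2: float | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# geometry predicates
# ---------------------------------------------------------------------------

def _pos(placement: PlacementTable, name: str):
    ids = placement.ids_of(name)
    return ids, placement.xyz[ids]


def _aa_tip_y(placement: PlacementTable) -> tuple[np.ndarray, np.ndarray]:
    """Granule-cell ids and the absolute y at which each ascending axon ends
    (= the height of its parallel fiber)."""
    grc_ids = placement.aa_height[:, 0].astype(np.int64)
    tip = placement.xyz[grc_ids, 1] + placement.aa_height[:, 1]
    return grc_ids, tip


def _pairs_from_masks(pre_ids, post_ids, mask_fn):
    """Loop the smaller population, vectorize over the larger."""
    pres, posts = [], []
    for k, pid in enumerate(post_ids):
        m = mask_fn(k)
        if m.any():
            sel = pre_ids[m]
            pres.append(sel)
            posts.append(np.full(len(sel), pid, dtype=np.int64))
    if not pres:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    return np.concatenate(pres), np.concatenate(posts)


def geometric_candidates(rule: ConnectionRule, placement: PlacementTable,
                         cfg: ScaffoldConfig) -> tuple[np.ndarray, np.ndarray]:
    """All (pre_id, post_id) pairs satisfying the rule's geometry.

    Symmetric within-population rules exclude self-pairs.  The fused
    golgi_to_granule rule has no geometry of its own and raises.
    """
    g = rule.geometry
    vol = cfg.volume
    mol_lo, mol_hi = vol.layer_bounds("molecular")
    name = rule.name

    if name == "glomerulus_to_granule":
        gid, gpos = _pos(placement, "Glom")
        cid, cpos = _pos(placement, "GrC")
        r = float(g["max_dendrite_length"])
        coo = cKDTree(gpos).sparse_distance_matrix(
            cKDTree(cpos), r, output_type="coo_matrix")
        return gid[coo.row], cid[coo.col]

    if name == "glomerulus_to_golgi":
        gid, gpos = _pos(placement, "Glom")
        qid, qpos = _pos(placement, "GoC")
        r2 = float(g["basolateral_radius_xz"]) ** 2

        def mask(k):
            dx = gpos[:, 0] - qpos[k, 0]
            dz = gpos[:, 2] - qpos[k, 2]
            return (dx * dx + dz * dz <= r2) & (gpos[:, 1] <= qpos[k, 1])
        return _pairs_from_masks(gid, qid, mask)

    if name == "golgi_to_glomerulus":
        pid, ppos = _pos(placement, "GoC")
        gid, gpos = _pos(placement, "Glom")
        hx = float(g["axon_halfwidth_x"])
        hz = float(g["axon_halfwidth_z"])
        pres, posts = [], []
        for k, goc in enumerate(pid):
            m = (np.abs(gpos[:, 0] - ppos[k, 0]) <= hx) & \
                (np.abs(gpos[:, 2] - ppos[k, 2]) <= hz)
            if m.any():
                sel = gid[m]
                pres.append(np.full(len(sel), goc, dtype=np.int64))
                posts.append(sel)
        if not pres:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(pres), np.concatenate(posts)

    if name == "golgi_to_granule":
        raise ValueError("golgi_to_granule is fused from golgi_to_glomerulus "
                         "and glomerulus_to_granule; use fuse_goc_glom_grc")

    if name in ("golgi_to_golgi", "stellate_to_stellate", "basket_to_basket"):
        pop = {"golgi_to_golgi": "GoC", "stellate_to_stellate": "SC",
               "basket_to_basket": "BC"}[name]
        ids, pos = _pos(placement, pop)
        r = float(g["max_distance"])
        coo = cKDTree(pos).sparse_distance_matrix(
            cKDTree(pos), r, output_type="coo_matrix")
        keep = coo.row != coo.col
        return ids[coo.row[keep]], ids[coo.col[keep]]

    if name == "ascending_axon_to_golgi":
        cid, cpos = _pos(placement, "GrC")
        qid, qpos = _pos(placement, "GoC")
        grc_ids, tip = _aa_tip_y(placement)
        n_global = int(placement.cell_id.max()) + 1 if len(placement) else 0
        tip_of = np.zeros(n_global)
        tip_of[grc_ids] = tip
        r2 = float(g["basolateral_radius_xz"]) ** 2
        ctip = tip_of[cid]

        def mask(k):
            dx = cpos[:, 0] - qpos[k, 0]
            dz = cpos[:, 2] - qpos[k, 2]
            return ((dx * dx + dz * dz <= r2)
                    & (cpos[:, 1] <= qpos[k, 1]) & (ctip >= qpos[k, 1]))
        return _pairs_from_masks(cid, qid, mask)

    if name == "parallel_fiber_to_golgi":
        cid, cpos = _pos(placement, "GrC")
        qid, qpos = _pos(placement, "GoC")
        _, tip = _aa_tip_y(placement)
        rx = float(g["apical_radius_x"])
        hz = float(g["pf_half_length"])
        in_mol = tip >= mol_lo

        def mask(k):
            return (in_mol
                    & (np.abs(cpos[:, 0] - qpos[k, 0]) <= rx)
                    & (np.abs(cpos[:, 2] - qpos[k, 2]) <= hz))
        return _pairs_from_masks(cid, qid, mask)

    if name in ("parallel_fiber_to_stellate", "parallel_fiber_to_basket"):
        pop = "SC" if name.endswith("stellate") else "BC"
        cid, cpos = _pos(placement, "GrC")
        qid, qpos = _pos(placement, pop)
        _, tip = _aa_tip_y(placement)
        rd = float(g["dendrite_radius"])
        hz = float(g["pf_half_length"])

        def mask(k):
            return ((np.abs(cpos[:, 0] - qpos[k, 0]) <= rd)
                    & (np.abs(tip - qpos[k, 1]) <= rd)
                    & (np.abs(cpos[:, 2] - qpos[k, 2]) <= hz))
        return _pairs_from_masks(cid, qid, mask)

    if name in ("stellate_to_purkinje", "basket_to_purkinje"):
        pop = "SC" if name.startswith("stellate") else "BC"
        iid, ipos = _pos(placement, pop)
        pid, ppos = _pos(placement, "PC")
        hx = float(g["axon_halfwidth_x"]) + float(g["slab_halfwidth_x"])
        hz = float(g["axon_halfwidth_z"]) + float(g["slab_halfwidth_z"])

        def mask(k):
            return ((np.abs(ipos[:, 0] - ppos[k, 0]) <= hx)
                    & (np.abs(ipos[:, 2] - ppos[k, 2]) <= hz))
        return _pairs_from_masks(iid, pid, mask)

    if name == "ascending_axon_to_purkinje":
        cid, cpos = _pos(placement, "GrC")
        pid, ppos = _pos(placement, "PC")
        _, tip = _aa_tip_y(placement)
        hx = float(g["slab_halfwidth_x"])
        hz = float(g["contact_halfwidth_z"])
        reaches = tip >= mol_lo  # the axon must enter the molecular layer

        def mask(k):
            return (reaches
                    & (np.abs(cpos[:, 0] - ppos[k, 0]) <= hx)
                    & (np.abs(cpos[:, 2] - ppos[k, 2]) <= hz))
        return _pairs_from_masks(cid, pid, mask)

    if name == "parallel_fiber_to_purkinje":
        cid, cpos = _pos(placement, "GrC")
        pid, ppos = _pos(placement, "PC")
        _, tip = _aa_tip_y(placement)
        hx = float(g["slab_halfwidth_x"])
        hz = float(g["pf_half_length"])
        in_mol = tip >= mol_lo

        def mask(k):
            return (in_mol
                    & (np.abs(cpos[:, 0] - ppos[k, 0]) <= hx)
                    & (np.abs(cpos[:, 2] - ppos[k, 2]) <= hz))
        return _pairs_from_masks(cid, pid, mask)

    if name == "purkinje_to_dcn":
        pid, _ = _pos(placement, "PC")
        did, _ = _pos(placement, "DCNC")
        pre = np.repeat(pid, len(did))
        post = np.tile(did, len(pid))
        return pre, post

    if name == "glomerulus_to_dcn":
        gid, _ = _pos(placement, "Glom")
        did, _ = _pos(placement, "DCNC")
        pre = np.repeat(gid, len(did))
        post = np.tile(did, len(gid))
        return pre, post

    raise ValueError(f"unknown connection rule {name!r}")


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _distance_weights(rule: ConnectionRule, delta: np.ndarray) -> np.ndarray:
    """Anisotropic Gaussian decay exp(-sum (d_axis / lambda_axis)^2); axes
    with no scale do not contribute."""
    if rule.pruning_scales is None:
        return np.ones(len(delta))
    q = np.zeros(len(delta))
    for ax, lam in enumerate(rule.pruning_scales):
        if lam is not None:
            q += (delta[:, ax] / lam) ** 2
    return np.exp(-q)


def _select_k_per_group(group: np.ndarray, keys: np.ndarray,
                        k: int) -> np.ndarray:
    """Indices of the k smallest keys within each group (all when fewer)."""
    order = np.lexsort((keys, group))
    gsorted = group[order]
    new = np.r_[True, gsorted[1:] != gsorted[:-1]]
    starts = np.flatnonzero(new)
    rank = np.arange(len(gsorted)) - np.repeat(starts, np.diff(
        np.r_[starts, len(gsorted)]))
    return order[rank < k]


def prune_candidates(pre: np.ndarray, post: np.ndarray,
                     rule: ConnectionRule, placement: PlacementTable,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample candidates down to the rule's convergence (per post cell) or,
    failing that, divergence (per pre cell) target.

    Selection is without replacement via exponential race keys
    ``Exp(1) / w`` with Gaussian distance weights ``w``, so a rule is
    reproducible under a fixed seed and exact: every post (pre) cell with at
    least the target number of candidates ends with exactly the target
    in-degree (out-degree).  Rules with neither target pass through.
    """
    if len(pre) == 0:
        return pre, post
    if rule.convergence is None and rule.divergence is None:
        return pre, post
    delta = placement.xyz[pre] - placement.xyz[post]
    w = _distance_weights(rule, delta)
    keys = rng.exponential(size=len(pre)) / np.maximum(w, 1e-300)
    if rule.convergence is not None:
        k = int(round(rule.convergence))
        sel = _select_k_per_group(post, keys, k)
    else:
        k = int(round(rule.divergence))
        sel = _select_k_per_group(pre, keys, k)
    sel.sort()
    return pre[sel], post[sel]


def fuse_goc_glom_grc(goc_glom: tuple[np.ndarray, np.ndarray],
                      glom_grc: tuple[np.ndarray, np.ndarray]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Relational join: (GoC g -> Glom m) x (Glom m -> GrC c) => (g -> c),
    duplicates collapsed.  A Golgi cell thereby inhibits exactly the granule
    cells driven by the glomeruli its axon reaches."""
    g_pre, g_post = goc_glom
    m_pre, m_post = glom_grc
    if len(g_pre) == 0 or len(m_pre) == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    order = np.argsort(m_pre, kind="stable")
    m_pre_s, m_post_s = m_pre[order], m_post[order]
    lo = np.searchsorted(m_pre_s, g_post, side="left")
    hi = np.searchsorted(m_pre_s, g_post, side="right")
    counts = hi - lo
    goc = np.repeat(g_pre, counts)
    idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) \
        if counts.sum() else np.empty(0, dtype=np.int64)
    grc = m_post_s[idx]
    pairs = np.unique(np.column_stack([goc, grc]), axis=0)
    return pairs[:, 0], pairs[:, 1]


def _with_distance(placement: PlacementTable, pre: np.ndarray,
                   post: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(placement.xyz[pre] - placement.xyz[post], axis=1)
    return np.column_stack([pre.astype(float), post.astype(float), d])


def build_connectome(placement: PlacementTable, cfg: ScaffoldConfig,
                     seed: int | None = None,
                     rules: dict[str, ConnectionRule] | None = None
                     ) -> Connectome:
    """Build all sixteen edge sets in dependency order.

    ``rules`` overrides the configured rule set (used by the
    orthogonal-plexus variant).  Per-rule child seeds derive from the master
    seed, so the connectome is reproducible given placement + seed.
    """
    seed = cfg.seed if seed is None else seed
    rules = cfg.rules if rules is None else rules
    ss = np.random.SeedSequence([seed, 1])
    streams = {name: np.random.default_rng(s)
               for name, s in zip(BUILD_ORDER, ss.spawn(len(BUILD_ORDER)))}
    for pop in ("GoC", "Glom", "GrC", "PC", "BC", "SC", "DCNC"):
        if len(placement.ids_of(pop)) == 0 and pop != "DCNC":
            logger.warning("population %s is empty", pop)
    conn = Connectome(seed=seed)
    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in BUILD_ORDER:
        rule = rules[name]
        if name == "golgi_to_granule":
            pre, post = fuse_goc_glom_grc(raw["golgi_to_glomerulus"],
                                          raw["glomerulus_to_granule"])
        else:
            cand = geometric_candidates(rule, placement, cfg)
            pre, post = prune_candidates(*cand, rule, placement,
                                         streams[name])
            _check_shortfall(rule, pre, post)
        raw[name] = (pre, post)
        conn.edges[name] = _with_distance(placement, pre, post)
        logger.info("%-28s %8d edges", name, len(pre))
    # golgi_to_glomerulus is a structural intermediate, not a synapse type
    del conn.edges["golgi_to_glomerulus"]
    return conn


def _check_shortfall(rule, pre, post):
    if rule.convergence is None or len(post) == 0:
        return
    k = int(round(rule.convergence))
    _, counts = np.unique(post, return_counts=True)
    short = int(np.sum(counts < k))
    if short:
        logger.info("%s: %d post cells below convergence target %d "
                    "(geometry shortfall at volume borders)",
                    rule.name, short, k)


def ratio_report(connectome: Connectome, placement: PlacementTable,
                 rules: dict[str, ConnectionRule]) -> RatioReport:
    """Mean +- sd convergence/divergence per connection type and the
    least-squares regression of model means against configured targets.

    The regression uses every rule with a convergence target plus the
    divergence-targeted rules; with fewer than two distinct targets the
    regression is flagged degenerate.
    """
    conv, div = {}, {}
    xs, ys = [], []
    for name, edges in connectome.edges.items():
        rule = rules.get(name)
        if rule is None or len(edges) == 0:
            continue
        post_type = rule.post_type
        pre_type = rule.pre_type
        n_post = len(placement.ids_of(post_type))
        n_pre = len(placement.ids_of(pre_type))
        _, in_deg = np.unique(edges[:, 1].astype(np.int64),
                              return_counts=True)
        in_deg = np.r_[in_deg, np.zeros(max(n_post - len(in_deg), 0))]
        _, out_deg = np.unique(edges[:, 0].astype(np.int64),
                               return_counts=True)
        out_deg = np.r_[out_deg, np.zeros(max(n_pre - len(out_deg), 0))]
        cm, cs = float(np.mean(in_deg)), float(np.std(in_deg))
        dm, ds = float(np.mean(out_deg)), float(np.std(out_deg))
        conv[name] = (cm, cs, rule.convergence)
        div[name] = (dm, ds, rule.divergence)
        if rule.convergence is not None:
            xs.append(rule.convergence)
            ys.append(cm)
        elif rule.divergence is not None:
            xs.append(rule.divergence)
            ys.append(dm)
    if len(set(xs)) < 2:
        return RatioReport(conv, div, slope=None, r2=None, degenerate=True)
    lin = stats.linregress(xs, ys)
    return RatioReport(conv, div, slope=float(lin.slope),
                       r2=float(lin.rvalue ** 2))


def orthogonal_plexus_rules(cfg: ScaffoldConfig) -> dict[str, ConnectionRule]:
    """Rule set with the stellate and basket axonal plexi swapped (the
    molecular-layer orientation experiment): each keeps its own targets but
    takes the other's axonal extents and pruning anisotropy."""
    import copy
    rules = copy.deepcopy(cfg.rules)
    sc, bc = rules["stellate_to_purkinje"], rules["basket_to_purkinje"]
    for key in ("axon_halfwidth_x", "axon_halfwidth_z"):
        sc.geometry[key], bc.geometry[key] = bc.geometry[key], sc.geometry[key]
    sc.pruning_scales, bc.pruning_scales = bc.pruning_scales, sc.pruning_scales
    return rules
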