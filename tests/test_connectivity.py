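"""Connectome construction: geometric predicates, pruning, fusion, and
report statistics — mostly on hand-built toy placements with brute-force
oracles."""

import copy

import numpy as np
import pytest

from cerescaffold import connectivity as C
from cerescaffold.config import ConnectionRule, default_config
from cerescaffold.placement import PlacementTable


def make_table(cfg, **pops):
    """Hand-built placement: pops maps type name -> (n, 3) positions;
    optional key 'aa' maps grc row order -> heights."""
    aa = pops.pop("aa", None)
    names = {n: cfg.neurons[n].type_code for n in cfg.neurons}
    xyz, codes = [], []
    for name, pos in pops.items():
        pos = np.asarray(pos, dtype=float).reshape(-1, 3)
        xyz.append(pos)
        codes.append(np.full(len(pos), names[name], dtype=np.int64))
    xyz = np.concatenate(xyz) if xyz else np.empty((0, 3))
    codes = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
    table = PlacementTable(cell_id=np.arange(len(xyz), dtype=np.int64),
                           type_code=codes, xyz=xyz, type_names=names)
    grc = table.ids_of("GrC")
    heights = np.full(len(grc), 200.0) if aa is None else np.asarray(aa, float)
    table.aa_height = np.column_stack([grc.astype(float), heights])
    return table


@pytest.fixture(scope="module")
def cfg():
    return default_config(0)


# ------------------------------------------------------ geometry predicates

def test_glom_grc_sphere_predicate(cfg):
    tab = make_table(cfg,
                     Glom=[[0, 75, 0], [39.0, 75, 0], [41.0, 75, 0]],
                     GrC=[[0, 75, 0]])
    pre, post = C.geometric_candidates(cfg.rules["glomerulus_to_granule"],
                                       tab, cfg)
    # gloms at 0 and 39 um connect, the one at 41 um is out of reach
    assert sorted(pre.tolist()) == [0, 1]
    assert set(post.tolist()) == {3}


def test_grc_without_nearby_glom_has_no_candidates(cfg):
    tab = make_table(cfg, Glom=[[0, 75, 0]], GrC=[[200, 75, 200]])
    pre, post = C.geometric_candidates(cfg.rules["glomerulus_to_granule"],
                                       tab, cfg)
    assert len(pre) == 0


def test_geometry_monotone_in_bound(cfg):
    rng = np.random.default_rng(0)
    tab = make_table(cfg,
                     Glom=rng.uniform(0, 150, (60, 3)) * [1, 0.5, 1],
                     GrC=rng.uniform(0, 150, (40, 3)) * [1, 0.5, 1])
    rule40 = cfg.rules["glomerulus_to_granule"]
    rule60 = copy.deepcopy(rule40)
    rule60.geometry["max_dendrite_length"] = 60.0
    a = set(map(tuple, np.column_stack(
        C.geometric_candidates(rule40, tab, cfg))))
    b = set(map(tuple, np.column_stack(
        C.geometric_candidates(rule60, tab, cfg))))
    assert a <= b and len(b) > len(a)


def test_symmetric_rule_excludes_self_pairs(cfg):
    tab = make_table(cfg, GoC=[[0, 75, 0], [50, 75, 0], [500, 75, 0]])
    pre, post = C.geometric_candidates(cfg.rules["golgi_to_golgi"], tab, cfg)
    assert (pre != post).all()
    # only the two nearby cells pair up, in both directions
    assert set(map(tuple, np.column_stack([pre, post]))) == {(0, 1), (1, 0)}


def test_aa_pc_requires_thin_z_alignment(cfg):
    # PC at x=200,z=200; GrC aligned in z within the contact half-width
    tab = make_table(cfg,
                     GrC=[[150, 75, 203], [150, 75, 215], [150, 75, 196]],
                     PC=[[200, 165, 200]],
                     aa=[200.0, 200.0, 10.0])
    pre, post = C.geometric_candidates(
        cfg.rules["ascending_axon_to_purkinje"], tab, cfg)
    # grc0: |dz|=3 <= 5 and aa reaches molecular layer -> candidate
    # grc1: |dz|=15 too far; grc2: aligned but aa too short (75+10 < 180)
    assert pre.tolist() == [0]


def test_pf_length_bound_applied(cfg):
    # pf runs along z; GrC beyond the 200 um half-length cannot reach the PC
    tab = make_table(cfg,
                     GrC=[[200, 75, 340], [200, 75, 100]],
                     PC=[[200, 165, 350]],
                     aa=[200.0, 200.0])
    pre, _ = C.geometric_candidates(
        cfg.rules["parallel_fiber_to_purkinje"], tab, cfg)
    assert pre.tolist() == [0]  # |dz| = 10 reaches; |dz| = 250 exceeds the bound


# ----------------------------------------------------------------- pruning

def test_prune_exact_convergence(cfg, rng):
    n_glom, n_grc = 60, 15
    tab = make_table(cfg,
                     Glom=rng.uniform(40, 110, (n_glom, 3)) * [1, 0.5, 1],
                     GrC=rng.uniform(40, 110, (n_grc, 3)) * [1, 0.5, 1])
    rule = cfg.rules["glomerulus_to_granule"]
    pre, post = C.geometric_candidates(rule, tab, cfg)
    p2, q2 = C.prune_candidates(pre, post, rule, tab, rng)
    _, counts = np.unique(q2, return_counts=True)
    cand_counts = np.unique(post, return_counts=True)[1]
    assert (cand_counts >= 4).all()  # dense toy: everyone has enough
    assert (counts == 4).all()
    # pruned set is a subset of the candidates
    assert set(map(tuple, np.column_stack([p2, q2]))) <= \
        set(map(tuple, np.column_stack([pre, post])))


def test_prune_identity_when_candidates_equal_target(cfg, rng):
    rule = copy.deepcopy(cfg.rules["glomerulus_to_granule"])
    rule.convergence = 3
    tab = make_table(cfg,
                     Glom=[[0, 75, 0], [10, 75, 0], [0, 75, 10]],
                     GrC=[[5, 75, 5]])
    pre, post = C.geometric_candidates(rule, tab, cfg)
    p2, q2 = C.prune_candidates(pre, post, rule, tab, rng)
    assert len(p2) == 3
    assert set(p2.tolist()) == {0, 1, 2}


def test_prune_prefers_near_candidates(cfg):
    # with a short decay length the near glom is selected almost always
    rule = copy.deepcopy(cfg.rules["glomerulus_to_granule"])
    rule.convergence = 1
    rule.pruning_scales = (8.0, 8.0, 8.0)
    near, far = 0, 0
    tab = make_table(cfg, Glom=[[5, 75, 0], [35, 75, 0]], GrC=[[0, 75, 0]])
    pre, post = C.geometric_candidates(rule, tab, cfg)
    for s in range(200):
        p2, _ = C.prune_candidates(pre, post, rule, tab,
                                   np.random.default_rng(s))
        if p2[0] == 0:
            near += 1
        else:
            far += 1
    assert near > 190


def test_prune_divergence_side(cfg, rng):
    rule = copy.deepcopy(cfg.rules["golgi_to_glomerulus"])
    rule.divergence = 2
    tab = make_table(cfg,
                     GoC=[[100, 75, 100]],
                     Glom=[[100 + dx, 50, 100] for dx in (0, 5, 10, 15, 20)])
    pre, post = C.geometric_candidates(rule, tab, cfg)
    p2, q2 = C.prune_candidates(pre, post, rule, tab, rng)
    assert len(q2) == 2


# ------------------------------------------------------------------ fusion

def test_fusion_definition_and_dedup():
    g = (np.array([7, 7]), np.array([100, 101]))      # GoC 7 -> gloms 100,101
    m = (np.array([100, 101, 101]), np.array([1, 1, 2]))  # gloms -> GrCs
    pre, post = C.fuse_goc_glom_grc(g, m)
    # 7->100->1 and 7->101->1 collapse to a single (7, 1) edge
    assert set(map(tuple, np.column_stack([pre, post]))) == {(7, 1), (7, 2)}


def test_fusion_matches_brute_force_join(cfg, rng):
    goc = rng.integers(0, 5, 40)
    glm = rng.integers(100, 110, 40)
    glm2 = rng.integers(100, 110, 60)
    grc = rng.integers(200, 230, 60)
    pre, post = C.fuse_goc_glom_grc((goc, glm), (glm2, grc))
    expected = {(int(a), int(c))
                for a, b in zip(goc, glm)
                for b2, c in zip(glm2, grc) if b == b2}
    assert set(map(tuple, np.column_stack([pre, post]))) == expected


def test_fusion_empty_inputs():
    e = np.empty(0, dtype=np.int64)
    pre, post = C.fuse_goc_glom_grc((e, e), (e, e))
    assert len(pre) == 0


# ------------------------------------------------- full connectome checks

def test_connectome_referential_integrity(cfg_small, placement_small,
                                          connectome_small):
    for name, edges in connectome_small.edges.items():
        if not len(edges):
            continue
        rule = cfg_small.rules[name]
        pre_ids = set(placement_small.ids_of(rule.pre_type).tolist())
        post_ids = set(placement_small.ids_of(rule.post_type).tolist())
        assert set(edges[:, 0].astype(int)) <= pre_ids, name
        assert set(edges[:, 1].astype(int)) <= post_ids, name
        # no duplicate (pre, post) pairs
        pairs = edges[:, :2].astype(np.int64)
        assert len(np.unique(pairs, axis=0)) == len(pairs), name


def test_connectome_distances_consistent(placement_small, connectome_small):
    for name, edges in connectome_small.edges.items():
        if not len(edges):
            continue
        pre = edges[:, 0].astype(np.int64)
        post = edges[:, 1].astype(np.int64)
        d = np.linalg.norm(placement_small.xyz[pre] - placement_small.xyz[post],
                           axis=1)
        assert np.allclose(edges[:, 2], d, atol=1e-6), name


def test_connectome_deterministic(cfg_tiny, placement_tiny):
    a = C.build_connectome(placement_tiny, cfg_tiny, seed=5)
    b = C.build_connectome(placement_tiny, cfg_tiny, seed=5)
    for name in a.edges:
        assert np.array_equal(a[name], b[name]), name


def test_empty_placement_gives_empty_connectome(cfg):
    tab = make_table(cfg)
    conn = C.build_connectome(tab, cfg, seed=0)
    assert conn.n_edges() == 0


# ------------------------------------------------------------ ratio report

def test_ratio_report_regression(cfg_small, placement_small, connectome_small):
    rep = C.ratio_report(connectome_small, placement_small, cfg_small.rules)
    assert not rep.degenerate
    assert rep.r2 >= 0.95
    assert 0.85 <= rep.slope <= 1.1
    mean, _, target = rep.convergence["glomerulus_to_granule"]
    assert mean == pytest.approx(target, rel=0.1)


def test_ratio_report_degenerate_single_target(cfg, rng):
    tab = make_table(cfg,
                     Glom=rng.uniform(20, 80, (30, 3)) * [1, 0.5, 1],
                     GrC=rng.uniform(20, 80, (10, 3)) * [1, 0.5, 1])
    rule = cfg.rules["glomerulus_to_granule"]
    pre, post = C.geometric_candidates(rule, tab, cfg)
    pre, post = C.prune_candidates(pre, post, rule, tab, rng)
    conn = C.Connectome(edges={"glomerulus_to_granule": np.column_stack(
        [pre.astype(float), post.astype(float), np.zeros(len(pre))])})
    rep = C.ratio_report(conn, tab, {"glomerulus_to_granule": rule})
    assert rep.degenerate
    assert rep.slope is None


# ------------------------------------------------------ orthogonal plexus

def test_orthogonal_plexus_swaps_axon_fields(cfg):
    rules = C.orthogonal_plexus_rules(cfg)
    sc0 = cfg.rules["stellate_to_purkinje"].geometry
    bc0 = cfg.rules["basket_to_purkinje"].geometry
    assert rules["stellate_to_purkinje"].geometry["axon_halfwidth_x"] == \
        bc0["axon_halfwidth_x"]
    assert rules["basket_to_purkinje"].geometry["axon_halfwidth_z"] == \
        sc0["axon_halfwidth_z"]
    # original config untouched
    assert cfg.rules["stellate_to_purkinje"].geometry == sc0
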