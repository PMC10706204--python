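"""Multiscale dilation-graph features against brute-force oracles.

The oracle rasterizes each region's dilation explicitly (union of disk
offsets around every region pixel on a padded canvas) and tests pairwise
pixel overlap; graph descriptors are recomputed with plain adjacency lists
and BFS, independent of networkx and of the package's distance-transform
shortcut.
"""

import numpy as np
import pytest

from cfsgrade.stain_segmenter import StainMap
from cfsgrade.topo_features import (
    ScaleSet,
    build_graph_at_scale,
    graph_features,
    topo_block,
    topo_feature_names,
)
from conftest import stain_map_from_points

# ---------------------------------------------------------------------------
# brute-force oracles


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr**2 + dc**2 <= radius**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def oracle_edges(stains: StainMap, radius: int) -> set:
    """Explicit dilation-overlap test on padded canvases."""
    pad = int(np.ceil(radius)) + 1
    H, W = stains.labels.shape
    offs = _disk_offsets(radius)
    canvases = []
    n = stains.n_regions
    for lab in range(1, n + 1):
        pix = np.argwhere(stains.labels == lab)
        canvas = np.zeros((H + 2 * pad, W + 2 * pad), bool)
        pts = (pix[:, None, :] + offs[None, :, :]).reshape(-1, 2) + pad
        canvas[pts[:, 0], pts[:, 1]] = True
        canvases.append(canvas)
    edges = set()
    for u in range(n):
        for v in range(u + 1, n):
            if (canvases[u] & canvases[v]).any():
                edges.add((u, v))
    return edges


def oracle_graph_features(n: int, edges) -> np.ndarray:
    """The 8 descriptors from adjacency lists and BFS only."""
    if n == 0:
        return np.zeros(8)
    adj = {v: set() for v in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    # connected components by BFS
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, queue = {s}, [s]
        while queue:
            x = queue.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        comps.append(comp)

    def bfs_dists(s):
        d = {s: 0}
        queue = [s]
        while queue:
            x = queue.pop(0)
            for y in adj[x]:
                if y not in d:
                    d[y] = d[x] + 1
                    queue.append(y)
        return d

    ecc = {v: max(bfs_dists(v).values()) for v in range(n)}
    deg = np.array([len(adj[v]) for v in range(n)], float)

    clus = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            clus.append(0.0)
            continue
        links = sum(1 for a in adj[v] for b in adj[v] if a < b and b in adj[a])
        clus.append(2.0 * links / (k * (k - 1)))

    return np.array(
        [
            len(comps),
            deg.mean(),
            deg.max(),
            np.mean([ecc[v] for v in range(n)]),
            max(ecc.values()),
            np.mean(clus),
            max(len(c) for c in comps) / n,
            (deg == 0).mean(),
        ]
    )


# ---------------------------------------------------------------------------
# tests


def test_edge_present_iff_dilations_touch():
    stains = stain_map_from_points([(30, 30), (30, 40)], blob_radius=0)
    assert build_graph_at_scale(stains, 8) == {(0, 1)}  # 10 px apart <= 2*8
    assert build_graph_at_scale(stains, 4) == set()  # 10 > 2*4
    only_one = stain_map_from_points([(30, 30)], blob_radius=0)
    assert build_graph_at_scale(only_one, 8) == set()


def test_edge_radius_must_be_positive():
    stains = stain_map_from_points([(10, 10)])
    with pytest.raises(ValueError):
        build_graph_at_scale(stains, 0)


def test_graph_features_hand_cases():
    # path edge on 3 vertices: components=2, mean deg=2/3, eccs=(1,1,0)
    np.testing.assert_allclose(
        graph_features(3, {(0, 1)}),
        [2, 2 / 3, 1, 2 / 3, 1, 0, 2 / 3, 1 / 3],
    )
    # triangle
    np.testing.assert_allclose(graph_features(3, {(0, 1), (0, 2), (1, 2)}),
                               [1, 2, 2, 1, 1, 1, 1, 0])
    # 5 isolated vertices
    np.testing.assert_allclose(graph_features(5, set()), [5, 0, 0, 0, 0, 0, 1 / 5, 1])
    # empty graph convention
    np.testing.assert_allclose(graph_features(0, set()), np.zeros(8))


def test_topo_block_empty_map_is_all_zero():
    empty = StainMap.from_mask(np.zeros((50, 80), bool))
    block = topo_block(empty)
    assert len(block) == 128
    assert all(v == 0.0 for v in block.values())


def test_topo_block_names_and_table_anchors():
    names = topo_feature_names()
    assert len(names) == 128
    block = topo_block(stain_map_from_points([(20, 20), (20, 60), (60, 40)]))
    # anchor names from the published top-10 list resolve to the right cells
    scales = ScaleSet().radii
    assert scales[14 - 1] == 56  # topology-14-5: diameter at scale 56
    assert scales[2 - 1] == 8  # topology-2-1: number of subgraphs at scale 8
    assert scales[5 - 1] == 20 and scales[10 - 1] == 40  # average degree scales
    assert scales[11 - 1] == 44 and scales[1 - 1] == 4
    for anchor in ("topology-2-1", "topology-5-2", "topology-10-2",
                   "topology-11-8", "topology-14-5", "topology-1-7"):
        assert anchor in block


def test_against_oracle_on_random_maps(rng):
    for _ in range(8):
        n_pts = rng.integers(2, 15)
        pts = np.column_stack(
            [rng.integers(5, 115, n_pts), rng.integers(5, 195, n_pts)]
        )
        stains = stain_map_from_points(pts, blob_radius=int(rng.integers(0, 3)))
        scales = ScaleSet(radii=(4, 8, 16, 32))
        block = topo_block(stains, scales)
        prev_edges = set()
        for k, radius in enumerate(scales.radii, start=1):
            edges = build_graph_at_scale(stains, radius)
            assert edges == oracle_edges(stains, radius)
            assert prev_edges <= edges  # monotone nesting
            prev_edges = edges
            expected = oracle_graph_features(stains.n_regions, edges)
            got = np.array([block[f"topology-{k}-{j}"] for j in range(1, 9)])
            np.testing.assert_allclose(got, expected, atol=1e-12)


def test_monotone_consequences_across_scales(rng):
    pts = np.column_stack([rng.integers(5, 115, 20), rng.integers(5, 195, 20)])
    block = topo_block(stain_map_from_points(pts))
    subgraphs = [block[f"topology-{k}-1"] for k in range(1, 17)]
    isolated = [block[f"topology-{k}-8"] for k in range(1, 17)]
    degree = [block[f"topology-{k}-2"] for k in range(1, 17)]
    giant = [block[f"topology-{k}-7"] for k in range(1, 17)]
    assert all(a >= b for a, b in zip(subgraphs, subgraphs[1:]))
    assert all(a >= b for a, b in zip(isolated, isolated[1:]))
    assert all(a <= b for a, b in zip(degree, degree[1:]))
    assert all(a <= b for a, b in zip(giant, giant[1:]))


def test_translation_invariance():
    pts = [(20, 30), (25, 60), (48, 45), (70, 100)]
    a = topo_block(stain_map_from_points(pts))
    b = topo_block(stain_map_from_points([(r + 15, c + 30) for r, c in pts]))
    for k in a:
        assert a[k] == b[k]


def test_complete_graph_at_huge_radius():
    stains = stain_map_from_points([(10, 10), (100, 180), (60, 90)])
    diag = int(np.hypot(120, 200))
    edges = build_graph_at_scale(stains, diag)
    assert edges == {(0, 1), (0, 2), (1, 2)}
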