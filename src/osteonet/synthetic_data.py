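"""Seeded generators for networks, culture images, and group data.

Every generator takes an explicit RNG seed and is fully deterministic for a
fixed spec; each emits ground truth sufficient to score the downstream
analysis without re-deriving it.

``gen_planted_graph`` emulates the structure of a curated interactome built
around seed proteins: two densely wired blocks joined only through a single
cut vertex (the planted *bottleneck*, guaranteed the strictly largest
betweenness) with one node wired to its whole block (the planted *hub*,
guaranteed the strictly largest degree).  ``gen_colony_field`` emulates
culture fields of sparse and dense colonies with controlled counts, areas,
and circularities; the preset "differentiated" condition plants the effect
seen after osteogenic induction — dense colonies smaller and more circular
than in the control condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .morphometry import DENSE, SPARSE, ColonyImage
from .network_io import InteractionNetwork, write_network
from .stats import GroupData
from .topology import betweenness_centrality

__all__ = [
    "PlantedGraphSpec",
    "ColonyFieldSpec",
    "PlacementError",
    "gen_planted_graph",
    "gen_string_tsv",
    "gen_colony_field",
    "control_field_spec",
    "differentiated_field_spec",
    "gen_group_data",
]


class PlacementError(ValueError):
    """Colonies could not be placed without overlap."""


# ---------------------------------------------------------------------------
# Planted interaction graphs


@dataclass
class PlantedGraphSpec:
    n_nodes: int = 24
    n_edges: int = 42
    n_seeds: int = 14
    score_range: tuple[float, float] = (0.9, 1.0)
    seed: int = 0


def _feasible_bounds(n: int) -> tuple[int, int]:
    a = (n - 1 + 1) // 2  # block A size (contains the hub), B gets the rest
    b = n - 1 - a
    mandatory = (a - 1) + 4 + (b - 1)
    return a, mandatory


def gen_planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[InteractionNetwork, dict]:
    """Scored simple graph with a planted hub and a planted bottleneck.

    Construction: nodes split into blocks A and B plus a bridge node X; X
    holds the only edges between the blocks (two per side), so every
    cross-block shortest path runs through it; the hub is wired to all of
    block A while extra intra-block edges are added (never raising any
    other node to the hub's degree) until ``n_edges`` is reached.  The
    result is verified — connected, hub strictly max degree, bottleneck
    strictly max betweenness — retrying with fresh draws from the same
    stream if a random extra edge spoils the betweenness ordering.

    Returns the network and a ground-truth dict with keys ``hub``,
    ``bottleneck``, and ``seeds`` (a roster of ``n_seeds`` nodes containing
    both planted roles).
    """
    n, e = spec.n_nodes, spec.n_edges
    if n < 7:
        raise ValueError("need at least 7 nodes to plant both roles")
    a_size, mandatory = _feasible_bounds(n)
    max_edges = n * (n - 1) // 2
    if not mandatory <= e <= max_edges:
        raise ValueError(
            f"n_edges={e} infeasible for n={n} (needs {mandatory}..{max_edges})"
        )
    if not 2 <= spec.n_seeds <= n:
        raise ValueError("n_seeds must be in [2, n_nodes]")
    lo, hi = spec.score_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("score_range must be within [0, 1]")

    rng = np.random.default_rng(spec.seed)
    for _attempt in range(50):
        net = _build_planted(spec, rng, a_size)
        if net is not None and _verify_planted(net):
            break
    else:
        raise RuntimeError("could not realize planted roles; relax the spec")

    ids = net.node_ids()
    hub, bottleneck = "H01", "X01"
    others = [v for v in ids if v not in (hub, bottleneck)]
    extra = rng.choice(others, size=spec.n_seeds - 2, replace=False)
    seeds = sorted([hub, bottleneck, *map(str, extra)])
    return net, {"hub": hub, "bottleneck": bottleneck, "seeds": seeds}


def _build_planted(
    spec: PlantedGraphSpec, rng: np.random.Generator, a_size: int
) -> Optional[InteractionNetwork]:
    n, e = spec.n_nodes, spec.n_edges
    hub, x = "H01", "X01"
    rest = [f"P{i:02d}" for i in range(2, n)]
    block_a = [hub] + rest[: a_size - 1]
    block_b = rest[a_size - 1 :]

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        edges.add((min(u, v), max(u, v)))

    for v in block_a[1:]:
        add(hub, v)
    # X is the sole connection between the blocks, two gateways per side
    for v in rng.choice(block_a, size=2, replace=False):
        add(x, str(v))
    for v in rng.choice(block_b, size=2, replace=False):
        add(x, str(v))
    # random spanning tree over block B
    order = list(rng.permutation(block_b))
    for i, v in enumerate(order[1:], start=1):
        add(str(v), str(order[rng.integers(0, i)]))

    hub_degree = len(block_a) - 1
    deg = {v: 0 for v in [hub, x, *rest]}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1

    pool = [
        (min(u, v), max(u, v))
        for blk in (block_a[1:], block_b)
        for i, u in enumerate(blk)
        for v in blk[i + 1 :]
    ]
    pool = [p for p in pool if p not in edges]
    rng.shuffle(pool)
    for u, v in pool:
        if len(edges) >= e:
            break
        if deg[u] + 1 < hub_degree and deg[v] + 1 < hub_degree:
            add(u, v)
            deg[u] += 1
            deg[v] += 1
    if len(edges) != e:
        return None

    net = InteractionNetwork()
    lo, hi = spec.score_range
    for u, v in sorted(edges):
        net.add_edge(u, v, float(rng.uniform(lo, hi)))
    return net


def _verify_planted(net: InteractionNetwork) -> bool:
    if not net.is_connected():
        return False
    degs = {v: net.degree(v) for v in net.node_ids()}
    top_k = max(degs, key=lambda v: (degs[v], v))
    if top_k != "H01" or sorted(degs.values())[-2] >= degs["H01"]:
        return False
    bc = betweenness_centrality(net)
    ordered = sorted(bc.items(), key=lambda kv: -kv[1])
    return ordered[0][0] == "X01" and ordered[0][1] > ordered[1][1]


def gen_string_tsv(
    spec: PlantedGraphSpec, path: str | Path
) -> tuple[Path, dict]:
    """Write a planted graph in the STRING TSV dialect; returns (path, truth)."""
    net, truth = gen_planted_graph(spec)
    return write_network(net, path), truth


# ---------------------------------------------------------------------------
# Synthetic culture fields


@dataclass
class ColonyFieldSpec:
    """Layout and rendering parameters for one synthetic culture field.

    Shapes: ``disk`` (circularity 1), ``ellipse`` (axis ratio sampled from
    ``ellipse_ratio_range``), ``blob`` (radially perturbed disk, the least
    circular family).  Sparse colonies are rendered at a moderate base
    intensity with bright resolvable nucleus dots; dense colonies as
    near-confluent bright texture — mirroring the nucleus-countability
    criterion that separates the two classes.
    """

    image_size: tuple[int, int] = (512, 512)
    n_colonies: int = 6
    cell_count_range: tuple[int, int] = (15, 60)
    sparse_fraction: float = 0.5
    shape_weights: dict = field(
        default_factory=lambda: {"disk": 0.4, "ellipse": 0.4, "blob": 0.2}
    )
    radius_range: tuple[float, float] = (18.0, 40.0)
    ellipse_ratio_range: tuple[float, float] = (1.4, 2.2)
    blob_wobble: float = 0.15
    noise_sd: float = 0.02
    background: float = 0.08
    seed: int = 0
    allow_overlap: bool = False
    field_id: str = ""


def control_field_spec(seed: int = 0, n_colonies: int = 8) -> ColonyFieldSpec:
    """Undifferentiated control: larger, more irregular dense colonies."""
    return ColonyFieldSpec(
        n_colonies=n_colonies,
        sparse_fraction=0.25,
        shape_weights={"disk": 0.1, "ellipse": 0.5, "blob": 0.4},
        radius_range=(26.0, 40.0),
        seed=seed,
        field_id=f"control_s{seed}",
    )


def differentiated_field_spec(seed: int = 0, n_colonies: int = 8) -> ColonyFieldSpec:
    """Osteogenic condition: dense colonies planted smaller and rounder."""
    return ColonyFieldSpec(
        n_colonies=n_colonies,
        sparse_fraction=0.25,
        shape_weights={"disk": 0.8, "ellipse": 0.2, "blob": 0.0},
        radius_range=(16.0, 26.0),
        ellipse_ratio_range=(1.2, 1.5),
        seed=seed,
        field_id=f"differentiated_s{seed}",
    )


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's second approximation
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _shape_outline(
    kind: str, r: float, spec: ColonyFieldSpec, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Radial outline (512 angular samples) and its ideal circularity."""
    theta = np.linspace(0.0, 2.0 * np.pi, 512, endpoint=False)
    if kind == "disk":
        radii = np.full_like(theta, r)
        ideal = 1.0
    elif kind == "ellipse":
        ratio = float(rng.uniform(*spec.ellipse_ratio_range))
        a, b = r * math.sqrt(ratio), r / math.sqrt(ratio)  # preserve area
        phi = float(rng.uniform(0, np.pi))
        radii = a * b / np.sqrt(
            (b * np.cos(theta - phi)) ** 2 + (a * np.sin(theta - phi)) ** 2
        )
        ideal = 4.0 * math.pi * (math.pi * a * b) / _ellipse_perimeter(a, b) ** 2
    elif kind == "blob":
        n_lobes = int(rng.integers(3, 7))
        phase = float(rng.uniform(0, 2 * np.pi))
        radii = r * (1.0 + spec.blob_wobble * np.sin(n_lobes * theta + phase))
        # polygon area/perimeter of the ideal outline (shoelace on dense samples)
        xs, ys = radii * np.cos(theta), radii * np.sin(theta)
        area = 0.5 * abs(
            np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
        )
        perim = np.sum(
            np.hypot(np.roll(xs, -1) - xs, np.roll(ys, -1) - ys)
        )
        ideal = 4.0 * math.pi * area / perim**2
    else:
        raise ValueError(f"unknown shape {kind!r}")
    return radii, float(ideal)


def _rasterize(
    center: tuple[float, float], radii: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    cy, cx = center
    h, w = shape
    rmax = float(radii.max())
    y0, y1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    x0, x1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    idx = (ang / (2.0 * np.pi) * len(radii)).astype(int) % len(radii)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = rr <= radii[idx]
    return mask


def gen_colony_field(spec: ColonyFieldSpec) -> tuple[ColonyImage, pd.DataFrame]:
    """Render one culture field and its ground-truth colony table.

    The truth table has one row per colony: ``colony_id``, ``cy``, ``cx``,
    ``shape``, ``area_px`` (exact rasterized area), ``ideal_circularity``
    (analytic, of the continuous outline), ``cell_count``,
    ``nuclei_countable``, and ``colony_class``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.full((h, w), spec.background)

    kinds = list(spec.shape_weights)
    probs = np.array([spec.shape_weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    placed: list[tuple[float, float, float]] = []  # cy, cx, bounding radius
    rows = []
    for cid in range(spec.n_colonies):
        kind = str(rng.choice(kinds, p=probs))
        r = float(rng.uniform(*spec.radius_range))
        radii, ideal = _shape_outline(kind, r, spec, rng)
        rmax = float(radii.max())
        for attempt in range(10_000):
            cy = float(rng.uniform(rmax + 2, h - rmax - 2))
            cx = float(rng.uniform(rmax + 2, w - rmax - 2))
            if spec.allow_overlap or all(
                math.hypot(cy - py, cx - px) > rmax + pr + 4 for py, px, pr in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place colony {cid} without overlap in 10^4 attempts"
            )
        placed.append((cy, cx, rmax))

        is_sparse = bool(rng.random() < spec.sparse_fraction)
        cell_count = int(rng.integers(*spec.cell_count_range))
        mask = _rasterize((cy, cx), radii, (h, w))

        if is_sparse:
            img[mask] = 0.60
            # resolvable nucleus dots, one per cell
            for _ in range(cell_count):
                ang = rng.uniform(0, 2 * np.pi)
                rad = math.sqrt(rng.uniform(0, 1)) * (r - 4)
                ny, nx = int(cy + rad * math.sin(ang)), int(cx + rad * math.cos(ang))
                yy, xx = np.mgrid[ny - 1 : ny + 2, nx - 1 : nx + 2]
                ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
                img[yy[ok], xx[ok]] = 0.95
        else:
            texture = rng.normal(0.82, 0.03, size=int(mask.sum()))
            img[mask] = np.clip(texture, 0.7, 0.95)

        rows.append(
            {
                "colony_id": cid,
                "cy": cy,
                "cx": cx,
                "shape": kind,
                "area_px": int(mask.sum()),
                "ideal_circularity": ideal,
                "cell_count": cell_count,
                "nuclei_countable": is_sparse,
                "colony_class": SPARSE if is_sparse else DENSE,
            }
        )

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = ColonyImage(
        pixels=np.clip(img, 0.0, 1.0),
        field_id=spec.field_id or f"field_s{spec.seed}",
    )
    return image, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group data for statistical simulations


def gen_group_data(
    means: list[float],
    sds: list[float] | float,
    n: int | list[int],
    seed: int = 0,
) -> list[GroupData]:
    """Normal draws per group, deterministic per seed."""
    k = len(means)
    if np.isscalar(sds):
        sds = [float(sds)] * k
    if np.isscalar(n):
        n = [int(n)] * k
    if len(sds) != k or len(n) != k:
        raise ValueError("means, sds, n must have matching lengths")
    rng = np.random.default_rng(seed)
    return [
        GroupData(label=f"g{i + 1}", observations=rng.normal(means[i], sds[i], n[i]))
        for i in range(k)
    ]
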