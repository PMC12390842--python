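"""Candidate-graph construction and exact ILP tracking.

Detections per frame become graph nodes scored ``1 - min_vol/volume``;
edges link detections in consecutive frames (lumen mode: maximum pairwise
overlap fraction, cell mode: mean of a normalized centroid-distance metric
and the mask IOU within the pair's joint bounding region).  An integer linear program selects the
subgraph minimizing the negated node/edge scores plus appear/disappear
penalties under parent/child degree caps.  Lumen tracking permits two
parents, so a selected node with two selected parents is a fusion event;
cell "tracklets" cap both degrees at one.

The ILP is solved exactly with HiGHS (``scipy.optimize.milp``); a
brute-force enumeration solver over all feasible edge subsets is provided
for validation on small graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

NodeKey = tuple[int, int]  # (frame, instance label)


@dataclass
class TrackingParams:
    mode: str = "lumen"  # "lumen" | "cell"
    max_dist_um: float = 1110.0
    min_vol_um3: float = 20_000.0  # node-score reference volume
    min_mask_vol_um3: float = 0.0  # cell mode: masks below this are dropped
    appear_cost: float = 0.8
    disappear_cost: float = 0.8
    max_children: int = 2
    max_parents: int = 2


def lumen_params(**overrides) -> TrackingParams:
    return replace(TrackingParams(), **overrides)


def cell_params(**overrides) -> TrackingParams:
    base = TrackingParams(
        mode="cell",
        max_dist_um=24.3,
        min_vol_um3=481.6,
        min_mask_vol_um3=1_444.0,
        max_children=1,
        max_parents=1,
    )
    return replace(base, **overrides)


@dataclass
class CandidateGraph:
    graph: nx.DiGraph
    params: TrackingParams

    @property
    def frames(self) -> list[int]:
        return sorted({f for f, _ in self.graph.nodes})


@dataclass
class TrackSolution:
    nodes: set[NodeKey]
    edges: set[tuple[NodeKey, NodeKey]]
    parents: dict[NodeKey, list[NodeKey]]
    children: dict[NodeKey, list[NodeKey]]
    appearances: set[NodeKey]
    disappearances: set[NodeKey]
    fusions: list[NodeKey]  # selected nodes with two selected parents
    objective: float
    params: TrackingParams
    first_frame: int = 0
    last_frame: int = 0

    def track_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


class InfeasibleModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# candidate graph


def _overlap_counts(a: np.ndarray, b: np.ndarray) -> dict[tuple[int, int], int]:
    m = (a > 0) & (b > 0)
    if not np.any(m):
        return {}
    pairs = a[m].astype(np.int64) * (int(b.max()) + 1) + b[m].astype(np.int64)
    uniq, counts = np.unique(pairs, return_counts=True)
    base = int(b.max()) + 1
    return {(int(p // base), int(p % base)): int(c)
            for p, c in zip(uniq, counts)}


def _pair_iou(overlaps, la, lb, vol_a_vox, vol_b_vox) -> float:
    """Positional IOU of two instance masks within their joint bounding
    region (intersection over union of voxel sets)."""
    ov = overlaps.get((la, lb), 0)
    union = vol_a_vox + vol_b_vox - ov
    return float(ov / union) if union else 0.0


def build_graph(
    instances: np.ndarray,
    spacing,
    params: TrackingParams,
) -> CandidateGraph:
    """Candidate graph from a (t, z, y, x) instance-label movie."""
    if instances.ndim != 4:
        raise ValueError("expected a (t, z, y, x) instance movie")
    spacing = np.asarray(spacing, float)
    voxel_vol = float(np.prod(spacing))
    g = nx.DiGraph()
    props_by_frame: dict[int, dict[int, object]] = {}
    nt = instances.shape[0]
    for t in range(nt):
        frame_props = {}
        for p in regionprops(instances[t].astype(int)):
            vol = p.num_pixels * voxel_vol
            if params.mode == "cell" and vol < params.min_mask_vol_um3:
                continue
            frame_props[p.label] = p
            g.add_node(
                (t, int(p.label)),
                frame=t,
                label=int(p.label),
                centroid=tuple(np.asarray(p.centroid) * spacing),
                volume_um3=vol,
                volume_vox=int(p.num_pixels),
                score=1.0 - params.min_vol_um3 / vol,
            )
        props_by_frame[t] = frame_props
    for t in range(nt - 1):
        a, b = props_by_frame[t], props_by_frame[t + 1]
        if not a or not b:
            continue
        overlaps = _overlap_counts(instances[t], instances[t + 1])
        for la, pa in a.items():
            ca = np.asarray(g.nodes[(t, la)]["centroid"])
            for lb, pb in b.items():
                cb = np.asarray(g.nodes[(t + 1, lb)]["centroid"])
                dist = float(np.linalg.norm(ca - cb))
                if dist > params.max_dist_um:
                    continue
                if params.mode == "lumen":
                    ov = overlaps.get((la, lb), 0)
                    score = max(
                        ov / pa.num_pixels, ov / pb.num_pixels
                    )
                else:
                    dist_metric = 1.0 - dist / params.max_dist_um
                    iou = _pair_iou(
                        overlaps, la, lb, pa.num_pixels, pb.num_pixels
                    )
                    score = 0.5 * (dist_metric + iou)
                if score > 0:
                    g.add_edge((t, la), (t + 1, lb), score=float(score))
    return CandidateGraph(graph=g, params=params)


# ---------------------------------------------------------------------------
# exact solver


def _solution_from_selection(
    cg: CandidateGraph,
    sel_nodes: set[NodeKey],
    sel_edges: set[tuple[NodeKey, NodeKey]],
) -> TrackSolution:
    g, params = cg.graph, cg.params
    frames = cg.frames
    first, last = frames[0], frames[-1]
    parents: dict[NodeKey, list[NodeKey]] = {n: [] for n in sel_nodes}
    children: dict[NodeKey, list[NodeKey]] = {n: [] for n in sel_nodes}
    for u, v in sel_edges:
        children[u].append(v)
        parents[v].append(u)
    appearances = {
        n for n in sel_nodes if n[0] > first and not parents[n]
    }
    disappearances = {
        n for n in sel_nodes if n[0] < last and not children[n]
    }
    fusions = sorted(n for n in sel_nodes if len(parents[n]) >= 2)
    objective = (
        -sum(g.nodes[n]["score"] for n in sel_nodes)
        - sum(g.edges[e]["score"] for e in sel_edges)
        + params.appear_cost * len(appearances)
        + params.disappear_cost * len(disappearances)
    )
    return TrackSolution(
        nodes=sel_nodes,
        edges=sel_edges,
        parents=parents,
        children=children,
        appearances=appearances,
        disappearances=disappearances,
        fusions=fusions,
        objective=float(objective),
        params=params,
        first_frame=first,
        last_frame=last,
    )


def solve(cg: CandidateGraph) -> TrackSolution:
    """Exact optimal selection of nodes and edges (HiGHS MILP).

    Minimizes ``sum(-node_score) + sum(-edge_score) + appear_cost * A +
    disappear_cost * D`` with per-node parent/child degree caps; an
    appearance is a selected node after the first frame without a selected
    in-edge, a disappearance a selected node before the last frame without a
    selected out-edge.
    """
    g, params = cg.graph, cg.params
    if g.number_of_nodes() == 0:
        raise ValueError("empty candidate graph")
    nodes = sorted(g.nodes)
    edges = sorted(g.edges)
    frames = cg.frames
    first, last = frames[0], frames[-1]
    n_idx = {n: i for i, n in enumerate(nodes)}
    nn, ne = len(nodes), len(edges)
    appear_nodes = [n for n in nodes if n[0] > first]
    disappear_nodes = [n for n in nodes if n[0] < last]
    a_idx = {n: nn + ne + i for i, n in enumerate(appear_nodes)}
    d_idx = {n: nn + ne + len(appear_nodes) + i
             for i, n in enumerate(disappear_nodes)}
    nvar = nn + ne + len(appear_nodes) + len(disappear_nodes)

    c = np.zeros(nvar)
    for n in nodes:
        c[n_idx[n]] = -g.nodes[n]["score"]
    for k, e in enumerate(edges):
        c[nn + k] = -g.edges[e]["score"]
    for n in appear_nodes:
        c[a_idx[n]] = params.appear_cost
    for n in disappear_nodes:
        c[d_idx[n]] = params.disappear_cost

    rows: list[dict[int, float]] = []
    in_edges: dict[NodeKey, list[int]] = {n: [] for n in nodes}
    out_edges: dict[NodeKey, list[int]] = {n: [] for n in nodes}
    for k, (u, v) in enumerate(edges):
        out_edges[u].append(nn + k)
        in_edges[v].append(nn + k)
    for n in nodes:
        if in_edges[n]:  # indegree cap (also: edge implies target node)
            row = {j: 1.0 for j in in_edges[n]}
            row[n_idx[n]] = -float(params.max_parents)
            rows.append(row)
        if out_edges[n]:  # outdegree cap (also: edge implies source node)
            row = {j: 1.0 for j in out_edges[n]}
            row[n_idx[n]] = -float(params.max_children)
            rows.append(row)
    for n in appear_nodes:  # x_v - sum(in) - a_v <= 0
        row = {n_idx[n]: 1.0, a_idx[n]: -1.0}
        for j in in_edges[n]:
            row[j] = row.get(j, 0.0) - 1.0
        rows.append(row)
    for n in disappear_nodes:  # x_v - sum(out) - d_v <= 0
        row = {n_idx[n]: 1.0, d_idx[n]: -1.0}
        for j in out_edges[n]:
            row[j] = row.get(j, 0.0) - 1.0
        rows.append(row)

    A = lil_matrix((len(rows), nvar))
    for r, row in enumerate(rows):
        for j, val in row.items():
            A[r, j] = val
    constraints = LinearConstraint(
        A.tocsr(), -np.inf, np.zeros(len(rows))
    )
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(nvar),
        bounds=(0, 1),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleModelError(
            f"MILP failed (status {res.status}: {res.message}); "
            f"{nn} nodes, {ne} edges"
        )
    x = res.x
    sel_nodes = {n for n in nodes if x[n_idx[n]] >= 0.5}
    sel_edges = {
        e for k, e in enumerate(edges) if x[nn + k] >= 0.5
    }
    return _solution_from_selection(cg, sel_nodes, sel_edges)


def audit_solution(sol: TrackSolution) -> None:
    """Assert structural consistency: endpoints selected, degree caps held."""
    for u, v in sol.edges:
        assert u in sol.nodes and v in sol.nodes, "edge without endpoints"
        assert v[0] == u[0] + 1, "edge not between consecutive frames"
    for n in sol.nodes:
        assert len(sol.parents[n]) <= sol.params.max_parents
        assert len(sol.children[n]) <= sol.params.max_children


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_solve(cg: CandidateGraph, max_edges: int = 16) -> TrackSolution:
    """Exhaustive enumeration over all feasible edge subsets.

    For every edge subset satisfying the degree caps, selected nodes are the
    edge endpoints plus any isolated node whose standalone contribution
    (negated score plus boundary-aware appear/disappear costs) is negative.
    Exact but exponential; intended for validating :func:`solve` on small
    graphs.
    """
    g, params = cg.graph, cg.params
    nodes = sorted(g.nodes)
    edges = sorted(g.edges)
    if len(edges) > max_edges:
        raise ValueError(f"too many edges for enumeration ({len(edges)})")
    frames = cg.frames
    first, last = frames[0], frames[-1]
    nn, ne = len(nodes), len(edges)
    n_idx = {n: i for i, n in enumerate(nodes)}
    w_edge = np.array([g.edges[e]["score"] for e in edges])
    score = np.array([g.nodes[n]["score"] for n in nodes])
    can_appear = np.array([n[0] > first for n in nodes])
    can_disappear = np.array([n[0] < last for n in nodes])
    iso_cost = (
        -score
        + params.appear_cost * can_appear
        + params.disappear_cost * can_disappear
    )
    iso_min = np.minimum(iso_cost, 0.0)

    In = np.zeros((ne, nn))
    Out = np.zeros((ne, nn))
    for k, (u, v) in enumerate(edges):
        Out[k, n_idx[u]] = 1
        In[k, n_idx[v]] = 1

    n_sub = 1 << ne
    member = (
        (np.arange(n_sub)[:, None] >> np.arange(ne)[None, :]) & 1
    ).astype(float)
    indeg = member @ In
    outdeg = member @ Out
    feasible = np.all(indeg <= params.max_parents, axis=1) & np.all(
        outdeg <= params.max_children, axis=1
    )
    selected = (indeg + outdeg) > 0
    obj = -(member @ w_edge)
    obj += selected @ (-score)
    obj += params.appear_cost * np.sum(
        selected & (indeg == 0) & can_appear[None, :], axis=1
    )
    obj += params.disappear_cost * np.sum(
        selected & (outdeg == 0) & can_disappear[None, :], axis=1
    )
    obj += (~selected) @ iso_min
    obj[~feasible] = np.inf
    best = int(np.argmin(obj))
    sel_edges = {edges[k] for k in range(ne) if member[best, k] > 0}
    sel_nodes = {
        nodes[i]
        for i in range(nn)
        if selected[best, i] or (not selected[best, i] and iso_cost[i] < 0)
    }
    return _solution_from_selection(cg, sel_nodes, sel_edges)


def random_candidate_graph(
    rng: np.random.Generator,
    max_nodes: int = 12,
    max_frames: int = 4,
    max_edges: int = 12,
) -> CandidateGraph:
    """Random small candidate graph for oracle-equivalence checks."""
    for _ in range(100):
        n_frames = int(rng.integers(2, max_frames + 1))
        sizes = rng.integers(1, 4, n_frames)
        while sizes.sum() > max_nodes:
            sizes[rng.integers(n_frames)] = max(
                1, sizes[rng.integers(n_frames)] - 1
            )
        params = TrackingParams(
            mode="lumen",
            max_dist_um=np.inf,
            min_vol_um3=1.0,
            appear_cost=float(rng.uniform(0.1, 1.2)),
            disappear_cost=float(rng.uniform(0.1, 1.2)),
            max_children=int(rng.integers(1, 3)),
            max_parents=int(rng.integers(1, 3)),
        )
        g = nx.DiGraph()
        for t in range(n_frames):
            for i in range(sizes[t]):
                g.add_node(
                    (t, i + 1),
                    frame=t,
                    label=i + 1,
                    centroid=(0.0, 0.0, 0.0),
                    volume_um3=1.0,
                    score=float(rng.uniform(-0.5, 1.0)),
                )
        for t in range(n_frames - 1):
            for i in range(sizes[t]):
                for j in range(sizes[t + 1]):
                    if rng.random() < 0.6:
                        g.add_edge(
                            (t, i + 1),
                            (t + 1, j + 1),
                            score=float(rng.uniform(0.05, 1.0)),
                        )
        if g.number_of_edges() <= max_edges:
            return CandidateGraph(graph=g, params=params)
    raise RuntimeError("failed to sample a small random graph")


# ---------------------------------------------------------------------------
# fusion extraction and tracklets


def extract_fusions(
    sol: TrackSolution,
    frame_interval: float,
    rolling_window: int = 10,
    max_path_frames: int = 10,
):
    """Fusion table, smoothed per-frame counts, and hours-since-fusion.

    Returns ``(fusion_table, counts_table, hours_since)`` where
    ``counts_table`` has raw and rolling-mean (window ``rolling_window``,
    min periods 1) fusion counts per frame, and ``hours_since`` maps each
    selected node to the time since the nearest fusion event within
    ``max_path_frames`` frames along the track graph (NaN beyond).
    """
    fusion_rows = [
        {
            "frame": n[0],
            "lumen_id": n[1],
            "parent_ids": tuple(p[1] for p in sorted(sol.parents[n])),
            "time_h": n[0] * frame_interval,
        }
        for n in sol.fusions
    ]
    fusion_table = pd.DataFrame(
        fusion_rows, columns=["frame", "lumen_id", "parent_ids", "time_h"]
    )
    frames = range(sol.first_frame, sol.last_frame + 1)
    counts = pd.Series(
        [sum(1 for n in sol.fusions if n[0] == t) for t in frames],
        index=list(frames),
        name="fusions",
    )
    counts_table = pd.DataFrame(
        {
            "frame": counts.index,
            "fusions": counts.to_numpy(),
            "fusions_smoothed": counts.rolling(
                rolling_window, min_periods=1
            ).mean().to_numpy(),
        }
    )
    hours_since: dict[NodeKey, float] = {}
    tg = sol.track_graph().to_undirected()
    dist: dict[NodeKey, int] = {}
    for f in sol.fusions:
        for node, d in nx.single_source_shortest_path_length(
            tg, f, cutoff=max_path_frames
        ).items():
            if node not in dist or d < dist[node]:
                dist[node] = d
    for n in sol.nodes:
        hours_since[n] = (
            dist[n] * frame_interval if n in dist else float("nan")
        )
    return fusion_table, counts_table, hours_since


def track_lumens(
    lumen_instances: np.ndarray, spacing, params: TrackingParams | None = None
) -> TrackSolution:
    cg = build_graph(lumen_instances, spacing, params or lumen_params())
    return solve(cg)


def build_tracklets(
    cell_instances: np.ndarray, spacing, params: TrackingParams | None = None
) -> TrackSolution:
    """Cell tracking with divisions/fusions disallowed (1 parent, 1 child)."""
    params = params or cell_params()
    if params.max_children != 1 or params.max_parents != 1:
        raise ValueError("tracklets require max 1 parent and 1 child")
    cg = build_graph(cell_instances, spacing, params)
    return solve(cg)


def solution_to_tracks(
    sol: TrackSolution, graph: CandidateGraph, frame_interval: float = 1.0
) -> pd.DataFrame:
    """Flatten a solution into a track table (track_id, frame, centroid um).

    Track identity propagates along selected edges; at a fusion the first
    parent's identity survives.
    """
    g = graph.graph
    track_of: dict[NodeKey, int] = {}
    next_track = 1
    for n in sorted(sol.nodes):
        pars = sorted(sol.parents[n])
        if pars and pars[0] in track_of:
            track_of[n] = track_of[pars[0]]
        else:
            track_of[n] = next_track
            next_track += 1
    rows = []
    for n in sorted(sol.nodes):
        cz, cy, cx = g.nodes[n]["centroid"]
        rows.append(
            {
                "track_id": track_of[n],
                "frame": n[0],
                "time_h": n[0] * frame_interval,
                "label": n[1],
                "z": cz,
                "y": cy,
                "x": cx,
                "volume_um3": g.nodes[n]["volume_um3"],
            }
        )
    return pd.DataFrame(rows)
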