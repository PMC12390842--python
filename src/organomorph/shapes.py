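"""Ellipsoid fits, organoid surface meshes, alignment index, morphotype
clustering and Shannon-diversity statistics.

The alignment index of a cell is the absolute cosine of the angle between
the major axis of an ellipsoid fitted to the cell's surface and the outward
normal of the organoid surface at the mesh vertex nearest to the cell
centroid: 1 = radially oriented (perpendicular to the surface), 0 =
tangential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

logger = logging.getLogger(__name__)

#: fits with any radius above this bound (in point-cloud units) are invalid
MAX_FIT_RADIUS = 180.0
#: cells rounder than this are orientation-degenerate
DEGENERATE_AXIS_RATIO = 0.9


@dataclass
class EllipsoidFit:
    centre: np.ndarray
    radii: np.ndarray  # descending
    axes: np.ndarray  # rows: principal directions matching ``radii``
    valid: bool

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def axis_ratio(self) -> float:
        return float(self.radii[-1] / self.radii[0])


def _invalid_fit() -> EllipsoidFit:
    return EllipsoidFit(
        centre=np.full(3, np.nan),
        radii=np.full(3, np.nan),
        axes=np.full((3, 3), np.nan),
        valid=False,
    )


def fit_ellipsoid(
    points: np.ndarray, max_radius: float = MAX_FIT_RADIUS
) -> EllipsoidFit:
    """Algebraic least-squares ellipsoid fit to surface points.

    Fits the general quadric ``x'Ax + 2b'x = 1``; the centre is
    ``-A^{-1}b`` and radii/principal axes come from the eigen-decomposition
    of the recentred quadric.  Returns ``valid=False`` (never raises) for
    fewer than 10 points, coplanar points, non-real/negative radii, or any
    radius above ``max_radius``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 10:
        return _invalid_fit()
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 3:
        return _invalid_fit()
    z, y, x = pts[:, 0], pts[:, 1], pts[:, 2]
    D = np.column_stack(
        [z * z, y * y, x * x, 2 * z * y, 2 * z * x, 2 * y * x, 2 * z, 2 * y,
         2 * x]
    )
    try:
        v, *_ = np.linalg.lstsq(D, np.ones(len(pts)), rcond=None)
        A3 = np.array(
            [[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]]
        )
        b = v[6:9]
        centre = -np.linalg.solve(A3, b)
        gamma = 1.0 + b @ np.linalg.solve(A3, b)
        evals, evecs = np.linalg.eigh(A3 / gamma)
    except np.linalg.LinAlgError:
        return _invalid_fit()
    if np.any(evals <= 0) or not np.all(np.isfinite(evals)):
        return _invalid_fit()
    radii = 1.0 / np.sqrt(evals)
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    axes = evecs.T[order]
    if np.any(radii > max_radius):
        return _invalid_fit()
    return EllipsoidFit(centre=centre, radii=radii, axes=axes, valid=True)


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # physical coordinates (z,y,x um)
    faces: np.ndarray
    normals: np.ndarray  # per-vertex outward unit normals

    def nearest_normal(self, point: np.ndarray):
        tree = cKDTree(self.vertices)
        _, idx = tree.query(point)
        return self.normals[idx]


def organoid_mesh(
    mask: np.ndarray,
    spacing,
    step_size: int = 4,
    taubin_iterations: int = 50,
) -> SurfaceMesh:
    """Smoothed organoid surface mesh with outward per-vertex normals.

    Marching cubes at a coarse step, trimesh-based cleaning and outward
    normal repair, then Taubin smoothing.
    """
    import trimesh
    import trimesh.repair
    import trimesh.smoothing

    if not np.any(mask):
        raise ValueError("empty organoid mask")
    verts, faces, _, _ = marching_cubes(
        np.pad(np.asarray(mask, dtype=np.uint8), 1),
        level=0.5,
        spacing=tuple(float(s) for s in spacing),
        step_size=step_size,
    )
    verts = verts - np.asarray(spacing, float)  # undo the 1-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    trimesh.smoothing.filter_taubin(mesh, iterations=taubin_iterations)
    normals = np.array(mesh.vertex_normals, dtype=float)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfaceMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces),
        normals=normals,
    )


def alignment_index(
    fit: EllipsoidFit, mesh: SurfaceMesh, centroid: np.ndarray
) -> float:
    """|cos| between the fit's major axis and the nearest surface normal."""
    if not fit.valid:
        raise ValueError("alignment index undefined for an invalid fit")
    normal = mesh.nearest_normal(np.asarray(centroid, float))
    major = fit.major_axis / np.linalg.norm(fit.major_axis)
    return float(abs(major @ normal))


def cell_surface_points(mask: np.ndarray, spacing, step_size: int = 2):
    """Marching-cubes surface point cloud of one cell mask (physical um)."""
    try:
        verts, _, _, _ = marching_cubes(
            np.pad(np.asarray(mask, dtype=np.uint8), 1),
            level=0.5,
            spacing=tuple(float(s) for s in spacing),
            step_size=step_size,
        )
    except (ValueError, RuntimeError):
        return np.empty((0, 3))
    return verts - np.asarray(spacing, float)


def cell_alignment_table(
    cell_instances: np.ndarray,
    organoid_mask: np.ndarray,
    spacing,
    mesh_step: int = 4,
    cell_step: int = 2,
    max_radius_um: float | None = None,
    degenerate_ratio: float = DEGENERATE_AXIS_RATIO,
) -> pd.DataFrame:
    """Per-cell ellipsoid fit and alignment index against the organoid mesh.

    Cells with invalid fits are kept with ``valid=False``; near-spherical
    cells (fit axis ratio above ``degenerate_ratio``) are flagged
    orientation-degenerate and get no index.
    """
    from skimage.measure import regionprops

    mesh = organoid_mesh(organoid_mask, spacing, step_size=mesh_step)
    tree = cKDTree(mesh.vertices)
    if max_radius_um is None:
        max_radius_um = MAX_FIT_RADIUS * float(min(spacing))
    rows = []
    for p in regionprops(cell_instances.astype(int)):
        sub = np.zeros_like(cell_instances, dtype=bool)
        z0, y0, x0, z1, y1, x1 = p.bbox
        sub = cell_instances[z0:z1, y0:y1, x0:x1] == p.label
        pts = cell_surface_points(sub, spacing, step_size=cell_step)
        offset = np.array([z0, y0, x0]) * np.asarray(spacing, float)
        fit = fit_ellipsoid(
            pts + offset if len(pts) else pts, max_radius=max_radius_um
        )
        row = {
            "structure_id": int(p.label),
            "valid": fit.valid,
            "fit_axis_ratio": fit.axis_ratio if fit.valid else np.nan,
            "degenerate": False,
            "alignment_index": np.nan,
        }
        if fit.valid:
            if fit.axis_ratio > degenerate_ratio:
                row["degenerate"] = True
            else:
                centroid = np.asarray(p.centroid) * np.asarray(spacing, float)
                _, idx = tree.query(centroid)
                major = fit.major_axis / np.linalg.norm(fit.major_axis)
                row["alignment_index"] = float(abs(major @ mesh.normals[idx]))
        rows.append(row)
    table = pd.DataFrame(rows)
    n_bad = int((~table["valid"]).sum()) if len(table) else 0
    if n_bad:
        logger.info("alignment: %d invalid ellipsoid fits excluded", n_bad)
    return table


# ---------------------------------------------------------------------------
# morphotype clustering


#: feature columns never used for clustering (identifiers, intensity, position)
_NON_CLUSTER = (
    "structure_id", "frame", "channel", "label", "predicted_label",
    "qc_pass", "condition", "day",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
)


@dataclass
class MorphotypeAssignment:
    table: pd.DataFrame  # input rows + "cluster" column
    embedding: np.ndarray | None
    cluster_graph: nx.Graph

    @property
    def clusters(self) -> np.ndarray:
        return self.table["cluster"].to_numpy()


def morphotype_feature_columns(table: pd.DataFrame) -> list[str]:
    """Non-intensity morphometrics plus the axis-length ratio."""
    cols = [
        c
        for c in table.columns
        if c not in _NON_CLUSTER
        and not c.startswith("intensity")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    return cols


def cluster_morphotypes(
    table: pd.DataFrame,
    n_pcs: int = 5,
    resolution: float = 0.6,
    seed: int = 0,
    n_neighbors: int = 15,
    paga_threshold: float = 0.1,
    embed: bool = False,
) -> MorphotypeAssignment:
    """Leiden morphotype clustering on PCA of standardized shape features.

    z-score -> PCA (``n_pcs``) -> kNN graph -> Leiden at ``resolution`` ->
    PAGA cluster graph with connectivities below ``paga_threshold`` pruned;
    optionally a seeded, graph-initialized 2D UMAP embedding.
    """
    import anndata as ad
    import scanpy as sc

    cols = morphotype_feature_columns(table)
    if len(table) <= n_pcs:
        raise ValueError("fewer structures than principal components")
    X = table[cols].to_numpy(dtype=float)
    adata = ad.AnnData(X)
    sc.pp.scale(adata)
    sc.tl.pca(adata, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(
        adata, n_neighbors=min(n_neighbors, len(table) - 1), n_pcs=n_pcs,
        random_state=seed,
    )
    sc.tl.leiden(
        adata, resolution=resolution, random_state=seed, flavor="leidenalg"
    )
    adata.obs["leiden"] = adata.obs["leiden"].astype(str)
    groups = sorted(adata.obs["leiden"].unique(), key=int)
    graph = nx.Graph()
    graph.add_nodes_from(int(g) for g in groups)
    if len(groups) > 1:
        from scipy import sparse

        try:
            sc.tl.paga(adata, groups="leiden")
            conn_mat = adata.uns["paga"]["connectivities"]
        except ValueError:
            # fully disconnected cluster graph (no inter-cluster edges)
            conn_mat = sparse.csr_matrix((len(groups), len(groups)))
        conn = np.asarray(conn_mat.todense())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if conn[i, j] >= paga_threshold:
                    graph.add_edge(
                        int(groups[i]), int(groups[j]),
                        weight=float(conn[i, j]),
                    )
    embedding = None
    if embed:
        try:
            sc.pl.paga(adata, plot=False, random_state=seed)
            sc.tl.umap(adata, init_pos="paga", random_state=seed)
        except Exception:  # pragma: no cover - fallback init
            sc.tl.umap(adata, random_state=seed)
        embedding = np.asarray(adata.obsm["X_umap"])
    out = table.copy()
    out["cluster"] = adata.obs["leiden"].astype(int).to_numpy()
    return MorphotypeAssignment(
        table=out, embedding=embedding, cluster_graph=graph
    )


def cluster_distance_from(graph: nx.Graph, root: int) -> dict[int, float]:
    """Shortest-path distances over the pruned cluster graph (ordering aid)."""
    return dict(nx.single_source_shortest_path_length(graph, root))


# ---------------------------------------------------------------------------
# Shannon diversity


def shannon_index(counts) -> float:
    """H' = -sum_i p_i log2 p_i over cluster counts, with 0*log(0) = 0."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.sum() <= 0:
        raise ValueError("Shannon index undefined for all-zero counts")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cluster_proportions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per condition-day proportions of each cluster (rows sum to 1)."""
    if assignments.empty:
        raise ValueError("empty assignments")
    counts = (
        assignments.groupby(["condition", "day", "cluster"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def bootstrap_shannon(
    assignments: pd.DataFrame, B: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Stratified bootstrap of the Shannon index per condition-day.

    Structures are resampled with replacement within each condition-day
    stratum; 95% percentile confidence intervals.  Strata with fewer than
    two structures are flagged with undefined CIs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (cond, day), grp in assignments.groupby(
        ["condition", "day"], observed=True
    ):
        clusters = grp["cluster"].to_numpy()
        h = shannon_index(np.bincount(pd.factorize(clusters)[0]))
        if len(clusters) < 2:
            rows.append(
                {"condition": cond, "day": day, "shannon": h,
                 "ci_low": np.nan, "ci_high": np.nan, "n": len(clusters),
                 "ci_defined": False}
            )
            continue
        codes = pd.factorize(clusters)[0]
        n_codes = codes.max() + 1
        hs = np.empty(B)
        for b in range(B):
            resampled = rng.integers(0, len(codes), len(codes))
            hs[b] = shannon_index(np.bincount(codes[resampled],
                                              minlength=n_codes))
        lo, hi = np.percentile(hs, [2.5, 97.5])
        rows.append(
            {"condition": cond, "day": day, "shannon": h,
             "ci_low": float(lo), "ci_high": float(hi), "n": len(clusters),
             "ci_defined": True}
        )
    return pd.DataFrame(rows)
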