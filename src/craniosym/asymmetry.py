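"""Left-right asymmetry scoring, head metrics and heat-map export.

Asymmetry is quantified on the dense template correspondence: for each
off-midline mirror pair of template vertices, the matched subject-surface
points are compared through their distances from the canonical origin, and
the absolute difference of the two distances is the pair's asymmetry (mm).
The whole-head mean is AH; the mean over the facial region (vertices nearer
the pronasale than the gnathion) is AF.  Head metrics are the height H
(vertex minus gnathion), anteroposterior length L and width W (mesh
extents) and the enclosed volume V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _trigeom
from .errors import MeshError
from .io import HeadMesh, LandmarkSet
from .template import CorrespondenceMap, SymmetricTemplate

__all__ = [
    "RegionMask",
    "PairwiseAsymmetry",
    "HeadMetrics",
    "AsymmetryResult",
    "layer_landmarks",
    "facial_region",
    "pointwise_asymmetry",
    "summarize",
    "head_metrics",
    "export_heatmap",
    "HEAT_SCALE_MM",
]

#: Fixed heat-map colour scale (mm), comparable across subjects and groups.
HEAT_SCALE_MM = (0.0, 5.0)


@dataclass
class RegionMask:
    """Per template-vertex facial membership; the complement is the skull."""

    in_face: np.ndarray  # (n,) bool

    @property
    def in_skull(self) -> np.ndarray:
        return ~self.in_face


@dataclass
class PairwiseAsymmetry:
    """Asymmetry per off-midline mirror pair of template vertices."""

    rep: np.ndarray  # (k,) representative vertex index (x > 0)
    partner: np.ndarray  # (k,) mirrored vertex index
    values: np.ndarray  # (k,) mm, non-negative


@dataclass
class HeadMetrics:
    H: float  # vertex-to-gnathion height, mm
    L: float  # anteroposterior length (z extent), mm
    W: float  # width (x extent), mm
    V: float  # enclosed volume, cm^3


@dataclass
class AsymmetryResult:
    pairs: PairwiseAsymmetry
    mask: RegionMask
    AH: float
    AF: float
    metrics: HeadMetrics | None = None

    @property
    def vertex_values(self) -> np.ndarray:
        """Per-vertex heat-map scalar (mirror pairs share, midline 0)."""
        n = len(self.mask.in_face)
        out = np.zeros(n)
        out[self.pairs.rep] = self.pairs.values
        out[self.pairs.partner] = self.pairs.values
        return out


def layer_landmarks(
    subject: HeadMesh,
    lms: LandmarkSet,
    n_layers: int = 4,
    per_layer: int = 10,
) -> LandmarkSet:
    """Construct the skull-layer landmarks by radial ray casting.

    ``n_layers`` heights are evenly spaced strictly between the otobasion-
    superius level and the vertex; at each height ``per_layer`` rays leave
    the y axis at azimuths ``360 k / per_layer`` degrees (0 = anterior,
    increasing toward the left) and the farthest surface intersection
    becomes ``Layer{i}-{k}``.  Returns a copy of ``lms`` with the
    constructed labels added.
    """
    y_obs = 0.5 * (lms["OBs-r"][1] + lms["OBs-l"][1])
    y_v = lms["V"][1]
    if not np.isfinite(y_obs) or not np.isfinite(y_v) or y_v <= y_obs:
        raise MeshError("vertical span OBs..V is not well-defined")
    tris = subject.triangles()
    out = lms.copy()
    origins = []
    dirs = []
    labels = []
    for k in range(1, n_layers + 1):
        y_k = y_obs + k / (n_layers + 1) * (y_v - y_obs)
        for j in range(per_layer):
            az = 2 * np.pi * j / per_layer
            origins.append([0.0, y_k, 0.0])
            dirs.append([np.sin(az), 0.0, np.cos(az)])
            labels.append(f"Layer{k}-{j}")
    points, hit = _trigeom.ray_triangles_farthest(
        np.array(origins), np.array(dirs), tris
    )
    for lab, p, h in zip(labels, points, hit):
        if not h:
            raise MeshError(f"layer ray {lab} does not intersect the mesh")
        out[lab] = p
    return out


def facial_region(template, prn, gn) -> RegionMask:
    """Facial mask: vertices at most as far from PRn as from Gn.

    The boundary is the perpendicular-bisector plane of the PRn-Gn segment;
    equality is counted as facial.  ``template`` may be a SymmetricTemplate
    or an (n, 3) vertex array.
    """
    if isinstance(template, SymmetricTemplate):
        v = template.mesh.vertices
    else:
        v = np.asarray(template, float)
    prn = np.asarray(prn, float)
    gn = np.asarray(gn, float)
    d_prn = np.linalg.norm(v - prn, axis=1)
    d_gn = np.linalg.norm(v - gn, axis=1)
    return RegionMask(d_prn <= d_gn)


def pointwise_asymmetry(
    corr: CorrespondenceMap,
    template: SymmetricTemplate,
    origin=(0.0, 0.0, 0.0),
    point_to_point: bool = False,
) -> PairwiseAsymmetry:
    """Per-mirror-pair asymmetry from the dense correspondence.

    Default statistic: |d_L - d_R| of the matched points' distances from the
    origin.  ``point_to_point`` instead uses the distance between the
    mirrored left match and the right match (sensitivity alternative).
    Midline vertices (self-paired) are excluded.
    """
    origin = np.asarray(origin, float)
    reps = template.left_pairs()
    partners = template.mirror[reps]
    if len(corr.points) != len(template.mesh.vertices):
        raise MeshError("correspondence does not cover every template vertex")
    p_rep = corr.points[reps]
    p_par = corr.points[partners]
    if point_to_point:
        mirrored = p_rep * np.array([-1.0, 1.0, 1.0]) + np.array(
            [2 * origin[0], 0.0, 0.0]
        )
        values = np.linalg.norm(mirrored - p_par, axis=1)
    else:
        d_rep = np.linalg.norm(p_rep - origin, axis=1)
        d_par = np.linalg.norm(p_par - origin, axis=1)
        values = np.abs(d_rep - d_par)
    return PairwiseAsymmetry(reps, partners, values)


def summarize(pairs: PairwiseAsymmetry, mask: RegionMask) -> tuple[float, float]:
    """Whole-head and facial mean asymmetry (AH, AF) in mm."""
    if len(pairs.values) == 0:
        raise MeshError("no mirror pairs to summarise")
    face = mask.in_face[pairs.rep]
    if not np.any(face):
        raise MeshError("facial mask selects no mirror pairs")
    return float(pairs.values.mean()), float(pairs.values[face].mean())


def head_metrics(subject: HeadMesh, lms: LandmarkSet) -> HeadMetrics:
    """Head height, length, width and volume in the canonical frame."""
    H = float(lms["V"][1] - lms["Gn"][1])
    L = float(subject.vertices[:, 2].max() - subject.vertices[:, 2].min())
    W = float(subject.vertices[:, 0].max() - subject.vertices[:, 0].min())
    V = subject.volume_mm3() / 1000.0  # cm^3
    return HeadMetrics(H, L, W, V)


def export_heatmap(
    template: SymmetricTemplate,
    pairs: PairwiseAsymmetry,
    path,
    scale: tuple[float, float] = HEAT_SCALE_MM,
    cmap: str = "turbo",
):
    """Write the asymmetry heat map as an ASCII PLY.

    Each vertex and its mirror partner carry the pair value as the scalar
    ``quality`` channel (midline vertices 0); colours map the fixed
    0-5 mm scale so maps are comparable across subjects.
    """
    import matplotlib

    from .io import _write_ply

    n = len(template.mesh.vertices)
    values = np.zeros(n)
    values[pairs.rep] = pairs.values
    values[pairs.partner] = pairs.values
    lo, hi = scale
    normed = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    colors = (np.asarray(matplotlib.colormaps[cmap](normed))[:, :3] * 255).astype(int)
    mesh = HeadMesh(template.mesh.vertices.copy(), template.mesh.faces.copy(), values)
    from pathlib import Path

    path = Path(path)
    _write_ply(mesh, path, colors=colors)
    return path


def render_views(mesh: HeadMesh, values: np.ndarray, out_prefix, scale=HEAT_SCALE_MM):
    """Optional PNG renders of the four canonical views.

    Facial frontal, craniofacial frontal, left and right lateral profile;
    simple orthographic scatter projections, intended for quick inspection
    rather than publication rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    views = {
        "facial_frontal": (2, 0, 1, 1.0),
        "craniofacial_frontal": (2, 0, 1, 1.0),
        "left_lateral": (0, 2, 1, 1.0),
        "right_lateral": (0, 2, 1, -1.0),
    }
    paths = []
    v = mesh.vertices
    for name, (depth, h_ax, v_ax, flip) in views.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        order = np.argsort(flip * v[:, depth])
        keep = order[len(order) // 2 :]  # front-facing half
        if name == "facial_frontal":
            keep = keep[v[keep, 1] < np.percentile(v[:, 1], 75)]
        sc = ax.scatter(
            flip * v[keep, h_ax], v[keep, v_ax], c=values[keep],
            s=4, vmin=scale[0], vmax=scale[1], cmap="turbo",
        )
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, label="asymmetry (mm)")
        p = f"{out_prefix}_{name}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
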