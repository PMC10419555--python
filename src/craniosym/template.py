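"""Symmetric craniofacial template, TPS warping and dense correspondence.

The analysis template is an analytic, exactly mirror-symmetric head
surrogate: a superellipsoid cranium blended with Gaussian nose and chin
protrusions, sampled on a pole-to-pole grid and built as a half mesh plus
its exact mirror copy so that the left-right vertex pairing is an exact
involution.  It carries anchor vertices for all 37 anatomical landmarks and
the 40 constructed skull-layer landmarks, is warped to a subject by a
3D thin-plate spline on paired landmarks, and is then projected onto the
subject surface by exact closest-point correspondence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _trigeom
from .errors import DegenerateGeometryError, MeshError
from .io import ANATOMICAL_LABELS, HeadMesh, LandmarkSet, write_mesh

__all__ = [
    "HeadShape",
    "SymmetricTemplate",
    "build_template",
    "scale_template",
    "TPSWarp",
    "fit_tps",
    "warp_points",
    "CorrespondenceMap",
    "closest_point_map",
]


@dataclass
class HeadShape:
    """Analytic star-shaped head surface: radius as a function of direction.

    ``ax/ay/az`` are the superellipsoid semi-axes (mm), ``exponent`` its
    shape exponent (2 = ellipsoid), and the nose/chin tuples are
    ``(amplitude mm, theta_sigma rad, phi_center rad, phi_sigma rad)``
    Gaussian protrusions centred on the anterior midline, even in azimuth
    so the surface is exactly mirror-symmetric.
    """

    ax: float = 80.0
    ay: float = 112.0
    az: float = 90.0
    # Exponent chosen so a generated head at the published mean H/L/W
    # encloses the published mean cranial volume (~3.54e3 cm^3); 2 would be
    # an ellipsoid (the nose/chin protrusions add a few percent).
    exponent: float = 1.90
    nose: tuple = (14.0, 0.26, np.radians(100.0), 0.16)
    chin: tuple = (8.0, 0.40, np.radians(146.0), 0.20)

    def radius(self, theta, phi):
        """Radial distance from centre along (theta, phi).

        ``phi`` is the polar angle from +y (superior), ``theta`` the azimuth
        about the y axis with 0 = +z (anterior) and positive toward +x
        (anatomical left).
        """
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        sphi = np.sin(phi)
        dx = sphi * np.sin(theta)
        dy = np.cos(phi)
        dz = sphi * np.cos(theta)
        p = self.exponent
        base = (
            np.abs(dx / self.ax) ** p
            + np.abs(dy / self.ay) ** p
            + np.abs(dz / self.az) ** p
        ) ** (-1.0 / p)
        th = np.arctan2(np.sin(theta), np.cos(theta))  # wrap to (-pi, pi]
        r = base
        for amp, sth, phc, sph in (self.nose, self.chin):
            r = r + amp * np.exp(
                -0.5 * (th / sth) ** 2 - 0.5 * ((phi - phc) / sph) ** 2
            )
        return r


@dataclass
class SymmetricTemplate:
    """Exactly mirror-symmetric head mesh with vertex pairing and anchors."""

    mesh: HeadMesh
    mirror: np.ndarray  # involutive vertex pairing m(i)
    anchors: dict[str, int] = field(default_factory=dict)
    shape: HeadShape | None = None
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def anchor_points(self, labels=None) -> LandmarkSet:
        labels = labels if labels is not None else list(self.anchors)
        lms = LandmarkSet()
        for lb in labels:
            lms[lb] = self.mesh.vertices[self.anchors[lb]]
        return lms

    def left_pairs(self) -> np.ndarray:
        """Representative (x > 0) vertex of each off-midline mirror pair."""
        idx = np.arange(len(self.mirror))
        return idx[(self.mirror != idx) & (self.mesh.vertices[:, 0] > 0)]

    def verify(self, atol: float = 0.0) -> None:
        v = self.mesh.vertices
        mir = v[self.mirror] * np.array([-1.0, 1.0, 1.0])
        if not np.allclose(v, mir, atol=atol):
            raise MeshError("mirror pairing is not an exact reflection")
        if not np.array_equal(self.mirror[self.mirror], np.arange(len(v))):
            raise MeshError("mirror pairing is not involutive")

    def save(self, mesh_path, sidecar_path=None) -> None:
        """PLY plus JSON sidecar (mirror pairing and anchors)."""
        mesh_path = Path(mesh_path)
        write_mesh(self.mesh, mesh_path)
        sidecar = Path(sidecar_path) if sidecar_path else mesh_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "mirror": self.mirror.tolist(),
                    "anchors": {k: int(v) for k, v in self.anchors.items()},
                },
            )
        )


# Nominal anchor directions (theta deg, phi deg); theta 0 = anterior,
# positive toward the anatomical left; phi from the vertex (+y) pole.
# Right-side members of bilateral pairs use negative theta; the left member
# is the exact mirror vertex.
_MIDLINE_ANGLES = {
    "V": (0.0, 0.0),
    "G": (0.0, 76.0),
    "N": (0.0, 86.0),
    "PRn": (0.0, 100.0),
    "C": (0.0, 105.0),
    "Sn": (0.0, 109.0),
    "Ls": (0.0, 116.0),
    "Sto": (0.0, 121.0),
    "Li": (0.0, 126.0),
    "B": (0.0, 132.0),
    "Pg": (0.0, 139.0),
    "Gn": (0.0, 148.0),
    "Cer": (0.0, 163.0),
    "Op": (180.0, 111.0),  # same height band as PRn: PRn-Op is the horizontal
    "O": (180.0, 70.0),
}
_RIGHT_ANGLES = {
    "Ala-r": (-9.0, 104.0),
    "Nb-r": (-5.0, 107.0),
    "As-r": (-10.0, 99.0),
    "En-r": (-13.0, 88.0),
    "Ex-r": (-33.0, 88.0),
    "Cph-r": (-4.0, 115.0),
    "Ch-r": (-17.0, 121.0),
    "Go-r": (-48.0, 133.0),
    "OBs-r": (-80.0, 80.0),
    "OBi-r": (-84.0, 97.0),
    "L-r": (-86.0, 103.0),
}


def _vertex_index(i_ring: int, j: int, m: int, nv: int) -> int:
    """Grid vertex index; ring 0 is the top pole, ring nv the bottom pole."""
    if i_ring == 0:
        return 0
    if i_ring == nv:
        return 1 + (nv - 1) * m
    return 1 + (i_ring - 1) * m + (j % m)


def build_template(
    radial_resolution: int = 48,
    vertical_resolution: int = 32,
    shape: HeadShape | None = None,
) -> SymmetricTemplate:
    """Construct the symmetric head template.

    ``radial_resolution`` is the azimuthal vertex count per ring (forced
    even so both midline columns exist); ``vertical_resolution`` the number
    of polar bands.  Anchors for all 77 labels are snapped to distinct grid
    vertices; too coarse a grid to separate them is an error.
    """
    m = int(radial_resolution)
    nv = int(vertical_resolution)
    if m < 8 or nv < 8:
        raise MeshError("template resolutions must be at least 8")
    if m % 2:
        m += 1
    shape = shape or HeadShape()

    n_vert = 2 + (nv - 1) * m
    vertices = np.zeros((n_vert, 3))
    vertices[0] = _surface_point(shape, 0.0, 0.0)
    vertices[-1] = _surface_point(shape, 0.0, np.pi)
    for i in range(1, nv):
        phi = np.pi * i / nv
        for j in range(0, m // 2 + 1):
            theta = 2 * np.pi * j / m
            vertices[_vertex_index(i, j, m, nv)] = _surface_point(shape, theta, phi)
        for j in range(m // 2 + 1, m):
            src = vertices[_vertex_index(i, m - j, m, nv)]
            vertices[_vertex_index(i, j, m, nv)] = src * np.array([-1.0, 1.0, 1.0])
    # Midline columns are exactly on the plane.
    for i in range(1, nv):
        for j in (0, m // 2):
            vertices[_vertex_index(i, j, m, nv), 0] = 0.0

    faces = []
    for j in range(m):  # top fan
        faces.append([0, _vertex_index(1, j, m, nv), _vertex_index(1, j + 1, m, nv)])
    for i in range(1, nv - 1):  # quad strips
        for j in range(m):
            a = _vertex_index(i, j, m, nv)
            b = _vertex_index(i, j + 1, m, nv)
            c = _vertex_index(i + 1, j, m, nv)
            d = _vertex_index(i + 1, j + 1, m, nv)
            # Mirror the diagonal split across the midsagittal plane so the
            # piecewise-linear surface (not just the vertex set) is exactly
            # symmetric.
            if j < m // 2:
                faces.append([a, c, d])
                faces.append([a, d, b])
            else:
                faces.append([a, c, b])
                faces.append([c, d, b])
    last = n_vert - 1
    for j in range(m):  # bottom fan
        faces.append([last, _vertex_index(nv - 1, j + 1, m, nv), _vertex_index(nv - 1, j, m, nv)])
    faces = np.array(faces, dtype=np.int64)

    mesh = HeadMesh(vertices, faces)
    tm = mesh.to_trimesh()
    if tm.volume < 0:  # enforce outward orientation
        faces = faces[:, [0, 2, 1]]
        mesh = HeadMesh(vertices, faces)

    mirror = np.empty(n_vert, dtype=np.int64)
    mirror[0] = 0
    mirror[-1] = n_vert - 1
    for i in range(1, nv):
        for j in range(m):
            mirror[_vertex_index(i, j, m, nv)] = _vertex_index(i, (m - j) % m, m, nv)

    anchors = _place_anchors(mesh, mirror, m, nv)
    tpl = SymmetricTemplate(mesh, mirror, anchors, shape, np.zeros(3))
    tpl.verify()
    return tpl


def _surface_point(shape: HeadShape, theta: float, phi: float) -> np.ndarray:
    r = float(shape.radius(theta, phi))
    sphi = np.sin(phi)
    return np.array([r * sphi * np.sin(theta), r * np.cos(phi), r * sphi * np.cos(theta)])


def _snap(theta_deg, phi_deg, m, nv, used, side):
    """Snap a nominal direction to an unused grid vertex.

    ``side`` constrains the azimuth column: 'mid' to the two midline
    columns, 'right' to columns with x < 0.
    """
    phi_ring = int(round(phi_deg / 180.0 * nv))
    if side == "mid":
        j0 = 0 if abs(theta_deg) < 90 else m // 2
        cols = [j0]
        if phi_ring <= 0:
            candidates = [(0, 0)] + [(r, j0) for r in range(1, nv)]
        else:
            candidates = [(phi_ring, j0)]
            for dr in range(1, nv):
                for r in (phi_ring - dr, phi_ring + dr):
                    if 0 < r < nv:
                        candidates.append((r, j0))
            candidates.append((0, 0))
    else:
        j0 = int(round(theta_deg / 360.0 * m)) % m
        j0 = min(max(j0, m // 2 + 1), m - 1)  # strictly right half
        phi_ring = min(max(phi_ring, 1), nv - 1)
        candidates = []
        for dist in range(0, m * nv):
            found_any = False
            for dr in range(-dist, dist + 1):
                dj = dist - abs(dr)
                for sj in ({dj, -dj}):
                    r, j = phi_ring + dr, j0 + sj
                    if 0 < r < nv and m // 2 < j < m:
                        candidates.append((r, j))
                        found_any = True
            if dist > max(m, nv) and not found_any:
                break
    for r, j in candidates:
        idx = _vertex_index(r, j, m, nv)
        if idx not in used:
            return idx
    raise MeshError("template resolution too low to place distinct anchors")


def _place_anchors(mesh: HeadMesh, mirror: np.ndarray, m: int, nv: int) -> dict[str, int]:
    used: set[int] = set()
    anchors: dict[str, int] = {}
    for lb, (th, ph) in _MIDLINE_ANGLES.items():
        idx = _snap(th, ph, m, nv, used, "mid")
        anchors[lb] = idx
        used.add(idx)
    for lb, (th, ph) in _RIGHT_ANGLES.items():
        idx = _snap(th, ph, m, nv, used, "right")
        anchors[lb] = idx
        used.add(idx)
        lidx = int(mirror[idx])
        if lidx in used:
            raise MeshError("template resolution too low to place distinct anchors")
        anchors[lb[:-2] + "-l"] = lidx
        used.add(lidx)
    anchors.update(_layer_anchors(mesh, mirror, m, nv, anchors, used))
    return anchors


def _layer_anchors(mesh, mirror, m, nv, anchors, used, n_layers=4, per_layer=10):
    """Skull-layer anchors: rings of 10 between the OBs level and the vertex."""
    v = mesh.vertices
    y_obs = 0.5 * (v[anchors["OBs-r"], 1] + v[anchors["OBs-l"], 1])
    y_v = v[anchors["V"], 1]
    out: dict[str, int] = {}
    for k in range(1, n_layers + 1):
        y_k = y_obs + k / (n_layers + 1) * (y_v - y_obs)
        for j in range(per_layer):
            if j > per_layer // 2:
                src = out[f"Layer{k}-{per_layer - j}"]
                idx = int(mirror[src])
                if idx in used:
                    raise MeshError("template resolution too low for layer anchors")
            else:
                az = 360.0 * j / per_layer
                col = int(round(az / 360.0 * m)) % m
                if j == 0:
                    col = 0
                elif 2 * j == per_layer:
                    col = m // 2
                col = min(col, m // 2)
                ring_idx = [_vertex_index(r, col, m, nv) for r in range(1, nv)]
                order = np.argsort(np.abs(v[ring_idx, 1] - y_k))
                idx = None
                for o in order:
                    cand = ring_idx[o]
                    if cand not in used and (j in (0, per_layer // 2) or mirror[cand] != cand):
                        idx = cand
                        break
                if idx is None:
                    raise MeshError("template resolution too low for layer anchors")
            out[f"Layer{k}-{j}"] = idx
            used.add(idx)
    return out


def scale_template(template: SymmetricTemplate, lms: LandmarkSet) -> SymmetricTemplate:
    """Anisotropically size the template to a subject in the canonical frame.

    Width from the gonion pair, height from vertex-gnathion, depth from
    pronasale-opisthocranion; the x scale acts symmetrically about the
    midsagittal plane so the mirror pairing survives exactly.
    """
    tpl_lms = template.anchor_points(["Go-r", "Go-l", "V", "Gn", "PRn", "Op"])

    def extents(src):
        w = src["Go-l"][0] - src["Go-r"][0]
        h = src["V"][1] - src["Gn"][1]
        d = src["PRn"][2] - src["Op"][2]
        return np.array([w, h, d])

    sub = extents(lms)
    tpl = extents(tpl_lms)
    if np.any(sub <= 0) or np.any(tpl <= 0):
        raise DegenerateGeometryError("non-positive landmark extent for scaling")
    s = sub / tpl
    c = template.center  # on the midsagittal plane, so x = 0 is preserved
    vertices = (template.mesh.vertices - c) * s + c
    mesh = HeadMesh(vertices, template.mesh.faces.copy())
    out = SymmetricTemplate(
        mesh, template.mirror.copy(), dict(template.anchors), template.shape, c.copy()
    )
    out.verify(atol=1e-9)
    return out


# ---------------------------------------------------------------------------
# Thin-plate spline (3D biharmonic kernel U(r) = r)


@dataclass
class TPSWarp:
    """Fitted thin-plate spline deformation.

    ``warp(p) = [1, p] @ affine + sum_i w_i |p - c_i|``; kernel weights
    satisfy the vanishing zeroth and first moment constraints, so the warp
    reduces to its affine part at infinity.
    """

    sources: np.ndarray  # (n, 3)
    targets: np.ndarray  # (n, 3)
    affine: np.ndarray  # (4, 3), rows [1, x, y, z]
    weights: np.ndarray  # (n, 3)
    regularization: float = 0.0

    def __call__(self, pts):
        return warp_points(self, pts)

    def bending_energy(self) -> float:
        """Non-negative; zero exactly when the control relation is affine."""
        K = _dist_matrix(self.sources, self.sources)
        return float(max(-np.trace(self.weights.T @ K @ self.weights), 0.0))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sources": self.sources.tolist(),
                    "targets": self.targets.tolist(),
                    "affine": self.affine.tolist(),
                    "weights": self.weights.tolist(),
                    "regularization": self.regularization,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "TPSWarp":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["sources"]),
            np.array(d["targets"]),
            np.array(d["affine"]),
            np.array(d["weights"]),
            d.get("regularization", 0.0),
        )


def _dist_matrix(a, b):
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


def fit_tps(sources, targets, regularization: float = 0.0) -> TPSWarp:
    """Fit the 3D thin-plate spline interpolating sources onto targets.

    With ``regularization`` 0 the warp interpolates the controls exactly;
    larger values trade interpolation for smoothness.  Requires at least 4
    non-coplanar, pairwise-distinct control points.
    """
    sources = np.asarray(sources, float)
    targets = np.asarray(targets, float)
    n = len(sources)
    if n < 4:
        raise DegenerateGeometryError("TPS needs at least 4 control pairs")
    if sources.shape != targets.shape:
        raise DegenerateGeometryError("source/target count mismatch")
    if regularization < 0:
        raise DegenerateGeometryError("regularization must be non-negative")
    K = _dist_matrix(sources, sources)
    close = np.argwhere((K < 1e-9) & ~np.eye(n, dtype=bool))
    if len(close):
        i, j = close[0]
        raise DegenerateGeometryError(
            f"duplicate TPS control points at indices {i} and {j}"
        )
    centered = sources - sources.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateGeometryError("TPS control points are coplanar")
    P = np.hstack([np.ones((n, 1)), sources])
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = K + regularization * np.eye(n)
    sys[:n, n:] = P
    sys[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = targets
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"singular TPS system: {exc}") from exc
    return TPSWarp(sources, targets, sol[n:], sol[:n], regularization)


def warp_points(warp: TPSWarp, pts) -> np.ndarray:
    """Evaluate the warp at the given points (deterministic, vectorised)."""
    pts = np.atleast_2d(np.asarray(pts, float))
    U = _dist_matrix(pts, warp.sources)
    P = np.hstack([np.ones((len(pts), 1)), pts])
    return P @ warp.affine + U @ warp.weights


# ---------------------------------------------------------------------------
# Dense correspondence


@dataclass
class CorrespondenceMap:
    """Per template-vertex nearest point on the subject surface."""

    points: np.ndarray  # (n, 3) matched surface points
    faces: np.ndarray  # (n,) matched face index
    distances: np.ndarray  # (n,) mm


def closest_point_map(
    warped_vertices, subject: HeadMesh, method: str = "auto"
) -> CorrespondenceMap:
    """Globally nearest subject-surface point for every template vertex.

    ``warped_vertices`` may be a SymmetricTemplate or an (n, 3) array.
    ``method`` is 'auto' (KD-tree accelerated, exact) or 'brute'.
    """
    if isinstance(warped_vertices, SymmetricTemplate):
        pts = warped_vertices.mesh.vertices
    else:
        pts = np.asarray(warped_vertices, float)
    if subject.n_faces == 0:
        raise MeshError("subject mesh has no faces")
    tris = subject.triangles()
    if method == "brute":
        p, f, d = _trigeom.closest_point_brute(pts, tris)
    else:
        p, f, d = _trigeom.closest_point_accelerated(pts, tris)
    return CorrespondenceMap(p, f, d)
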