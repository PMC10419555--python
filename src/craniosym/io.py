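"""Mesh and landmark I/O plus the canonical head coordinate frame.

Every downstream computation assumes head geometry expressed in a canonical
frame: the midsagittal plane is ``{x = 0}`` with +x toward the subject's
anatomical left, +y superior, +z anterior, and the origin at the midpoint of
the two otobasion-inferius landmarks projected onto the fitted midsagittal
plane.  All coordinates are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import AlignmentError, LandmarkError, MeshFormatError

__all__ = [
    "MIDLINE_LABELS",
    "BILATERAL_BASES",
    "BILATERAL_LABELS",
    "ANATOMICAL_LABELS",
    "HeadMesh",
    "LandmarkSet",
    "CanonicalFrame",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "estimate_canonical_frame",
    "apply_frame",
]

#: The 15 midline soft-tissue landmarks.
MIDLINE_LABELS = (
    "G", "N", "PRn", "Sn", "C", "Ls", "Li", "Sto",
    "B", "Pg", "Gn", "V", "Op", "O", "Cer",
)

#: Base names of the 11 bilateral landmark pairs (suffixed ``-r`` / ``-l``).
BILATERAL_BASES = (
    "Ala", "Nb", "As", "Ex", "En", "Cph", "Ch", "Go", "OBs", "OBi", "L",
)

BILATERAL_LABELS = tuple(
    f"{base}-{side}" for base in BILATERAL_BASES for side in ("r", "l")
)

#: Closed vocabulary of the 37 anatomical landmarks.
ANATOMICAL_LABELS = MIDLINE_LABELS + BILATERAL_LABELS


def is_layer_label(label: str) -> bool:
    """True for constructed skull-layer labels of the form ``Layer{k}-{j}``."""
    if not label.startswith("Layer"):
        return False
    body = label[5:]
    parts = body.split("-")
    return len(parts) == 2 and all(p.isdigit() for p in parts)


def _valid_label(label: str) -> bool:
    return label in ANATOMICAL_LABELS or is_layer_label(label)


@dataclass
class HeadMesh:
    """Triangulated head surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    scalar : optional (n,) per-vertex scalar channel (e.g. asymmetry, mm)
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("vertex coordinates must be finite")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError("face indices out of range")
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=float)
            if self.scalar.shape != (len(self.vertices),):
                raise MeshFormatError("scalar channel length mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def volume_mm3(self) -> float:
        """Enclosed volume by signed-tetrahedron summation (mm^3)."""
        from .errors import MeshError

        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise MeshError("volume requires a watertight mesh")
        return float(abs(tm.volume))

    def copy(self) -> "HeadMesh":
        return HeadMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalar is None else self.scalar.copy(),
        )


class LandmarkSet:
    """Named 3D landmarks drawn from the closed 37-label vocabulary.

    Accepts the 37 anatomical labels of the measurement scheme plus the
    constructed skull-layer labels ``Layer{k}-{j}`` used by the asymmetry
    analysis.  Bilateral labels must come as complete ``-r`` / ``-l`` pairs.
    """

    def __init__(self, points: dict[str, np.ndarray] | None = None):
        self._points: dict[str, np.ndarray] = {}
        if points:
            for label, p in points.items():
                self[label] = p

    def __setitem__(self, label: str, p) -> None:
        if not _valid_label(label):
            raise LandmarkError(f"label {label!r} outside the landmark vocabulary")
        arr = np.asarray(p, dtype=float).reshape(3)
        if not np.all(np.isfinite(arr)):
            raise LandmarkError(f"non-finite coordinates for landmark {label!r}")
        self._points[label] = arr

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self._points[label]
        except KeyError:
            raise LandmarkError(f"landmark {label!r} not present") from None

    def __contains__(self, label: str) -> bool:
        return label in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self):
        return iter(self._points)

    def labels(self) -> list[str]:
        return list(self._points)

    def items(self):
        return self._points.items()

    def missing_anatomical(self) -> list[str]:
        return [lb for lb in ANATOMICAL_LABELS if lb not in self._points]

    def require_complete(self) -> None:
        """Raise unless all 37 anatomical landmarks are present."""
        missing = self.missing_anatomical()
        if missing:
            raise LandmarkError(
                "landmark set incomplete; missing: " + ", ".join(missing)
            )
        for base in BILATERAL_BASES:
            if (f"{base}-r" in self) != (f"{base}-l" in self):
                raise LandmarkError(f"bilateral pair {base} incomplete")

    def as_array(self, labels) -> np.ndarray:
        return np.array([self[lb] for lb in labels])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        out = LandmarkSet()
        for lb, p in self.items():
            out._points[lb] = rotation @ p + translation
        return out

    def mirrored(self) -> "LandmarkSet":
        """Reflect across {x = 0} and swap -r/-l labels."""
        out = LandmarkSet()
        for lb, p in self.items():
            q = p * np.array([-1.0, 1.0, 1.0])
            if lb.endswith("-r") and not is_layer_label(lb):
                lb = lb[:-2] + "-l"
            elif lb.endswith("-l") and not is_layer_label(lb):
                lb = lb[:-2] + "-r"
            out._points[lb] = q
        return out

    def copy(self) -> "LandmarkSet":
        out = LandmarkSet()
        out._points = {lb: p.copy() for lb, p in self.items()}
        return out


@dataclass
class CanonicalFrame:
    """Rigid transform into the canonical head frame.

    ``canonical = rotation @ world + translation``; rotation is proper
    orthonormal.  After the transform the midsagittal plane is ``{x = 0}``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise AlignmentError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "CanonicalFrame":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "CanonicalFrame":
        rot = self.rotation.T
        return CanonicalFrame(rot, -rot @ self.translation)


# ---------------------------------------------------------------------------
# Mesh I/O


def _sniff_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unknown mesh format {fmt!r} (expected ply or obj)")
    return fmt


def _read_ply_with_scalar(path: Path) -> HeadMesh | None:
    """Parse an ASCII PLY that carries a per-vertex ``quality`` channel.

    Returns None when the file is not ASCII or has no quality property, in
    which case the generic loader is used instead.
    """
    with open(path, "rb") as fh:
        header = fh.readline()
        if not header.startswith(b"ply"):
            return None
        lines = [header.decode()]
        while True:
            line = fh.readline().decode()
            lines.append(line)
            if line.strip() == "end_header":
                break
        body = fh.read().decode()
    if "format ascii" not in lines[1]:
        return None
    n_vertex = n_face = 0
    vertex_props: list[str] = []
    element = None
    for line in lines[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vertex = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vertex_props.append(tok[2])
    if "quality" not in vertex_props:
        return None
    rows = body.strip().split("\n")
    vdata = np.array(
        [[float(v) for v in rows[i].split()] for i in range(n_vertex)]
    )
    cols = {name: j for j, name in enumerate(vertex_props)}
    vertices = vdata[:, [cols["x"], cols["y"], cols["z"]]]
    scalar = vdata[:, cols["quality"]]
    faces = []
    for i in range(n_vertex, n_vertex + n_face):
        tok = rows[i].split()
        count = int(tok[0])
        idx = [int(t) for t in tok[1 : 1 + count]]
        for k in range(1, count - 1):  # fan-triangulate if needed
            faces.append([idx[0], idx[k], idx[k + 1]])
    return HeadMesh(vertices, np.array(faces, dtype=np.int64), scalar)


def read_mesh(path, fmt: str | None = None) -> HeadMesh:
    """Read a PLY or OBJ surface; non-triangular faces are triangulated."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file {path} does not exist")
    fmt = _sniff_format(path, fmt)
    if fmt == "ply":
        withscalar = _read_ply_with_scalar(path)
        if withscalar is not None:
            return withscalar
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # pragma: no cover - delegated parser detail
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshFormatError(f"{path} does not contain a single triangulated surface")
    return HeadMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def write_mesh(mesh: HeadMesh, path, fmt: str | None = None) -> Path:
    """Write PLY (ASCII, with scalar channel if present) or OBJ."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    if fmt == "ply":
        _write_ply(mesh, path)
    else:
        if mesh.scalar is not None:
            raise MeshFormatError("OBJ cannot carry the per-vertex scalar channel")
        mesh.to_trimesh().export(str(path), file_type="obj")
    return path


def _write_ply(
    mesh: HeadMesh, path: Path, colors: np.ndarray | None = None
) -> None:
    # double-precision properties so coordinate round-trips stay sub-um
    n_v, n_f = mesh.n_vertices, mesh.n_faces
    has_q = mesh.scalar is not None
    has_c = colors is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n_v}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_q:
            fh.write("property double quality\n")
        if has_c:
            fh.write(
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            )
        fh.write(f"element face {n_f}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(n_v):
            x, y, z = mesh.vertices[i]
            row = f"{x:.8f} {y:.8f} {z:.8f}"
            if has_q:
                row += f" {mesh.scalar[i]:.8f}"
            if has_c:
                r, g, b = colors[i]
                row += f" {int(r)} {int(g)} {int(b)}"
            fh.write(row + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# Landmark I/O


def read_landmarks(path, require_complete: bool = True) -> LandmarkSet:
    """Read landmarks from CSV (``label,x,y,z`` with header) or JSON.

    JSON files hold a mapping ``{label: [x, y, z]}``.  Labels outside the
    closed vocabulary are rejected; with ``require_complete`` all 37
    anatomical landmarks must be present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"landmark file {path} does not exist")
    lms = LandmarkSet()
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        items = mapping.items()
    else:
        rows = path.read_text().strip().split("\n")
        header = [h.strip().lower() for h in rows[0].split(",")]
        if header[:4] != ["label", "x", "y", "z"]:
            raise LandmarkError(
                f"expected CSV header 'label,x,y,z', found {rows[0]!r}"
            )
        items = []
        for row in rows[1:]:
            if not row.strip():
                continue
            tok = row.split(",")
            items.append((tok[0].strip(), [float(t) for t in tok[1:4]]))
    for label, xyz in items:
        if label in lms:
            raise LandmarkError(f"duplicate landmark label {label!r}")
        lms[label] = xyz
    if require_complete:
        lms.require_complete()
    return lms


def write_landmarks(lms: LandmarkSet, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {lb: [float(v) for v in p] for lb, p in lms.items()}
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = ["label,x,y,z"]
        for lb, p in lms.items():
            lines.append(f"{lb},{p[0]:.9f},{p[1]:.9f},{p[2]:.9f}")
        path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Canonical frame


def estimate_canonical_frame(lms: LandmarkSet) -> CanonicalFrame:
    """Fit the midsagittal plane and build the canonical head frame.

    The plane normal is the dominant direction of the unit right-minus-left
    difference vectors of the 11 bilateral pairs; the plane passes through
    the centroid of the pair midpoints.  +x points toward the anatomical
    left; the in-plane +z (anterior) axis follows the projected
    pronasale-opisthocranion chord, and +y completes the right-handed
    frame (validated: the vertex must come out superior to the gnathion).
    The origin is the otobasion-inferius midpoint projected onto the plane.
    """
    lms.require_complete()
    rights = lms.as_array([f"{b}-r" for b in BILATERAL_BASES])
    lefts = lms.as_array([f"{b}-l" for b in BILATERAL_BASES])
    diffs = rights - lefts
    norms = np.linalg.norm(diffs, axis=1)
    if np.all(norms < 1e-12):
        raise AlignmentError("all bilateral pairs coincident; cannot fit plane")
    units = diffs[norms > 1e-12] / norms[norms > 1e-12, None]
    # Align signs before extracting the principal direction.
    ref = units[0]
    units = units * np.sign(units @ ref)[:, None]
    _, _, vt = np.linalg.svd(units)
    normal = vt[0]
    # Point the normal toward the anatomical left.
    if np.mean((lefts - rights) @ normal) < 0:
        normal = -normal
    centroid = 0.5 * (rights + lefts).mean(axis=0)

    x_axis = normal
    # In-plane anterior axis from the pronasale-opisthocranion chord (the
    # anthropometric horizontal); the vertical follows by right-handedness.
    fwd = lms["PRn"] - lms["Op"]
    fwd = fwd - (fwd @ x_axis) * x_axis
    nfwd = np.linalg.norm(fwd)
    if nfwd < 1e-9:
        raise AlignmentError("PRn-Op direction degenerate with the plane normal")
    z_axis = fwd / nfwd
    y_axis = np.cross(z_axis, x_axis)
    if (lms["V"] - lms["Gn"]) @ y_axis <= 0:
        raise AlignmentError(
            "axis conventions inconsistent: vertex not superior to gnathion"
        )
    obi_mid = 0.5 * (lms["OBi-r"] + lms["OBi-l"])
    origin = obi_mid - ((obi_mid - centroid) @ x_axis) * x_axis
    rotation = np.vstack([x_axis, y_axis, z_axis])
    return CanonicalFrame(rotation, -rotation @ origin)


def apply_frame(obj, frame: CanonicalFrame):
    """Apply the rigid transform to a HeadMesh or LandmarkSet."""
    if isinstance(obj, HeadMesh):
        out = obj.copy()
        out.vertices = frame.apply(obj.vertices)
        return out
    if isinstance(obj, LandmarkSet):
        return obj.transformed(frame.rotation, frame.translation)
    raise TypeError(f"cannot apply frame to {type(obj).__name__}")
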