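"""The 14-parameter soft-tissue measurement battery (8 linear, 6 angular).

Vertical face heights (N-Gn, N-Sn, Sto-Gn, Sn-Sto, N-Sto), the
anteroposterior positions of the subnasale (Sn to the N-Pg line) and of the
pogonion (Pg to the N-B line), mandibular body length (Go-Gn per side), and
the profile angles: nasolabial (∠Cm-Sn-Ls, with the columella point C
standing for Cm), labiomental (∠Li-B-Pg), lower lip to submental plane
(∠B-Pg : Cer-Gn), gonial (∠OBi-Go-Gn per side), facial convexity
(∠N-Sn-Pg) and full soft-tissue convexity (∠N-PRn-Pg).

The two line-distance parameters carry a sign (+ anterior); anterior is
derived intrinsically from the landmarks (unit pronasale-minus-
opisthocranion), so all 14 values are invariant under rigid motion and
under mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DegenerateGeometryError, LandmarkError
from .io import LandmarkSet

__all__ = [
    "distance",
    "point_to_line_distance",
    "angle_at_vertex",
    "angle_between_segments",
    "MeasurementRecord",
    "measure_subject",
    "PARAMETER_CODES",
]

#: Table-ordered prime codes for the 14 parameters.
PARAMETER_CODES = {
    "N_Gn": "a'",
    "N_Sn": "b'",
    "Sto_Gn": "c'",
    "Sn_Sto": "d'",
    "N_Sto": "e'",
    "Sn_to_NPg": "f'",
    "Go_Gn": "g'",
    "Pg_to_NB": "h'",
    "nasolabial_angle": "i'",
    "labiomental_angle": "j'",
    "lowerlip_submental_angle": "k'",
    "gonial_angle": "l'",
    "facial_convexity": "m'",
    "soft_tissue_convexity": "n'",
}


def distance(p, q) -> float:
    """Euclidean distance in mm."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def point_to_line_distance(p, a, b, signed_axis=None) -> float:
    """Perpendicular distance from ``p`` to the infinite line through a, b.

    With ``signed_axis`` the result is signed by the component of the
    offset vector (p minus its projection) along that axis.
    """
    p = np.asarray(p, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = b - a
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise DegenerateGeometryError("line endpoints coincide")
    d = d / nd
    offset = (p - a) - ((p - a) @ d) * d
    dist = float(np.linalg.norm(offset))
    if signed_axis is not None:
        sign = np.sign(offset @ np.asarray(signed_axis, float))
        if sign != 0:
            dist *= sign
    return dist


def angle_at_vertex(a, v, b) -> float:
    """Angle at vertex ``v`` between rays v->a and v->b, degrees in (0, 180]."""
    a = np.asarray(a, float)
    v = np.asarray(v, float)
    b = np.asarray(b, float)
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("angle vertex coincides with an endpoint")
    c = np.clip(u1 @ u2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_between_segments(a1, a2, b1, b2) -> float:
    """Angle between directed segments a1->a2 and b1->b2, degrees in (0, 180]."""
    u = np.asarray(a2, float) - np.asarray(a1, float)
    v = np.asarray(b2, float) - np.asarray(b1, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("degenerate segment")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class MeasurementRecord:
    """One subject's 14 measurements, bilateral ones per side plus mean."""

    N_Gn: float                       # a', mm
    N_Sn: float                       # b', mm
    Sto_Gn: float                     # c', mm
    Sn_Sto: float                     # d', mm
    N_Sto: float                      # e', mm
    Sn_to_NPg: float                  # f', mm, signed (+ anterior)
    Go_Gn: float                      # g', mm, mean of sides
    Pg_to_NB: float                   # h', mm, signed (+ anterior)
    nasolabial_angle: float           # i', degrees
    labiomental_angle: float          # j', degrees
    lowerlip_submental_angle: float   # k', degrees
    gonial_angle: float               # l', degrees, mean of sides
    facial_convexity: float           # m', degrees
    soft_tissue_convexity: float      # n', degrees
    Go_Gn_r: float = float("nan")
    Go_Gn_l: float = float("nan")
    gonial_angle_r: float = float("nan")
    gonial_angle_l: float = float("nan")

    def to_dict(self, per_side: bool = False) -> dict[str, float]:
        out = {}
        for f in fields(self):
            if not per_side and f.name not in PARAMETER_CODES:
                continue
            out[f.name] = getattr(self, f.name)
        return out

    def values14(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAMETER_CODES])


_REQUIRED = {
    "N_Gn": ("N", "Gn"),
    "N_Sn": ("N", "Sn"),
    "Sto_Gn": ("Sto", "Gn"),
    "Sn_Sto": ("Sn", "Sto"),
    "N_Sto": ("N", "Sto"),
    "Sn_to_NPg": ("Sn", "N", "Pg", "PRn", "Op"),
    "Go_Gn": ("Go-r", "Go-l", "Gn"),
    "Pg_to_NB": ("Pg", "N", "B", "PRn", "Op"),
    "nasolabial_angle": ("C", "Sn", "Ls"),
    "labiomental_angle": ("Li", "B", "Pg"),
    "lowerlip_submental_angle": ("B", "Pg", "Cer", "Gn"),
    "gonial_angle": ("OBi-r", "OBi-l", "Go-r", "Go-l", "Gn"),
    "facial_convexity": ("N", "Sn", "Pg"),
    "soft_tissue_convexity": ("N", "PRn", "Pg"),
}


def measure_subject(lms: LandmarkSet) -> MeasurementRecord:
    """Compute the full measurement battery from a complete landmark set."""
    missing = lms.missing_anatomical()
    if missing:
        affected = sorted(
            name
            for name, req in _REQUIRED.items()
            if any(lb in missing for lb in req)
        )
        raise LandmarkError(
            "missing landmarks "
            + ", ".join(missing)
            + "; affected measurements: "
            + ", ".join(affected)
        )

    anterior = lms["PRn"] - lms["Op"]
    anterior = anterior / np.linalg.norm(anterior)

    go_gn_r = distance(lms["Go-r"], lms["Gn"])
    go_gn_l = distance(lms["Go-l"], lms["Gn"])
    gonial_r = angle_at_vertex(lms["OBi-r"], lms["Go-r"], lms["Gn"])
    gonial_l = angle_at_vertex(lms["OBi-l"], lms["Go-l"], lms["Gn"])

    return MeasurementRecord(
        N_Gn=distance(lms["N"], lms["Gn"]),
        N_Sn=distance(lms["N"], lms["Sn"]),
        Sto_Gn=distance(lms["Sto"], lms["Gn"]),
        Sn_Sto=distance(lms["Sn"], lms["Sto"]),
        N_Sto=distance(lms["N"], lms["Sto"]),
        Sn_to_NPg=point_to_line_distance(
            lms["Sn"], lms["N"], lms["Pg"], signed_axis=anterior
        ),
        Go_Gn=0.5 * (go_gn_r + go_gn_l),
        Pg_to_NB=point_to_line_distance(
            lms["Pg"], lms["N"], lms["B"], signed_axis=anterior
        ),
        nasolabial_angle=angle_at_vertex(lms["C"], lms["Sn"], lms["Ls"]),
        labiomental_angle=angle_at_vertex(lms["Li"], lms["B"], lms["Pg"]),
        lowerlip_submental_angle=angle_between_segments(
            lms["B"], lms["Pg"], lms["Cer"], lms["Gn"]
        ),
        gonial_angle=0.5 * (gonial_r + gonial_l),
        facial_convexity=angle_at_vertex(lms["N"], lms["Sn"], lms["Pg"]),
        soft_tissue_convexity=angle_at_vertex(lms["N"], lms["PRn"], lms["Pg"]),
        Go_Gn_r=go_gn_r,
        Go_Gn_l=go_gn_l,
        gonial_angle_r=gonial_r,
        gonial_angle_l=gonial_l,
    )
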