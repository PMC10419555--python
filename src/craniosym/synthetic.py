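"""Synthetic head cohorts calibrated to published pediatric group norms.

The generator emulates the measured population the analysis layer expects:
for each occlusion class (I/II/III) and sex it draws target values for the
14 anthropometric parameters from configured normal distributions
(defaults: the published class-by-sex means and SDs), then *constructively*
places landmarks so that re-measuring the subject reproduces every drawn
target to numerical precision.  Head size norms (H, L, W) and the facial /
whole-head asymmetry magnitudes (AF, AH) are drawn per class and realised
in an optional analytic head mesh with a controlled left-right radial
asymmetry field.

Geometric feasibility.  The vertical chain N-Sn (b'), Sn-Sto (d') and
N-Sto (e') is almost collinear in real faces, so e' is within a fraction of
a millimetre of b' + d'; independent draws would violate the triangle
inequality about half the time and rejection sampling would visibly bias
the cohort means.  The generator therefore draws (b', d', c') jointly
normal with a minimal moment-matched covariance and *derives*
``e' = b' + d' - delta1`` and ``a' = e' + c' - delta2`` where delta1/delta2
are the (positive) collinearity defects implied by the configured means.
All five parameters then match their configured means and SDs exactly in
expectation while every draw is geometrically realisable.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import MeasurementRecord, measure_subject
from .errors import GenerationError
from .io import LandmarkSet, HeadMesh, write_landmarks, write_mesh
from .template import HeadShape, build_template

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_PARAMS",
    "DEFAULT_HEAD_NORMS",
    "CohortConfig",
    "SubjectSample",
    "generate_subject",
    "generate_cohort",
    "simulate_raters",
    "reliability_study",
]

#: Roster sizes per (class, sex).
DEFAULT_GROUP_SIZES = {
    ("I", "M"): 38, ("I", "F"): 36,
    ("II", "M"): 24, ("II", "F"): 26,
    ("III", "M"): 4, ("III", "F"): 11,
}

# Published per-class, per-sex calibration targets: mean, SD.
# Distances in mm, angles in degrees.
DEFAULT_PARAMS = {
    "I": {
        "M": {
            "N_Gn": (103.80, 4.31), "N_Sn": (43.22, 2.32), "Sto_Gn": (43.72, 3.72),
            "Sn_Sto": (20.54, 1.90), "N_Sto": (63.53, 2.93), "Sn_to_NPg": (6.49, 1.84),
            "Go_Gn": (61.45, 4.33), "Pg_to_NB": (2.60, 2.22),
            "nasolabial_angle": (106.85, 10.50), "labiomental_angle": (140.48, 12.09),
            "lowerlip_submental_angle": (121.81, 8.31), "gonial_angle": (146.85, 3.89),
            "facial_convexity": (163.55, 4.45), "soft_tissue_convexity": (137.57, 3.53),
        },
        "F": {
            "N_Gn": (102.65, 5.58), "N_Sn": (43.53, 2.43), "Sto_Gn": (43.53, 4.21),
            "Sn_Sto": (19.15, 2.42), "N_Sto": (62.45, 3.76), "Sn_to_NPg": (5.85, 1.96),
            "Go_Gn": (60.00, 3.64), "Pg_to_NB": (1.82, 1.54),
            "nasolabial_angle": (104.34, 12.48), "labiomental_angle": (143.97, 11.80),
            "lowerlip_submental_angle": (119.60, 9.51), "gonial_angle": (146.65, 3.80),
            "facial_convexity": (164.84, 4.92), "soft_tissue_convexity": (136.96, 3.25),
        },
    },
    "II": {
        "M": {
            "N_Gn": (106.98, 4.75), "N_Sn": (43.99, 2.16), "Sto_Gn": (46.28, 4.87),
            "Sn_Sto": (21.00, 1.97), "N_Sto": (64.71, 3.14), "Sn_to_NPg": (6.76, 1.76),
            "Go_Gn": (60.84, 4.43), "Pg_to_NB": (2.16, 3.29),
            "nasolabial_angle": (109.58, 9.47), "labiomental_angle": (135.18, 14.60),
            "lowerlip_submental_angle": (124.55, 9.19), "gonial_angle": (145.38, 4.75),
            "facial_convexity": (163.04, 4.08), "soft_tissue_convexity": (135.91, 2.82),
        },
        "F": {
            "N_Gn": (102.02, 5.56), "N_Sn": (42.26, 2.31), "Sto_Gn": (43.56, 4.72),
            "Sn_Sto": (20.02, 2.33), "N_Sto": (61.96, 3.49), "Sn_to_NPg": (6.12, 2.02),
            "Go_Gn": (60.26, 3.34), "Pg_to_NB": (1.95, 1.41),
            "nasolabial_angle": (104.86, 10.73), "labiomental_angle": (139.31, 13.34),
            "lowerlip_submental_angle": (119.50, 10.10), "gonial_angle": (146.38, 4.75),
            "facial_convexity": (163.91, 5.04), "soft_tissue_convexity": (136.21, 3.31),
        },
    },
    "III": {
        "M": {
            "N_Gn": (104.16, 7.32), "N_Sn": (42.15, 2.32), "Sto_Gn": (45.63, 6.35),
            "Sn_Sto": (19.70, 2.26), "N_Sto": (61.68, 4.41), "Sn_to_NPg": (4.62, 1.50),
            "Go_Gn": (60.50, 6.03), "Pg_to_NB": (2.19, 1.24),
            "nasolabial_angle": (108.11, 13.77), "labiomental_angle": (143.79, 16.38),
            "lowerlip_submental_angle": (120.89, 6.51), "gonial_angle": (144.51, 3.80),
            "facial_convexity": (167.98, 3.68), "soft_tissue_convexity": (140.65, 3.51),
        },
        "F": {
            "N_Gn": (104.59, 9.06), "N_Sn": (44.93, 5.49), "Sto_Gn": (43.01, 4.02),
            "Sn_Sto": (19.66, 2.46), "N_Sto": (64.27, 7.05), "Sn_to_NPg": (6.02, 3.40),
            "Go_Gn": (62.93, 2.87), "Pg_to_NB": (1.82, 1.64),
            "nasolabial_angle": (111.43, 10.59), "labiomental_angle": (141.69, 9.53),
            "lowerlip_submental_angle": (116.56, 13.27), "gonial_angle": (147.92, 2.09),
            "facial_convexity": (165.29, 7.19), "soft_tissue_convexity": (136.74, 4.20),
        },
    },
}

#: Per-class head norms and asymmetry magnitudes: mean, SD (H/L/W/AH/AF mm).
DEFAULT_HEAD_NORMS = {
    "I": {"H": (228.6, 9.81), "L": (181.38, 6.87), "W": (160.98, 10.10),
          "AH": (2.32, 1.14), "AF": (0.94, 0.51)},
    "II": {"H": (228.82, 10.54), "L": (182.19, 7.74), "W": (164.77, 12.70),
           "AH": (2.18, 1.13), "AF": (0.88, 0.35)},
    "III": {"H": (227.1, 9.13), "L": (180.58, 8.25), "W": (161.00, 8.78),
            "AH": (1.85, 0.85), "AF": (0.82, 0.36)},
}


@dataclass
class CohortConfig:
    """Everything the generator needs, seedable end-to-end."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    params: dict = field(default_factory=lambda: _deepcopy_params(DEFAULT_PARAMS))
    head_norms: dict = field(default_factory=lambda: _deepcopy_params(DEFAULT_HEAD_NORMS))
    age_p10: float = 0.13  # probability a subject is 10 rather than 9 years old
    rater_noise_sd: float = 0.5  # mm, isotropic landmark digitisation noise
    seed: int | None = None
    mesh_resolution: tuple[int, int] = (40, 28)

    def validate(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 0:
                raise GenerationError(f"negative group size for {key}")
        for cls, by_sex in self.params.items():
            for sex, cell in by_sex.items():
                for p, (mu, sd) in cell.items():
                    if sd < 0:
                        raise GenerationError(f"negative SD for {cls}/{sex}/{p}")
                d1, d2 = _collinearity_defects(cell)
                if d1 <= 0 or d2 <= 0:
                    raise GenerationError(
                        f"configured means for {cls}/{sex} are not geometrically"
                        f" consistent (collinearity defects {d1:.3f}, {d2:.3f})"
                    )
        for cls, norms in self.head_norms.items():
            for p, (mu, sd) in norms.items():
                if sd < 0 or mu <= 0:
                    raise GenerationError(f"invalid head norm {cls}/{p}")
        if self.rater_noise_sd < 0:
            raise GenerationError("rater noise SD must be non-negative")

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "group_sizes": {f"{c}/{s}": n for (c, s), n in self.group_sizes.items()},
            "params": self.params,
            "head_norms": self.head_norms,
            "age_p10": self.age_p10,
            "rater_noise_sd": self.rater_noise_sd,
            "seed": self.seed,
            "mesh_resolution": list(self.mesh_resolution),
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        if "group_sizes" in d:
            cfg.group_sizes = {
                tuple(k.split("/")): v for k, v in d["group_sizes"].items()
            }
        for key in ("age_p10", "rater_noise_sd", "seed"):
            if key in d and d[key] is not None:
                setattr(cfg, key, d[key])
        if "mesh_resolution" in d:
            cfg.mesh_resolution = tuple(d["mesh_resolution"])
        for key in ("params", "head_norms"):
            if key in d:
                setattr(
                    cfg,
                    key,
                    {
                        cls_: {
                            k2: (
                                {p: tuple(v) for p, v in v2.items()}
                                if isinstance(v2, dict)
                                else tuple(v2)
                            )
                            for k2, v2 in by.items()
                        }
                        for cls_, by in d[key].items()
                    },
                )
        cfg.validate()
        return cfg


def _deepcopy_params(d):
    return {
        k: {
            k2: (dict(v2) if isinstance(v2, dict) else tuple(v2))
            for k2, v2 in v.items()
        }
        for k, v in d.items()
    }


def _collinearity_defects(cell) -> tuple[float, float]:
    d1 = cell["N_Sn"][0] + cell["Sn_Sto"][0] - cell["N_Sto"][0]
    d2 = cell["N_Sto"][0] + cell["Sto_Gn"][0] - cell["N_Gn"][0]
    return d1, d2


def _chain_sampler(cell):
    """Moment-matched covariance factor for the (b', d', c') joint draw."""
    sb = cell["N_Sn"][1]
    sd_ = cell["Sn_Sto"][1]
    sc = cell["Sto_Gn"][1]
    se = cell["N_Sto"][1]
    sa = cell["N_Gn"][1]
    if min(sb, sd_, sc) == 0:
        return np.zeros((3, 3))
    rho_bd = (se**2 - sb**2 - sd_**2) / (2 * sb * sd_)
    rho_bd = float(np.clip(rho_bd, -0.98, 0.98))
    K = (sa**2 - se**2 - sc**2) / 2.0  # Cov(b + d, c)
    k_b = K * sb / (sb + sd_)
    k_d = K * sd_ / (sb + sd_)
    cov = np.array(
        [
            [sb**2, rho_bd * sb * sd_, k_b],
            [rho_bd * sb * sd_, sd_**2, k_d],
            [k_b, k_d, sc**2],
        ]
    )
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 1e-10, None)
        warnings.warn(
            "chain covariance not positive definite; nearest-PD fallback used"
        )
        return v @ np.diag(np.sqrt(w))


def _trunc_normal(rng, mu, sd, lo=None, hi=None, nsd=4.0, max_tries=200):
    if sd == 0:
        return mu
    for _ in range(max_tries):
        x = rng.normal(mu, sd)
        if abs(x - mu) > nsd * sd:
            continue
        if lo is not None and x < lo:
            continue
        if hi is not None and x > hi:
            continue
        return x
    raise GenerationError(f"could not draw a feasible value around {mu}")


# ---------------------------------------------------------------------------
# Constructive landmark placement (midline work happens in the x = 0 plane)


def _rot_x(v, deg):
    """Rotate a 3D vector about the +x axis (within the midsagittal plane)."""
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([v[0], c * v[1] - s * v[2], s * v[1] + c * v[2]])


def _rodrigues(v, axis, deg):
    t = np.radians(deg)
    k = axis / np.linalg.norm(axis)
    return (
        v * np.cos(t) + np.cross(k, v) * np.sin(t) + k * (k @ v) * (1 - np.cos(t))
    )


def _signed_line_offset(p, a, b):
    """Signed (z anterior) perpendicular distance from p to line a-b."""
    d = b - a
    d = d / np.linalg.norm(d)
    off = (p - a) - ((p - a) @ d) * d
    mag = np.linalg.norm(off)
    return mag if off[2] >= 0 else -mag


def _place_pg(N, Sn, b, m_deg, f) -> np.ndarray:
    """Pogonion from the facial-convexity angle and the Sn-to-N-Pg offset."""
    u1 = (N - Sn) / b
    fa = abs(f) if abs(f) > 1e-8 else 1e-8
    sin_m = np.sin(np.radians(m_deg))
    cr2 = b * b * sin_m * sin_m
    if cr2 <= fa * fa:
        raise GenerationError("convexity angle and Sn offset are inconsistent")
    cos_m = np.cos(np.radians(m_deg))
    # t^2 (b^2 sin^2 m - f^2) + 2 f^2 b cos m t - f^2 b^2 = 0
    A = cr2 - fa * fa
    B = 2 * fa * fa * b * cos_m
    C = -(fa * fa) * b * b
    t = (-B + np.sqrt(B * B - 4 * A * C)) / (2 * A)
    for side in (1.0, -1.0):
        v = _rot_x(u1, side * m_deg)
        if v[1] >= 0:  # pogonion must head inferior
            continue
        pg = Sn + t * v
        f_meas = _signed_line_offset(Sn, N, pg)
        if abs(abs(f_meas) - fa) < 1e-6 and (f == 0 or np.sign(f_meas) == np.sign(f)):
            return pg
    raise GenerationError("no pogonion placement matches the drawn sign")


def _place_prn(N, Pg, n_deg, y_target=None) -> np.ndarray:
    """Pronasale on the anterior inscribed-angle arc over the N-Pg chord.

    Every point of the arc sees N-Pg under the drawn full-convexity angle;
    the free position along the arc is fixed at the anatomical nose-tip
    height ``y_target`` when the horizontal section intersects the arc,
    falling back to the arc apex otherwise.
    """
    chord = Pg - N
    Lc = np.linalg.norm(chord)
    sin_n = np.sin(np.radians(n_deg))
    R = Lc / (2 * sin_n)
    mid = 0.5 * (N + Pg)
    chat = chord / Lc
    w = np.array([0.0, -chat[2], chat[1]])  # in-plane perpendicular
    if w[2] < 0:
        w = -w
    s = np.sqrt(max(R * R - Lc * Lc / 4.0, 0.0))
    if n_deg >= 90.0:
        center = mid - s * w
        apex = mid + (R - s) * w
    else:
        center = mid + s * w
        apex = mid + (R + s) * w
    if y_target is not None and abs(y_target - center[1]) < R:
        dz = np.sqrt(R * R - (y_target - center[1]) ** 2)
        cand = np.array([0.0, y_target, center[2] + dz])  # anterior root
        # Must lie on the same (anterior) arc as the apex.
        if (cand - mid) @ w > 0:
            return cand
    return apex


def _place_b(N, Pg, Cer, Gn, k_deg, h) -> np.ndarray:
    """Sublabiale from the submental-plane angle and the Pg-to-N-B offset."""
    gdir = (Gn - Cer) / np.linalg.norm(Gn - Cer)
    a_vec = Pg - N
    A2 = a_vec @ a_vec
    ha = abs(h) if abs(h) > 1e-8 else 1e-8
    candidates = []
    for side in (1.0, -1.0):
        v = _rot_x(gdir, side * k_deg)
        cr = np.linalg.norm(np.cross(a_vec, v))
        if cr * cr <= ha * ha:
            continue
        dotav = a_vec @ v
        A = cr * cr - ha * ha
        B = 2 * ha * ha * dotav
        C = -(ha * ha) * A2
        disc = B * B - 4 * A * C
        if disc < 0:
            continue
        s = (-B + np.sqrt(disc)) / (2 * A)
        if s <= 0 or s > 60.0:  # sublabiale stays in the chin region
            continue
        Bpt = Pg - s * v
        h_meas = _signed_line_offset(Pg, N, Bpt)
        if abs(abs(h_meas) - ha) < 1e-6 and (h == 0 or np.sign(h_meas) == np.sign(h)):
            candidates.append(Bpt)
    if not candidates:
        raise GenerationError("no sublabiale placement matches the drawn target")
    # Prefer the anatomical branch (sublabiale above the pogonion); the other
    # branch is kept so retrusive (negative) pogonion offsets stay drawable.
    above = [b_ for b_ in candidates if b_[1] >= Pg[1]]
    return above[0] if above else candidates[0]


@dataclass
class SubjectSample:
    """One generated subject: landmarks, drawn targets, optional mesh."""

    cls: str
    sex: str
    age: int
    landmarks: LandmarkSet
    targets: dict[str, float]
    norms: dict[str, float]
    mesh: HeadMesh | None = None

    def measurements(self) -> MeasurementRecord:
        return measure_subject(self.landmarks)


def generate_subject(
    cls: str,
    sex: str,
    cfg: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
    with_mesh: bool = False,
) -> SubjectSample:
    """Draw parameter targets and construct a subject realising them.

    The returned landmarks are in the canonical frame (midline exactly on
    ``x = 0``, origin at the projected otobasion-inferius midpoint); with
    ``with_mesh`` an analytic head mesh with the drawn size norms and the
    configured left-right asymmetry field is attached.
    """
    cfg = cfg or CohortConfig()
    rng = rng or np.random.default_rng()
    cell = cfg.params[cls][sex]
    norms_cfg = cfg.head_norms[cls]
    d1, d2 = _collinearity_defects(cell)
    Lchain = _chain_sampler(cell)
    mu_chain = np.array([cell["N_Sn"][0], cell["Sn_Sto"][0], cell["Sto_Gn"][0]])
    sds_chain = np.array([cell["N_Sn"][1], cell["Sn_Sto"][1], cell["Sto_Gn"][1]])

    for attempt in range(200):
        z = rng.standard_normal(3)
        b, d, c = mu_chain + Lchain @ z
        if np.any(np.abs(np.array([b, d, c]) - mu_chain) > 4.0 * sds_chain + 1e-12):
            continue
        e = b + d - d1
        a = e + c - d2
        if min(b, d, c, e, a) <= 1.0:
            continue
        if e <= abs(b - d) + 0.05 or a <= abs(e - c) + 0.05:
            continue
        break
    else:
        raise GenerationError("could not draw a feasible vertical chain")

    g = _trunc_normal(rng, *cell["Go_Gn"], lo=5.0)
    i_ang = _trunc_normal(rng, *cell["nasolabial_angle"], lo=20.0, hi=175.0)
    j_ang = _trunc_normal(rng, *cell["labiomental_angle"], lo=20.0, hi=179.0)
    l_ang = _trunc_normal(rng, *cell["gonial_angle"], lo=90.0, hi=178.0)
    n_ang = _trunc_normal(rng, *cell["soft_tissue_convexity"], lo=95.0, hi=178.0)

    # Midline chain.
    Gn = np.zeros(3)
    N = np.array([0.0, a, 0.0])
    y_sto = (a * a + c * c - e * e) / (2 * a)
    z_sto = np.sqrt(max(c * c - y_sto * y_sto, 0.0))
    Sto = np.array([0.0, y_sto, z_sto])
    u = (Sto - N) / e
    w_perp = np.array([0.0, u[2], -u[1]])
    if w_perp[2] < 0:
        w_perp = -w_perp
    t_sn = (b * b + e * e - d * d) / (2 * e)
    h_sn = np.sqrt(max(b * b - t_sn * t_sn, 0.0))
    Sn = N + t_sn * u + h_sn * w_perp

    # f and m jointly determine the pogonion; redraw the pair when the
    # solve is inconsistent (b sin m <= |f|) or lands outside the chin
    # region (extreme-tail draws make the near-degenerate solve explode).
    Pg = None
    for _ in range(200):
        f = _trunc_normal(rng, *cell["Sn_to_NPg"])
        m_ang = _trunc_normal(rng, *cell["facial_convexity"], lo=95.0, hi=178.0)
        if b * np.sin(np.radians(m_ang)) <= abs(f) + 0.05:
            continue
        try:
            cand = _place_pg(N, Sn, b, m_ang, f)
        except GenerationError:
            continue
        if np.linalg.norm(cand - Gn) <= 50.0 and np.linalg.norm(cand - Sn) <= 90.0:
            Pg = cand
            break
    if Pg is None:
        raise GenerationError("Sn offset inconsistent with facial convexity")
    PRn = _place_prn(N, Pg, n_ang, y_target=Sn[1] + 0.24 * (N[1] - Sn[1]))
    Cer = Gn + np.array([0.0, -35.0, -35.0])  # subhyoid point; Cer-Gn is the submental plane

    for _ in range(200):
        h = _trunc_normal(rng, *cell["Pg_to_NB"])
        k_ang = _trunc_normal(rng, *cell["lowerlip_submental_angle"], lo=60.0, hi=175.0)
        try:
            Bpt = _place_b(N, Pg, Cer, Gn, k_ang, h)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError("sublabiale placement failed repeatedly")

    v_bp = (Pg - Bpt) / np.linalg.norm(Pg - Bpt)
    li_dir = _rot_x(v_bp, -j_ang)
    if li_dir[2] < 0:
        li_dir = _rot_x(v_bp, j_ang)
    Li = Bpt + 9.0 * li_dir

    # Nasolabial pair about Sn, bisected by the anterior axis.
    zhat = np.array([0.0, 0.0, 1.0])
    C = Sn + 11.0 * _rot_x(zhat, -(i_ang / 2.0))  # superior ray (columella)
    Ls = Sn + 13.0 * _rot_x(zhat, i_ang / 2.0)  # inferior ray (upper lip)

    # Head norms; the remaining (nominal) landmarks come from the sized
    # template anchors so landmarks and head surface stay mutually
    # consistent (no local warp dimples at uncontrolled positions).
    H = _trunc_normal(rng, *norms_cfg["H"], lo=a + 40.0)
    Lnorm = _trunc_normal(rng, *norms_cfg["L"], lo=120.0)
    W = _trunc_normal(rng, *norms_cfg["W"], lo=110.0)
    AF = max(_trunc_normal(rng, *norms_cfg["AF"], lo=0.0), 0.0)
    AH = max(_trunc_normal(rng, *norms_cfg["AH"], lo=0.0), 0.0)

    tpl0 = _base_template(cfg.mesh_resolution)
    anchor = _anchor_lookup(tpl0, H, Lnorm, W)

    # Mandible: drawn Go-Gn length along the template's gonion direction;
    # the otobasion-inferius is the template's, rotated in its own plane so
    # the gonial angle is exactly the drawn value.
    a_go = anchor("Go-r")
    Go_r = Gn + g * a_go / np.linalg.norm(a_go)
    ray_gn = (Gn - Go_r) / np.linalg.norm(Gn - Go_r)
    T = anchor("OBi-r") - Go_r
    l0 = np.degrees(
        np.arccos(np.clip(T @ ray_gn / np.linalg.norm(T), -1.0, 1.0))
    )
    axis = np.cross(ray_gn, T)
    if np.linalg.norm(axis) < 1e-9:
        axis = np.cross(ray_gn, np.array([0.0, 1.0, 0.0]))
    OBi_r = None
    for sgn in (1.0, -1.0):
        cand = Go_r + _rodrigues(T, axis, sgn * (l_ang - l0))
        ang = np.degrees(
            np.arccos(
                np.clip(
                    (cand - Go_r)
                    @ ray_gn
                    / np.linalg.norm(cand - Go_r),
                    -1.0,
                    1.0,
                )
            )
        )
        if abs(ang - l_ang) < 1e-6:
            OBi_r = cand
            break
    if OBi_r is None:
        raise GenerationError("gonial angle could not be realised")

    lms = LandmarkSet()
    for lb, p in {
        "N": N, "Sn": Sn, "Sto": Sto, "Gn": Gn, "Pg": Pg, "PRn": PRn,
        "B": Bpt, "Li": Li, "Ls": Ls, "C": C, "Cer": Cer,
        "G": anchor("G"), "V": anchor("V"), "Op": anchor("Op"),
        "O": anchor("O"),
    }.items():
        lms[lb] = p
    right = {
        lb: anchor(lb)
        for lb in (
            "OBs-r", "L-r", "En-r", "Ex-r", "Ala-r", "Nb-r", "As-r",
            "Cph-r", "Ch-r",
        )
    }
    right["Go-r"] = Go_r
    right["OBi-r"] = OBi_r
    for lb, p in right.items():
        lms[lb] = p
        lms[lb[:-2] + "-l"] = p * np.array([-1.0, 1.0, 1.0])

    # Shift so the origin is the projected OBi midpoint (canonical origin).
    obi_mid = 0.5 * (lms["OBi-r"] + lms["OBi-l"])
    shift = np.array([0.0, obi_mid[1], obi_mid[2]])
    for lb in lms.labels():
        lms[lb] = lms[lb] - shift

    targets = {
        "N_Gn": a, "N_Sn": b, "Sto_Gn": c, "Sn_Sto": d, "N_Sto": e,
        "Sn_to_NPg": f, "Go_Gn": g, "Pg_to_NB": h,
        "nasolabial_angle": i_ang, "labiomental_angle": j_ang,
        "lowerlip_submental_angle": k_ang, "gonial_angle": l_ang,
        "facial_convexity": m_ang, "soft_tissue_convexity": n_ang,
    }
    norms = {"H": H, "L": Lnorm, "W": W, "AF": AF, "AH": AH}
    age = 9 + int(rng.random() < cfg.age_p10)

    mesh = None
    if with_mesh:
        mesh = _subject_mesh(lms, norms, cfg.mesh_resolution)
    return SubjectSample(cls, sex, age, lms, targets, norms, mesh)




_BASE_TEMPLATE_CACHE: dict = {}


def _base_template(resolution):
    key = tuple(resolution)
    if key not in _BASE_TEMPLATE_CACHE:
        _BASE_TEMPLATE_CACHE[key] = build_template(resolution[0], resolution[1])
    return _BASE_TEMPLATE_CACHE[key]


def _anchor_lookup(tpl0, H, Lnorm, W):
    """Template anchors sized to the drawn head norms, gnathion at origin.

    The y scale pins the vertex-to-gnathion anchor height to H; x and z
    scales pin the mesh extents to W and L.
    """
    from .io import ANATOMICAL_LABELS

    v = tpl0.mesh.vertices
    A = {lb: v[tpl0.anchors[lb]] for lb in ANATOMICAL_LABELS}
    H_t = A["V"][1] - A["Gn"][1]
    s = np.array([W / np.ptp(v[:, 0]), H / H_t, Lnorm / np.ptp(v[:, 2])])
    off = -(A["Gn"] * s)

    def anchor(lb):
        return A[lb] * s + off

    anchor.scale = s
    anchor.offset = off
    return anchor


def _subject_mesh(lms: LandmarkSet, norms: dict, resolution) -> HeadMesh:
    """Subject head surface: the template TPS-warped to the landmarks.

    The base template is sized to the drawn H/L/W extents, warped by a
    thin-plate spline pairing its 37 anatomical anchors with the generated
    landmarks (so the surface passes through them), re-pinned to the exact
    drawn width and length, and finally given an antisymmetric radial
    displacement about the canonical origin: left vertices move outward
    and right vertices inward by half the regional asymmetry magnitude, so
    matched left/right origin-distances differ by the configured AF/AH
    amounts while extents are preserved.
    """
    from .template import fit_tps, warp_points
    from .io import ANATOMICAL_LABELS

    H, Lnorm, W = norms["H"], norms["L"], norms["W"]
    tpl = _base_template(resolution)
    anchor = _anchor_lookup(tpl, H, Lnorm, W)
    # The same sizing used for the nominal landmarks, so most TPS controls
    # are fixed points and the warp only bends the parameter-driven face.
    v = tpl.mesh.vertices * anchor.scale + anchor.offset
    # Landmarks were shifted to the canonical origin after placement;
    # recover that shift from a nominal anchor-backed landmark.
    v = v + (lms["V"] - anchor("V"))

    src = np.array([v[tpl.anchors[lb]] for lb in ANATOMICAL_LABELS])
    tgt = np.array([lms[lb] for lb in ANATOMICAL_LABELS])
    warp = fit_tps(src, tgt, 0.0)
    v = warp_points(warp, v)
    # Re-pin width and length exactly (the warp perturbs them slightly).
    v[:, 0] *= W / np.ptp(v[:, 0])
    zmax = v[:, 2].max()
    v[:, 2] = (v[:, 2] - zmax) * (Lnorm / np.ptp(v[:, 2])) + zmax

    # Asymmetry injection: regional magnitudes from the AF/AH targets.
    # Displacement is along the outward surface normal with amplitude
    # t / (2 n.x) so each point's distance from the canonical origin moves
    # by exactly +-t/2; a normal (parallel-surface) offset keeps the
    # closest-point feet from sliding tangentially, so the pipeline reads
    # the configured magnitude.
    import trimesh as _tm

    af_t, ah_t = norms["AF"], norms["AH"]
    prn, gn = lms["PRn"], lms["Gn"]
    d_prn = np.linalg.norm(v - prn, axis=1)
    d_gn = np.linalg.norm(v - gn, axis=1)
    face = d_prn <= d_gn
    # Smooth facial blend (sigmoid over the signed bisector-plane distance)
    # and a taper to zero at the midsagittal seam: hard steps would make
    # the closest-point feet slide and dilute the measured magnitude.
    blend = 1.0 / (1.0 + np.exp((d_prn - d_gn) / 10.0))
    w = np.tanh(np.abs(v[:, 0]) / 12.0)
    off_mid = np.abs(v[:, 0]) > 1e-9
    # Amplitudes a_f, a_s such that the mean injected magnitude over the
    # facial region equals AF and over the whole head equals AH.
    sel_f = face & off_mid
    Ef_b = (blend * w)[sel_f].mean() if sel_f.any() else 1.0
    Ef_s = ((1 - blend) * w)[sel_f].mean() if sel_f.any() else 0.0
    Eh_b = (blend * w)[off_mid].mean()
    Eh_s = ((1 - blend) * w)[off_mid].mean()
    M = np.array([[Ef_b, Ef_s], [Eh_b, Eh_s]])
    try:
        a_f, a_s = np.linalg.solve(M, np.array([af_t, ah_t]))
    except np.linalg.LinAlgError:
        a_f = a_s = ah_t
    a_f, a_s = max(a_f, 0.0), max(a_s, 0.0)
    amp = (a_f * blend + a_s * (1 - blend)) * w
    normals = _tm.Trimesh(v, tpl.mesh.faces, process=False).vertex_normals
    xhat = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-9)
    cosang = np.clip(np.einsum("ij,ij->i", normals, xhat), 0.25, None)
    side = np.sign(v[:, 0])
    v = v + (side * amp / (2.0 * cosang))[:, None] * normals
    return HeadMesh(v, tpl.mesh.faces.copy())


def generate_cohort(
    cfg: CohortConfig | None = None,
    out_dir=None,
    with_meshes: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the full roster and (optionally) write it to disk.

    Returns a cohort table with one row per subject: id, class, sex, age,
    the 14 measured parameters (equal to the drawn targets by construction)
    and the drawn head norms / asymmetry targets.  With ``out_dir`` the
    roster CSV and per-subject landmark CSVs (and meshes) are written;
    identical seeds give byte-identical files.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "landmarks").mkdir(exist_ok=True)
        if with_meshes:
            (out_dir / "meshes").mkdir(exist_ok=True)

    rows = []
    subjects = []
    idx = 0
    for (cls, sex) in sorted(cfg.group_sizes):
        for _ in range(cfg.group_sizes[(cls, sex)]):
            idx += 1
            sid = f"S{idx:03d}"
            subj = generate_subject(cls, sex, cfg, rng, with_mesh=with_meshes)
            rec = subj.measurements()
            row = {"id": sid, "cls": cls, "sex": sex, "age": subj.age}
            row.update(rec.to_dict())
            row.update(subj.norms)
            rows.append(row)
            subjects.append(subj)
            if out_dir is not None:
                write_landmarks(subj.landmarks, out_dir / "landmarks" / f"{sid}.csv")
                if with_meshes:
                    write_mesh(subj.mesh, out_dir / "meshes" / f"{sid}.ply")
    df = pd.DataFrame(rows)
    df.attrs["subjects"] = subjects
    if out_dir is not None:
        roster = df[["id", "cls", "sex", "age"]].copy()
        roster.to_csv(out_dir / "roster.csv", index=False)
        df.to_csv(out_dir / "cohort.csv", index=False, float_format="%.6f")
    return df


def simulate_raters(
    lms: LandmarkSet,
    n_raters: int = 2,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
):
    """Independent raters as isotropic Gaussian landmark perturbations.

    Returns ``(landmark_sets, measurement_records)``, one per rater; with
    zero noise every rater reproduces the subject exactly.
    """
    if noise_sd < 0:
        raise GenerationError("noise SD must be non-negative")
    rng = rng or np.random.default_rng()
    sets, records = [], []
    for _ in range(n_raters):
        pert = lms.copy()
        for lb in pert.labels():
            pert[lb] = pert[lb] + rng.normal(0.0, noise_sd, 3)
        sets.append(pert)
        records.append(measure_subject(pert))
    return sets, records


def reliability_study(
    cfg: CohortConfig | None = None,
    n_subjects: int = 31,
    n_raters: int = 2,
    noise_ratio: float = 0.25,
    cls: str = "I",
    sex: str = "M",
    rng: np.random.Generator | None = None,
    mode: str = "parameter",
) -> dict[str, float]:
    """Inter-rater agreement emulation: ICC(2,1) per parameter.

    ``mode='parameter'`` adds per-parameter measurement noise with SD equal
    to ``noise_ratio`` times the configured between-subject SD — the direct
    reading of 'rater noise at 25% of SD'.  ``mode='landmark'`` perturbs
    landmark positions by ``noise_ratio`` mm isotropically and re-measures,
    which propagates differently into each parameter.
    """
    from .stats import icc_agreement

    cfg = cfg or CohortConfig()
    rng = rng or np.random.default_rng()
    cell = cfg.params[cls][sex]
    params = list(cell)
    iccs = {}
    if mode == "parameter":
        for p in params:
            mu, sd = cell[p]
            truth = rng.normal(mu, sd, n_subjects)
            ratings = truth[:, None] + rng.normal(
                0.0, noise_ratio * sd, (n_subjects, n_raters)
            )
            iccs[p] = icc_agreement(ratings)
    elif mode == "landmark":
        ratings = {p: np.empty((n_subjects, n_raters)) for p in params}
        for s in range(n_subjects):
            subj = generate_subject(cls, sex, cfg, rng)
            _, recs = simulate_raters(subj.landmarks, n_raters, noise_ratio, rng)
            for p in params:
                for r, rec in enumerate(recs):
                    ratings[p][s, r] = getattr(rec, p)
        for p in params:
            iccs[p] = icc_agreement(ratings[p])
    else:
        raise GenerationError(f"unknown reliability mode {mode!r}")
    return iccs
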