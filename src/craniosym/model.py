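"""Model/Results front-end for the per-subject fit and the cohort analysis.

Two statsmodels-style entry points wrap the functional layers:

* :class:`AsymmetryModel` — fit the symmetric template to one subject
  (scale, thin-plate-spline warp on paired landmarks, closest-point
  correspondence) and score asymmetry.  ``fit()`` returns an
  :class:`AsymmetryResults` with AH/AF, head metrics and a ``summary()``.
* :class:`CohortModel` — the statistics layer over a cohort table;
  ``fit()`` returns a :class:`CohortResults` carrying the class-by-sex
  group summaries, pairwise and omnibus p values and the roster
  distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asymmetry as asym
from . import stats as cstats
from .errors import CraniosymError
from .io import HeadMesh, LandmarkSet, apply_frame, estimate_canonical_frame
from .template import (
    SymmetricTemplate,
    build_template,
    closest_point_map,
    fit_tps,
    scale_template,
    warp_points,
)

__all__ = ["AsymmetryModel", "AsymmetryResults", "CohortModel", "CohortResults"]


class AsymmetryModel:
    """Symmetric-template asymmetry fit for a single subject.

    Parameters
    ----------
    mesh : HeadMesh
        Subject head surface (canonical frame, or raw with ``align=True``).
    landmarks : LandmarkSet
        The 37 anatomical landmarks of the subject.
    template : SymmetricTemplate, optional
        Analysis template; built at default resolution when omitted.
    tps_lambda : float
        TPS regularisation (0 = exact landmark interpolation).
    iterations : int
        Closest-point passes; the method is single-pass by design, extra
        iterations re-project the deformed template.
    align : bool
        Estimate the canonical frame from the landmarks and transform both
        inputs before fitting.
    """

    def __init__(
        self,
        mesh: HeadMesh,
        landmarks: LandmarkSet,
        template: SymmetricTemplate | None = None,
        tps_lambda: float = 0.0,
        iterations: int = 1,
        align: bool = False,
        point_to_point: bool = False,
    ):
        if align:
            frame = estimate_canonical_frame(landmarks)
            mesh = apply_frame(mesh, frame)
            landmarks = apply_frame(landmarks, frame)
        self.mesh = mesh
        self.landmarks = landmarks
        self.template = template or build_template()
        self.tps_lambda = tps_lambda
        self.iterations = max(int(iterations), 1)
        self.point_to_point = point_to_point

    def fit(self) -> "AsymmetryResults":
        lms = asym.layer_landmarks(self.mesh, self.landmarks)
        tpl_s = scale_template(self.template, lms)
        labels = list(self.template.anchors)
        src = np.array([tpl_s.mesh.vertices[tpl_s.anchors[lb]] for lb in labels])
        tgt = np.array([lms[lb] for lb in labels])
        warp = fit_tps(src, tgt, self.tps_lambda)
        warped = warp_points(warp, tpl_s.mesh.vertices)
        corr = closest_point_map(warped, self.mesh)
        for _ in range(self.iterations - 1):
            corr = closest_point_map(corr.points, self.mesh)
        pairs = asym.pointwise_asymmetry(
            corr, self.template, origin=(0.0, 0.0, 0.0),
            point_to_point=self.point_to_point,
        )
        mask = asym.facial_region(warped, lms["PRn"], lms["Gn"])
        AH, AF = asym.summarize(pairs, mask)
        metrics = asym.head_metrics(self.mesh, lms)
        result = asym.AsymmetryResult(pairs, mask, AH, AF, metrics)
        return AsymmetryResults(
            model=self, warp=warp, correspondence=corr,
            warped_vertices=warped, result=result, layered_landmarks=lms,
        )


@dataclass
class AsymmetryResults:
    """Fitted template correspondence and asymmetry scores."""

    model: AsymmetryModel
    warp: object
    correspondence: object
    warped_vertices: np.ndarray
    result: asym.AsymmetryResult
    layered_landmarks: LandmarkSet

    @property
    def AH(self) -> float:
        return self.result.AH

    @property
    def AF(self) -> float:
        return self.result.AF

    @property
    def metrics(self) -> asym.HeadMetrics:
        return self.result.metrics

    def export_heatmap(self, path, **kw):
        return asym.export_heatmap(self.model.template, self.result.pairs, path, **kw)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Craniofacial asymmetry fit",
            "=" * 42,
            f"template vertices     {len(self.model.template.mesh.vertices):>10d}",
            f"mean fit residual (mm){self.correspondence.distances.mean():>10.3f}",
            f"AH  whole-head (mm)   {self.AH:>10.3f}",
            f"AF  facial (mm)       {self.AF:>10.3f}",
            f"H   height (mm)       {m.H:>10.2f}",
            f"L   length (mm)       {m.L:>10.2f}",
            f"W   width (mm)        {m.W:>10.2f}",
            f"V   volume (cm^3)     {m.V:>10.1f}",
        ]
        return "\n".join(lines)


class CohortModel:
    """Statistics layer over a cohort table.

    The table needs columns ``id, cls, sex, age`` plus measurement columns
    (the 14 parameters, and head/asymmetry metrics when available).
    """

    def __init__(self, data: pd.DataFrame, t_variant: str = "pooled"):
        required = {"id", "cls", "sex"}
        if not required.issubset(data.columns):
            raise CraniosymError(f"cohort table needs columns {sorted(required)}")
        self.data = data.reset_index(drop=True)
        self.t_variant = t_variant

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "CohortModel":
        return cls(df, **kw)

    @classmethod
    def from_synthetic(cls, config=None, rng=None, **kw) -> "CohortModel":
        from .synthetic import generate_cohort

        return cls(generate_cohort(config, rng=rng), **kw)

    def fit(self, parameters=None) -> "CohortResults":
        summary = cstats.summarize_cohort(
            self.data, parameters=parameters, variant=self.t_variant
        )
        dist = cstats.class_distribution(self.data)
        return CohortResults(self, summary, dist)


@dataclass
class CohortResults:
    """Group summaries, test p values and the roster distribution."""

    model: CohortModel
    group_summary: cstats.GroupSummary
    distribution: pd.DataFrame

    def summary(self, decimals: int = 2) -> str:
        out = ["Cohort summary", "=" * 60, "Roster:"]
        out.append(self.distribution.to_string(index=False))
        out.append("")
        out.append("Group means (mean ± SD by class; p values vs class):")
        out.append(
            self.group_summary.formatted(decimals).to_string(index=False)
        )
        return "\n".join(out)

    def to_tables(self, out_dir) -> dict:
        """Write roster / group-summary CSVs shaped like the study tables."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out_dir / "table_roster.csv"
        self.distribution.to_csv(p, index=False)
        paths["roster"] = p
        formatted = self.group_summary.formatted()
        p = out_dir / "table_groups.csv"
        formatted.to_csv(p, index=False)
        paths["groups"] = p
        p = out_dir / "table_groups_raw.csv"
        self.group_summary.table.to_csv(p, float_format="%.6f")
        paths["groups_raw"] = p
        return paths
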