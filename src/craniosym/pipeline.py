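"""End-to-end orchestration: simulate -> align -> measure -> correspond ->
asymmetry -> statistics -> tables and heat maps, reproducible from a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anthropometry import measure_subject
from .asymmetry import HEAT_SCALE_MM, export_heatmap
from .errors import CraniosymError
from .io import apply_frame, estimate_canonical_frame
from .model import AsymmetryModel, CohortModel
from .synthetic import CohortConfig, generate_subject
from .template import build_template

log = logging.getLogger("craniosym")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    out_dir: str | Path = "runs/craniosym"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int | None = 0
    with_meshes: bool = True
    template_resolution: tuple[int, int] = (48, 32)
    t_variant: str = "pooled"  # or "welch"
    icc_form: str = "ICC2"
    tps_lambda: float = 0.0
    iterations: int = 1
    heat_scale: tuple[float, float] = HEAT_SCALE_MM
    render_pngs: bool = False
    log_level: str = "INFO"

    def digest(self) -> str:
        payload = json.dumps(
            {
                k: str(v)
                for k, v in self.__dict__.items()
                if k not in ("cohort", "out_dir")
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full study pipeline; returns the run directory.

    Outputs: per-subject measurement CSV, cohort table, roster/group
    summary tables, per-class mean asymmetry heat-map PLYs, and a manifest
    recording the seed, package version and configuration hash.  Any stage
    failure aborts with the stage named; partial outputs are retained.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stages: dict[str, float] = {}
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        log.info("stage %s", name)
        stages[name] = time.time()

    try:
        stage("simulate")
        rows = []
        subjects = []
        idx = 0
        for (cls, sex) in sorted(cfg.cohort.group_sizes):
            for _ in range(cfg.cohort.group_sizes[(cls, sex)]):
                idx += 1
                subj = generate_subject(
                    cls, sex, cfg.cohort, rng, with_mesh=cfg.with_meshes
                )
                subjects.append((f"S{idx:03d}", subj))
    except Exception as exc:
        raise CraniosymError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("measure")
        for sid, subj in subjects:
            frame = estimate_canonical_frame(subj.landmarks)
            lms = apply_frame(subj.landmarks, frame)
            rec = measure_subject(lms)
            row = {"id": sid, "cls": subj.cls, "sex": subj.sex, "age": subj.age}
            row.update(rec.to_dict())
            rows.append(row)
    except Exception as exc:
        raise CraniosymError(f"stage 'measure' failed: {exc}") from exc

    df = pd.DataFrame(rows)

    template = None
    if cfg.with_meshes:
        try:
            stage("asymmetry")
            template = build_template(*cfg.template_resolution)
            heat_sum: dict[str, np.ndarray] = {}
            heat_n: dict[str, int] = {}
            for (sid, subj), row in zip(subjects, rows):
                frame = estimate_canonical_frame(subj.landmarks)
                mesh = apply_frame(subj.mesh, frame)
                lms = apply_frame(subj.landmarks, frame)
                res = AsymmetryModel(
                    mesh,
                    lms,
                    template=template,
                    tps_lambda=cfg.tps_lambda,
                    iterations=cfg.iterations,
                ).fit()
                row.update(
                    {
                        "AH": res.AH,
                        "AF": res.AF,
                        "H": res.metrics.H,
                        "L": res.metrics.L,
                        "W": res.metrics.W,
                        "V": res.metrics.V,
                    }
                )
                vv = res.result.vertex_values
                heat_sum[subj.cls] = heat_sum.get(subj.cls, 0.0) + vv
                heat_n[subj.cls] = heat_n.get(subj.cls, 0) + 1
            df = pd.DataFrame(rows)
            for cls_name, total in heat_sum.items():
                mean_vals = total / heat_n[cls_name]
                pairs = _pairs_from_vertex_values(template, mean_vals)
                ply = out / f"heatmap_class_{cls_name}.ply"
                export_heatmap(template, pairs, ply, scale=cfg.heat_scale)
                if cfg.render_pngs:
                    from .asymmetry import render_views

                    render_views(
                        template.mesh, mean_vals, out / f"heatmap_class_{cls_name}"
                    )
        except CraniosymError:
            raise
        except Exception as exc:
            raise CraniosymError(f"stage 'asymmetry' failed: {exc}") from exc

    try:
        stage("stats")
        results = CohortModel(df, t_variant=cfg.t_variant).fit()
        df.to_csv(out / "cohort.csv", index=False, float_format="%.6f")
        results.to_tables(out)
        (out / "summary.txt").write_text(results.summary())
    except Exception as exc:
        raise CraniosymError(f"stage 'stats' failed: {exc}") from exc

    manifest = {
        "package": "craniosym",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_subjects": len(subjects),
        "with_meshes": cfg.with_meshes,
        "stages": list(stages),
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s (%.1fs)", out, manifest["runtime_s"])
    return out


def _pairs_from_vertex_values(template, vertex_values):
    """Rebuild a PairwiseAsymmetry view from per-vertex mean values."""
    from .asymmetry import PairwiseAsymmetry

    reps = template.left_pairs()
    partners = template.mirror[reps]
    return PairwiseAsymmetry(reps, partners, vertex_values[reps])
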