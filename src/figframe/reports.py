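"""Pipeline composition, mean frames, and static report generation.

``run_pipeline`` ties the stages together: read (or simulate) pointing
records, assemble the seven per-paradigm frames per subject, write the
descriptor table, run the comparison plans, and emit a static report
(CSV tables, SVG frame overlays, a Markdown summary) with a provenance
block (package version, seed, full configuration) alongside every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .frames import FigureFrame, FrameAssemblyError, frames_from_records, ideal_frame
from .io import (
    PERIMETER_ORDER,
    Paradigm,
    PointingRecord,
    SubjectMeta,
    meta_table,
    read_pointing_table,
)
from .morphometry import DescribeConfig, describe_cohort
from .stats import (
    ComparisonPlan,
    cognition_plan,
    compare_cohort,
    sex_area_plan,
    DEFAULT_SEED,
)

__all__ = [
    "RunConfig",
    "mean_frame",
    "frames_to_csv",
    "frames_to_svg",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def mean_frame(frames: Sequence[FigureFrame]) -> FigureFrame:
    """Vertex-wise arithmetic mean of label-aligned frames.

    All frames must share one paradigm; vertices are averaged per target
    label in planar coordinates (matching polygon-overlay group figures),
    never on rasters.
    """
    if not frames:
        raise FrameAssemblyError("need at least one frame")
    paradigms = {f.paradigm for f in frames}
    if len(paradigms) != 1:
        raise FrameAssemblyError(
            f"frames span paradigms {sorted(p.value if p else 'None' for p in paradigms)}"
        )
    verts = np.mean([f.vertices for f in frames], axis=0)
    centers = [f.center_point for f in frames]
    center = (
        tuple(np.mean([np.asarray(c) for c in centers], axis=0))
        if all(c is not None for c in centers)
        else None
    )
    return FigureFrame(
        f"mean(n={len(frames)})",
        frames[0].paradigm,
        verts,
        center,
        all(f.complete for f in frames),
    )


def frames_to_csv(frames: Sequence[FigureFrame], path: str | Path) -> Path:
    """Vertex table: one row per frame x perimeter target."""
    rows = []
    for f in frames:
        for i, t in enumerate(PERIMETER_ORDER):
            rows.append(
                {
                    "subject_id": f.subject_id,
                    "paradigm": f.paradigm.value if f.paradigm else None,
                    "target": t.value,
                    "x": f.vertices[i, 0],
                    "y": f.vertices[i, 1],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


_SVG_COLORS = ("#006d77", "#9d0208", "#7b2cbf", "#e85d04", "#2b9348")


def frames_to_svg(
    frames: Sequence[FigureFrame],
    path: str | Path,
    show_ideal: bool = True,
    extent: float = 1.2,
    size_px: int = 500,
) -> Path:
    """Plain-SVG overlay of frame polygons (plus the ideal frame, dashed)."""
    s = size_px / (2.0 * extent)

    def xy(v):
        return f"{(v[0] + extent) * s:.2f},{(extent - v[1]) * s:.2f}"

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size_px}"'
        f' height="{size_px}" viewBox="0 0 {size_px} {size_px}">',
        f'<rect width="{size_px}" height="{size_px}" fill="white"/>',
    ]
    if show_ideal:
        pts = " ".join(xy(v) for v in ideal_frame().vertices)
        parts.append(
            f'<polygon points="{pts}" fill="none" stroke="#888"'
            ' stroke-dasharray="6 4" stroke-width="1.5"/>'
        )
    for i, f in enumerate(frames):
        verts = f.vertices[~np.isnan(f.vertices).any(axis=1)]
        pts = " ".join(xy(v) for v in verts)
        color = _SVG_COLORS[i % len(_SVG_COLORS)]
        parts.append(
            f'<polygon points="{pts}" fill="{color}" fill-opacity="0.08"'
            f' stroke="{color}" stroke-width="1.5"><title>{f.subject_id}'
            f"</title></polygon>"
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
    return Path(path)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    input_path: str | Path
    output_dir: str | Path
    canvas_px: int = 2000
    extent: float = 1.2
    fill_rule: str = "even_odd"
    avg_diameter_method: str = "caliper"
    strict: bool = True
    plans: tuple[ComparisonPlan, ...] | None = None
    n_boot: int = 1000
    seed: int = DEFAULT_SEED
    make_figures: bool = True


def _provenance(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (Path, Paradigm)):
            return str(obj)
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return {
        "package": "figframe",
        "version": __version__,
        "seed": config.seed,
        "config": enc(config),
    }


def run_pipeline(
    config: RunConfig,
    records: Sequence[PointingRecord] | None = None,
    meta: Sequence[SubjectMeta] | None = None,
) -> dict[str, Path]:
    """Run frames -> descriptors -> comparisons -> report.

    Records/meta may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.input_path``.  Returns a mapping
    of artifact names to paths.  Outputs are deterministic given the
    configuration and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if records is None:
        records, meta = read_pointing_table(config.input_path, strict=config.strict)
    meta = list(meta or [])

    frames = frames_from_records(records, strict=config.strict)
    artifacts["frames_csv"] = frames_to_csv(frames, out / "frames.csv")

    desc_config = DescribeConfig(
        canvas_px=config.canvas_px,
        extent=config.extent,
        fill_rule=config.fill_rule,
        avg_diameter_method=config.avg_diameter_method,
    )
    descriptors = describe_cohort(frames, desc_config)
    desc_path = out / "descriptors.csv"
    descriptors.to_csv(desc_path, index=False)
    artifacts["descriptors_csv"] = desc_path

    plans = config.plans
    if plans is None:
        plans = (
            sex_area_plan(n_boot=config.n_boot),
            cognition_plan(n_boot=config.n_boot),
        )
    mdf = meta_table(meta)
    results = []
    for plan in plans:
        try:
            results.append(compare_cohort(descriptors, mdf, plan, seed=config.seed))
        except ValueError as exc:
            logger.warning("plan %s skipped: %s", plan.name, exc)
    if results:
        res_df = pd.concat(results, ignore_index=True)
        res_path = out / "comparisons.csv"
        res_df.to_csv(res_path, index=False)
        artifacts["comparisons_csv"] = res_path
    else:
        res_df = pd.DataFrame()

    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(_provenance(config), indent=1, default=str))
    artifacts["provenance_json"] = prov_path

    if config.make_figures and meta:
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        groups = {(m.cognition, m.sex) for m in meta}
        by_subject = {m.subject_id: m for m in meta}
        for paradigm in sorted({f.paradigm for f in frames}, key=lambda p: p.order_index):
            pframes = [f for f in frames if f.paradigm is paradigm and f.complete]
            means = []
            for cognition, sex in sorted(groups):
                members = [
                    f
                    for f in pframes
                    if f.subject_id in by_subject
                    and by_subject[f.subject_id].cognition == cognition
                    and by_subject[f.subject_id].sex == sex
                ]
                if members:
                    mf = mean_frame(members)
                    mf = FigureFrame(
                        f"{cognition}/{sex} (n={len(members)})",
                        mf.paradigm,
                        mf.vertices,
                        mf.center_point,
                        mf.complete,
                    )
                    means.append(mf)
            if means:
                frames_to_svg(
                    means,
                    figdir / f"mean_frames_{paradigm.value}.svg",
                    extent=config.extent,
                )
        artifacts["figures_dir"] = figdir

    report = [
        "# Figure-frame analysis report",
        "",
        f"- package: figframe {__version__}",
        f"- seed: {config.seed}",
        f"- canvas: {config.canvas_px} px, extent ±{config.extent} (tangent units)",
        f"- subjects: {len({r.subject_id for r in records})},"
        f" frames: {len(frames)}",
        "",
        "## Artifacts",
        "",
    ]
    report += [f"- `{name}`: {p.name}" for name, p in artifacts.items()]
    if len(res_df):
        report += [
            "",
            "## Comparisons",
            "",
            res_df.to_string(index=False),
        ]
    rpt_path = out / "report.md"
    rpt_path.write_text("\n".join(report) + "\n")
    artifacts["report_md"] = rpt_path
    return artifacts
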