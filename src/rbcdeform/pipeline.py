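"""End-to-end workflow: simulate -> analyze images -> summarize -> correlate -> report.

A :class:`RunConfig` names the stages to run and their parameters; outputs
land in one directory together with a manifest (tool version, config hash,
seed, per-stage row counts) so a run can be reproduced exactly from its
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deformability import DEFAULT_ND_CUTOFF, er_histogram, pool, summarize
from .errors import InputError, RBCDeformError
from .imaging import SegParams, analyze_field
from .lfq import write_cohort_csv
from .model import MembraneHbDeformability
from .presets import DEFAULT_PRESET, load_preset
from .synthimage import load_field, render_field, save_field
from .synthlfq import generate_lfq_cohort, scale_counts

__all__ = ["RunConfig", "run_pipeline", "make_report", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate-images",
    "analyze-images",
    "summarize",
    "simulate-lfq",
    "correlate",
    "report",
)

RECORD_COLUMNS = [
    "field_id", "label", "x", "y", "area_px", "a", "b", "er",
    "orientation_deg", "qc",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    preset: str = DEFAULT_PRESET
    n_fields: int = 25
    n_samples: int | None = None  # None: preset's own cohort size
    nd_cutoff: float = DEFAULT_ND_CUTOFF
    images_dir: str | None = None  # analyze existing images instead of simulating
    cohort_csv: str | None = None  # correlate an existing cohort instead of simulating
    field_overrides: dict = field(default_factory=dict)
    seg_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise InputError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _field_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _records_frame(per_field: dict[str, list]) -> pd.DataFrame:
    rows = []
    for field_id, records in per_field.items():
        for r in records:
            rows.append(
                {
                    "field_id": field_id, "label": r.label, "x": r.x, "y": r.y,
                    "area_px": r.area_px, "a": r.a, "b": r.b, "er": r.er,
                    "orientation_deg": r.orientation_deg,
                    "qc": ";".join(sorted(r.qc)),
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = load_preset(config.preset)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    current = None
    try:
        records_df = None
        cohort_path = None
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            current = stage
            if stage == "simulate-images":
                img_dir = outdir / "images"
                img_dir.mkdir(exist_ok=True)
                n_cells_total = 0
                for i, s in enumerate(_field_seeds(config.seed, config.n_fields)):
                    spec = preset.field_spec(seed=s, **config.field_overrides)
                    image, truths = render_field(spec)
                    save_field(
                        image, truths,
                        img_dir / f"field_{i:03d}.tif",
                        img_dir / f"field_{i:03d}_truth.csv",
                    )
                    n_cells_total += len(truths)
                manifest["stages"][stage] = {
                    "n_fields": config.n_fields, "n_cells": n_cells_total,
                }
            elif stage == "analyze-images":
                src = Path(config.images_dir) if config.images_dir else outdir / "images"
                if not src.is_dir():
                    raise InputError(f"image directory does not exist: {src}")
                seg = SegParams(**config.seg_overrides)
                per_field = {}
                for path in sorted(src.glob("*.tif")) + sorted(src.glob("*.png")):
                    per_field[path.stem] = analyze_field(load_field(path), seg)
                records_df = _records_frame(per_field)
                records_df.to_csv(outdir / "records.csv", index=False)
                manifest["stages"][stage] = {"n_records": len(records_df)}
            elif stage == "summarize":
                if records_df is None:
                    rec_path = outdir / "records.csv"
                    if not rec_path.exists():
                        raise InputError(f"records file does not exist: {rec_path}")
                    records_df = pd.read_csv(rec_path, keep_default_na=False)
                ok = records_df[records_df["qc"].astype(str) == ""]
                fields = [
                    grp["er"].to_numpy() for _, grp in ok.groupby("field_id")
                ]
                summary = pool(
                    [summarize(f, nd_cutoff=config.nd_cutoff) for f in fields]
                )
                (outdir / "er_summary.json").write_text(
                    json.dumps(summary.to_dict(), indent=2)
                )
                counts, edges = er_histogram(
                    ok["er"].to_numpy(), bin_width=0.05
                )
                _plot_histogram(counts, edges, outdir / "er_hist.png")
                manifest["stages"][stage] = {"n_cells": summary.n_cells}
            elif stage == "simulate-lfq":
                spec = preset.cohort
                if config.n_samples is not None:
                    spec = scale_counts(spec, config.n_samples)
                spec = replace(spec, seed=config.seed)
                table, aer = generate_lfq_cohort(spec)
                cohort_path = outdir / "cohort.csv"
                write_cohort_csv(cohort_path, table, aer)
                manifest["stages"][stage] = {"n_samples": table.n_samples}
            elif stage == "correlate":
                path = Path(config.cohort_csv) if config.cohort_csv else cohort_path
                if path is None or not Path(path).exists():
                    raise InputError(f"cohort file does not exist: {path}")
                results = MembraneHbDeformability.from_cohort_csv(path).fit()
                tables = outdir / "tables"
                tables.mkdir(exist_ok=True)
                results.abundance.to_csv(tables / "abundance.csv")
                results.subunit_corr.r.to_csv(tables / "subunit_corr_r.csv")
                results.subunit_corr.p.to_csv(tables / "subunit_corr_p.csv")
                results.subunit_corr.tier.to_csv(tables / "subunit_corr_tier.csv")
                if results.screen is not None:
                    results.screen_frame().to_csv(tables / "deformability_screen.csv")
                if results.groups is not None:
                    results.groups_frame().to_csv(tables / "group_contrast.csv")
                (outdir / "model_summary.txt").write_text(results.summary() + "\n")
                manifest["stages"][stage] = {
                    "n_samples": results.model.lfq.n_samples,
                }
            elif stage == "report":
                report_path = make_report(outdir)
                manifest["stages"][stage] = {"report": report_path.name}
        manifest["status"] = "success"
    except RBCDeformError as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RBCDeformError(f"stage '{current}' failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plot_histogram(counts, edges, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="#a03030", edgecolor="white", linewidth=0.3)
    ax.set_xlabel("elongation ratio ER")
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report(outdir) -> Path:
    """Assemble a markdown report from whatever outputs are present."""
    outdir = Path(outdir)
    lines = ["# RBC deformability / membrane-bound Hb report", ""]
    missing = []

    summary_path = outdir / "er_summary.json"
    if summary_path.exists():
        s = json.loads(summary_path.read_text())
        lines += [
            "## Deformability (pooled over fields)", "",
            f"- cells: {s['n_cells']} across {s['n_fields']} fields",
            f"- AER: {s['aer']:.3f} (SD {s['sd']:.3f}, median {s['median_er']:.3f})",
            f"- non-deformable fraction (ER < {s['nd_cutoff']}): "
            f"{s['frac_nondeformable']:.3f}",
            "",
        ]
        if (outdir / "er_hist.png").exists():
            lines += ["![ER distribution](er_hist.png)", ""]
    else:
        missing.append(str(summary_path.name))

    tables = outdir / "tables"
    named = [
        ("abundance.csv", "Subunit abundance, Ln(LFQ)"),
        ("subunit_corr_r.csv", "Inter-subunit correlation matrix (r)"),
        ("group_contrast.csv", "Fresh vs stored contrast"),
        ("deformability_screen.csv", "Deformability screen (subunit vs AER)"),
    ]
    for fname, title in named:
        path = tables / fname
        if path.exists():
            df = pd.read_csv(path)
            lines += [f"## {title}", "", df.to_markdown(index=False), ""]
        else:
            missing.append(f"tables/{fname}")
    if missing:
        lines += ["## Missing outputs", ""] + [f"- {m}" for m in missing] + [""]
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
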