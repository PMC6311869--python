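"""End-to-end orchestration: simulate -> gate -> score -> compare -> render.

Two execution modes:

``summary``
    Compare cohorts directly from the transcribed published summary
    statistics (deterministic; the reference path for reproducing printed
    p-values).

``simulation``
    Generate event-level cohorts from the presets, gate them with the
    builtin panels, compute per-animal percentages (plus the exhaustion
    score for the lymphoid panels and the macrophage profile for the
    myeloid panel), then summarize and compare.

All randomness flows from ``RunConfig.seed``; a manifest records seeds and
conventions so a rerun with the same config produces identical artifacts.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__ as _pkg_version
from .exceptions import ConfigurationError, PipelineError
from .gating import apply_gate_tree, builtin_panels, results_by_label
from .presets import TCES_LABEL, builtin_cohort_presets, get_panel
from .stats import (
    ComparisonResult,
    GroupSummary,
    MacrophageProfile,
    TCESInputs,
    bonferroni_threshold,
    compare_group_summaries,
    compare_panels,
    compute_tces,
    m1m2_ratio,
    round_sig,
)
from .synthetic import CohortSpec, EventTable, generate_cohort

__all__ = [
    "RunConfig",
    "ReportTable",
    "run_pipeline",
    "render_table",
    "report_rows_from_csv",
    "animal_percentages",
    "tces_from_percentages",
    "simulate_cohort_percentages",
]

logger = logging.getLogger("immunoflow")

RENDER_FORMATS = ("csv", "json", "markdown")
M1M2_LABEL = "M1:M2 ratio"

_CSV_COLUMNS = [
    "population",
    "mean_a", "sd_a", "n_a",
    "mean_b", "sd_b", "n_b",
    "t", "df", "p_value", "corrected_alpha", "significant",
]


@dataclass(frozen=True)
class RunConfig:
    panels: tuple[str, ...]
    cohort_a: str
    cohort_b: str
    mode: str = "summary"
    seed: int = 0
    output_dir: str | Path | None = None
    events_per_animal: int | None = None
    basis: str = "parent"
    rounding: int = 4
    formats: tuple[str, ...] = ("csv", "json", "markdown")
    sampling: str = "quantile"
    assignment: str = "exact"
    write_events: bool = False

    def __post_init__(self) -> None:
        if not self.panels:
            raise ConfigurationError("at least one panel is required")
        if self.cohort_a == self.cohort_b:
            raise ConfigurationError("a comparison needs two distinct cohorts")
        if self.mode not in ("summary", "simulation"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.basis not in ("parent", "root"):
            raise ConfigurationError(f"unknown basis {self.basis!r}")
        for fmt in self.formats:
            if fmt not in RENDER_FORMATS:
                raise ConfigurationError(f"unknown render format {fmt!r}")


@dataclass(frozen=True)
class ReportTable:
    """One rendered comparison table (rows = one Bonferroni family)."""

    title: str
    rows: tuple[ComparisonResult, ...]
    footnote: str
    family_size: int
    corrected_alpha: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) != self.family_size:
            raise ConfigurationError(
                f"report has {len(self.rows)} rows but family size {self.family_size}"
            )


# ---------------------------------------------------------------------------
# Per-animal scoring
# ---------------------------------------------------------------------------

def animal_percentages(
    events: EventTable,
    panel: str,
    thresholds=None,
    basis: str = "parent",
) -> dict[str, float]:
    """Gate one animal with a builtin panel; percentages on the chosen basis."""
    tree = builtin_panels(thresholds)[panel]
    results = results_by_label(apply_gate_tree(events, tree))
    attr = "pct_of_parent" if basis == "parent" else "pct_of_root"
    return {label: getattr(r, attr) for label, r in results.items()}


def tces_from_percentages(pcts: Mapping[str, float]) -> float:
    """Exhaustion score from a gated percentage table (lymphoid panels)."""
    inputs = TCESInputs(
        pct_PD1_CTL=pcts["PD-1+ CTLs"],
        pct_Tim3_CTL=pcts["Tim-3+ CTLs"],
        pct_PD1_Th=pcts["PD-1+ Ths"],
        pct_Tim3_Th=pcts["Tim-3+ Ths"],
        pct_CTL=pcts["CTLs"],
        pct_Th=pcts["Ths"],
    )
    return compute_tces(inputs)


def macrophage_profile_from_percentages(pcts: Mapping[str, float]) -> MacrophageProfile:
    return MacrophageProfile(
        pct_Tgm2=pcts["Tgm2+ macrophages"],
        pct_Arg1=pcts["Arg1+ macrophages"],
        pct_Cxcl9=pcts["Cxcl9+ macrophages"],
        pct_Nos2=pcts["Nos2+ macrophages"],
    )


def simulate_cohort_percentages(
    spec: CohortSpec,
    events_per_animal: int | None = None,
    assignment: str = "exact",
    basis: str = "parent",
    keep_events: bool = False,
):
    """Simulate, gate, and score one cohort.

    Returns ``(per_row, per_animal, events)`` where ``per_row`` maps each
    report-row label to per-animal values (including derived scores) and
    ``per_animal`` is the full gated percentage table per animal.
    ``events`` is None unless ``keep_events``.
    """
    definition = get_panel(spec.panel)
    tables = generate_cohort(
        spec, assignment=assignment, events_per_animal=events_per_animal
    )
    per_animal: list[dict[str, float]] = []
    for table in tables:
        logger.info("gate: cohort=%s panel=%s animal=%s", spec.cohort_label, spec.panel, table.animal_id)
        pcts = animal_percentages(table, spec.panel, basis=basis)
        if TCES_LABEL in definition.report_rows:
            pcts[TCES_LABEL] = tces_from_percentages(pcts)
        if spec.panel == "4":
            try:
                pcts[M1M2_LABEL] = m1m2_ratio(macrophage_profile_from_percentages(pcts))
            except Exception:
                pcts[M1M2_LABEL] = float("nan")
        per_animal.append(pcts)
    per_row = {
        label: [pcts[label] for pcts in per_animal] for label in definition.report_rows
    }
    return per_row, per_animal, (tables if keep_events else None)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _derived_seed(seed: int, *parts: str) -> int:
    text = ":".join((str(seed),) + parts)
    return zlib.crc32(text.encode("utf-8"))


def _summary_table(spec: CohortSpec, rows: Sequence[str]) -> dict[str, GroupSummary]:
    out = {}
    for label in rows:
        if label in spec.population_stats:
            mean, sd = spec.population_stats[label]
        elif label in spec.derived_stats:
            mean, sd = spec.derived_stats[label]
        else:
            raise PipelineError(
                f"stage=summarize cohort={spec.cohort_label} population={label}: "
                "no summary statistics available"
            )
        out[label] = GroupSummary(mean=mean, sd=sd, n=spec.n_animals)
    return out


def _footnote(family_size: int, alpha: float) -> str:
    return (
        "Two-tailed Student's t-test (pooled variance) with Bonferroni "
        f"correction; significance assigned to p values < {round_sig(alpha, 3):g} "
        f"(family of {family_size} comparisons, family-wise alpha 0.05)."
    )


def run_pipeline(config: RunConfig) -> dict[str, ReportTable]:
    """Run the configured comparisons; returns one report per panel.

    When ``config.output_dir`` is set, also writes per-panel report files
    in the configured formats, per-animal percentage tables (simulation
    mode), optional event tables, and a JSON manifest.
    """
    presets = builtin_cohort_presets()
    out_dir = Path(config.output_dir) if config.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, ReportTable] = {}
    manifest: dict[str, object] = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "mode": config.mode,
        "basis": config.basis,
        "sampling": config.sampling,
        "assignment": config.assignment,
        "cohorts": [config.cohort_a, config.cohort_b],
        "panels": list(config.panels),
        "conventions": {
            "percent_basis": "percent of parent gate (Tregs of Ths, sub-markers of their subset)",
            "t_test": "pooled-variance two-tailed Student's t",
        },
        "files": {},
    }

    for panel in config.panels:
        definition = get_panel(panel)
        rows = definition.report_rows
        family_size = len(rows)
        alpha = bonferroni_threshold(family_size)
        specs = []
        for cohort in (config.cohort_a, config.cohort_b):
            try:
                spec = presets[(cohort, panel)]
            except KeyError:
                raise PipelineError(
                    f"stage=configure panel={panel}: no preset for cohort {cohort!r}"
                ) from None
            specs.append(
                replace(
                    spec,
                    seed=_derived_seed(config.seed, cohort, panel),
                    sampling=config.sampling,
                    **(
                        {"events_per_animal": config.events_per_animal}
                        if config.events_per_animal
                        else {}
                    ),
                )
            )
        spec_a, spec_b = specs

        if config.mode == "summary":
            logger.info("compare(summary): panel=%s %s vs %s", panel, spec_a.cohort_label, spec_b.cohort_label)
            comparisons = compare_group_summaries(
                _summary_table(spec_a, rows),
                _summary_table(spec_b, rows),
                family_size=family_size,
            )
        else:
            sim = {}
            for spec in (spec_a, spec_b):
                try:
                    per_row, per_animal, tables = simulate_cohort_percentages(
                        spec,
                        assignment=config.assignment,
                        basis=config.basis,
                        keep_events=config.write_events,
                    )
                except Exception as exc:  # annotate with the failing stage
                    raise PipelineError(
                        f"stage=simulate panel={panel} cohort={spec.cohort_label}: {exc}"
                    ) from exc
                sim[spec.cohort_label] = (per_row, per_animal, tables)
                if out_dir is not None:
                    _write_animal_artifacts(
                        out_dir, panel, spec, per_animal, tables, manifest
                    )
            comparisons = compare_panels(
                sim[spec_a.cohort_label][0],
                sim[spec_b.cohort_label][0],
                family_size=family_size,
            )

        report = ReportTable(
            title=(
                f"Panel {panel}: {config.cohort_a} (n={spec_a.n_animals}) vs "
                f"{config.cohort_b} (n={spec_b.n_animals}) [{config.mode} mode]"
            ),
            rows=tuple(comparisons),
            footnote=_footnote(family_size, alpha),
            family_size=family_size,
            corrected_alpha=alpha,
            metadata={
                "panel": panel,
                "mode": config.mode,
                "basis": config.basis,
                "seed": config.seed,
            },
        )
        reports[panel] = report
        if out_dir is not None:
            for fmt in config.formats:
                ext = {"csv": "csv", "json": "json", "markdown": "md"}[fmt]
                path = out_dir / f"panel_{panel}_report.{ext}"
                render_table(report, fmt, path=path, rounding=config.rounding)
                manifest["files"][str(path.relative_to(out_dir))] = fmt

    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return reports


def _write_animal_artifacts(out_dir, panel, spec, per_animal, tables, manifest):
    panel_dir = out_dir / f"panel_{panel}" / spec.cohort_label
    panel_dir.mkdir(parents=True, exist_ok=True)
    pct_path = panel_dir / "animal_percentages.csv"
    with open(pct_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["animal_index", "population", "pct"])
        for i, pcts in enumerate(per_animal):
            for label, value in pcts.items():
                writer.writerow([i, label, repr(float(value))])
    manifest["files"][str(pct_path.relative_to(out_dir))] = "per-animal percentages"
    if tables:
        for table in tables:
            path = panel_dir / f"{table.animal_id}.csv"
            table.to_csv(path)
            manifest["files"][str(path.relative_to(out_dir))] = "events"


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_table(
    report: ReportTable,
    format: str,
    path: str | Path | None = None,
    rounding: int = 4,
) -> str:
    """Render a report as csv, json, or markdown; optionally write to ``path``.

    Significant rows carry an asterisk in the markdown rendering; the CSV
    rendering keeps full float precision so it round-trips exactly.
    """
    if format == "csv":
        text = _render_csv(report)
    elif format == "json":
        text = _render_json(report)
    elif format == "markdown":
        text = _render_markdown(report, rounding)
    else:
        raise ConfigurationError(f"unknown render format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def _render_csv(report: ReportTable) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for row in report.rows:
        writer.writerow([
            row.label,
            repr(row.summary_a.mean), repr(row.summary_a.sd), row.summary_a.n,
            repr(row.summary_b.mean), repr(row.summary_b.sd), row.summary_b.n,
            repr(row.t_statistic), row.degrees_of_freedom,
            repr(row.p_value), repr(row.corrected_alpha), row.significant,
        ])
    return buf.getvalue()


def report_rows_from_csv(text: str) -> list[ComparisonResult]:
    """Inverse of the CSV rendering."""
    reader = csv.DictReader(io.StringIO(text))
    rows = []
    for record in reader:
        rows.append(
            ComparisonResult(
                label=record["population"],
                summary_a=GroupSummary(
                    float(record["mean_a"]), float(record["sd_a"]), int(record["n_a"])
                ),
                summary_b=GroupSummary(
                    float(record["mean_b"]), float(record["sd_b"]), int(record["n_b"])
                ),
                t_statistic=float(record["t"]),
                degrees_of_freedom=int(record["df"]),
                p_value=float(record["p_value"]),
                corrected_alpha=float(record["corrected_alpha"]),
                significant=record["significant"] == "True",
            )
        )
    return rows


def _render_json(report: ReportTable) -> str:
    payload = {
        "title": report.title,
        "footnote": report.footnote,
        "family_size": report.family_size,
        "corrected_alpha": report.corrected_alpha,
        "metadata": dict(report.metadata),
        "rows": [
            {
                "population": row.label,
                "group_a": {"mean": row.summary_a.mean, "sd": row.summary_a.sd, "n": row.summary_a.n},
                "group_b": {"mean": row.summary_b.mean, "sd": row.summary_b.sd, "n": row.summary_b.n},
                "t": row.t_statistic,
                "df": row.degrees_of_freedom,
                "p_value": row.p_value,
                "corrected_alpha": row.corrected_alpha,
                "significant": row.significant,
            }
            for row in report.rows
        ],
    }
    return json.dumps(payload, indent=2)


def _fmt(value: float, rounding: int) -> str:
    return f"{round_sig(float(value), rounding):g}"


def _render_markdown(report: ReportTable, rounding: int) -> str:
    lines = [
        f"### {report.title}",
        "",
        "| Population | Group A (mean ± SD, n) | Group B (mean ± SD, n) | p |",
        "| --- | --- | --- | --- |",
    ]
    for row in report.rows:
        star = "\\*" if row.significant else ""
        a = f"{_fmt(row.summary_a.mean, rounding)} ± {_fmt(row.summary_a.sd, rounding)} (n={row.summary_a.n})"
        b = f"{_fmt(row.summary_b.mean, rounding)} ± {_fmt(row.summary_b.sd, rounding)} (n={row.summary_b.n})"
        lines.append(f"| {row.label} | {a} | {b} | {_fmt(row.p_value, 2)}{star} |")
    lines += ["", f"_{report.footnote}_", ""]
    return "\n".join(lines)
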