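"""Builtin antibody-panel definitions and published cohort summary presets.

The cohort presets transcribe the published group summary tables
(mean %, SD %, n per population) for four groups:

- ``WT``  — wild-type tumor-bearing animals
- ``TF``  — transfected (reporter-bearing) tumor-bearing animals
- ``SH``  — sham (vehicle-inoculated) controls
- ``TF_aPDL1`` — transfected tumor-bearing animals under checkpoint blockade

Panels: ``1`` (lymphoid/myeloid overview, spleen), ``1t`` (same panel on
tumor tissue), ``2`` (tumor-cell PD-L1), ``3`` (lymphoid exhaustion),
``3mod`` (panel 3 without the NK identifier), ``4`` (myeloid polarization).

All percentages are interpreted uniformly as percent-of-parent within the
panel's gating hierarchy (regulatory T cells as percent of T helper cells,
granulocytes as percent of myeloid lineage cells, and so on); top-level
populations have the leukocyte gate as parent, so their percentages are
percent of CD45+ events.

Per-subset percentages of the exhaustion markers (PD-1, Tim-3) are not
published; the exhaustion panels instead sample each animal's derived
exhaustion score from the published score summary (``derived_stats``) and
back-solve the marker positivity that produces it (see
``_exhaustion_coupling``). That coupling is artifact plumbing, not
published data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .synthetic import CohortSpec, MarkerModel, PopulationSpec

__all__ = ["PanelDefinition", "get_panel", "builtin_cohort_presets", "TCES_LABEL"]

TCES_LABEL = "TCES"

#: fraction of acquired events inside the leukocyte (CD45+) gate for
#: density-separated splenocytes; fixed (zero-SD) artifact parameter
SPLEEN_LEUKOCYTE_PCT = 95.0
#: leukocyte / non-leukocyte split assumed for dissociated tumor tissue
TUMOR_LEUKOCYTE_PCT = 40.0
TUMOR_CELL_PCT = 60.0


@dataclass(frozen=True)
class PanelDefinition:
    """Generative structure of one antibody panel.

    ``populations`` is the disjoint partition hierarchy (identity markers
    only). ``expression_bindings`` maps a reported statistic label to a
    probabilistic marker on one population: ``(stat_label, population,
    marker)`` means events of ``population`` are positive for ``marker``
    with the per-animal sampled fraction of ``stat_label``.
    """

    panel: str
    markers: tuple[str, ...]
    populations: tuple[PopulationSpec, ...]
    expression_bindings: tuple[tuple[str, str, str], ...]
    report_rows: tuple[str, ...]
    fixed_stats: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: optional hook deriving additional marker fractions from sampled ones,
    #: signature (cohort, fractions, sample_stat) -> None (mutates fractions)
    coupling: Callable | None = None

    def marker_models(self) -> list[MarkerModel]:
        return [MarkerModel(marker) for marker in self.markers]

    def stat_labels(self) -> set[str]:
        labels = {p.label for p in self.populations}
        labels.update(stat for stat, _, _ in self.expression_bindings)
        labels.update(self.fixed_stats)
        return labels

    def partition_sibling_groups(self) -> list[list[str]]:
        groups: dict[str | None, list[str]] = {}
        for pop in self.populations:
            groups.setdefault(pop.parent, []).append(pop.label)
        return [g for g in groups.values() if len(g) > 1]

    def concretize(self, fractions: Mapping[str, float]) -> list[PopulationSpec]:
        """Insert per-animal expression probabilities into marker profiles."""
        extra: dict[str, dict[str, float]] = {}
        for stat, population, marker in self.expression_bindings:
            if stat in fractions:
                extra.setdefault(population, {})[marker] = float(fractions[stat])
        specs = []
        for pop in self.populations:
            profile = dict(pop.marker_profile)
            profile.update(extra.get(pop.label, {}))
            specs.append(
                PopulationSpec(pop.label, pop.parent, profile, pop.target_fraction)
            )
        return specs


def _lymphoid_overview(panel: str, leukocyte_pct: float) -> PanelDefinition:
    return PanelDefinition(
        panel=panel,
        markers=("CD45", "CD4", "CD8", "NKp46", "CD11b", "Ly6G", "Foxp3"),
        populations=(
            PopulationSpec("Leukocytes", None, {"CD45": 1.0}),
            PopulationSpec("NK cells", "Leukocytes", {"NKp46": 1.0}),
            PopulationSpec("CTLs", "Leukocytes", {"CD8": 1.0}),
            PopulationSpec("Ths", "Leukocytes", {"CD4": 1.0}),
            PopulationSpec("MLCs", "Leukocytes", {"CD11b": 1.0}),
        ),
        expression_bindings=(
            ("Tregs", "Ths", "Foxp3"),
            ("Granulocytes", "MLCs", "Ly6G"),
        ),
        report_rows=("NK cells", "CTLs", "Ths", "Tregs", "MLCs", "Granulocytes"),
        fixed_stats={"Leukocytes": (leukocyte_pct, 0.0)},
    )


_EXHAUSTION_MARKER_LABELS = ("PD-1+ CTLs", "Tim-3+ CTLs", "PD-1+ Ths", "Tim-3+ Ths")


def _exhaustion_coupling(cohort: CohortSpec, fractions: dict, sample_stat) -> None:
    """Derive per-animal PD-1/Tim-3 positivity from the cohort's score stats.

    The published tables summarize the derived exhaustion score, not the
    underlying marker percentages, so the generator samples a per-animal
    score from the cohort's (mean, SD) and back-solves the common marker
    percentage that yields it given the animal's sampled T-cell fractions:
    score = 4 * marker_pct / (pct_CTL + pct_Th).
    """
    stats = cohort.derived_stats.get(TCES_LABEL)
    if stats is None:
        return
    score = max(sample_stat(TCES_LABEL, *stats), 0.0)
    denominator_pct = (fractions.get("CTLs", 0.0) + fractions.get("Ths", 0.0)) * 100.0
    marker_pct = min(max(score * denominator_pct / 4.0, 0.0), 100.0)
    for label in _EXHAUSTION_MARKER_LABELS:
        fractions[label] = marker_pct / 100.0


def _exhaustion_panel(panel: str, with_nk: bool) -> PanelDefinition:
    markers = ["CD45", "CD4", "CD8", "PD-1", "Tim-3", "CTLA-4", "Foxp3"]
    populations = [
        PopulationSpec("Leukocytes", None, {"CD45": 1.0}),
        PopulationSpec("CTLs", "Leukocytes", {"CD8": 1.0}),
        PopulationSpec("Ths", "Leukocytes", {"CD4": 1.0}),
    ]
    rows = ["CTLs", "Ths", "Tregs", "CTLA-4+ CTLs", TCES_LABEL]
    if with_nk:
        markers.insert(3, "NKp46")
        populations.insert(1, PopulationSpec("NK cells", "Leukocytes", {"NKp46": 1.0}))
        rows.insert(0, "NK cells")
    return PanelDefinition(
        panel=panel,
        markers=tuple(markers),
        populations=tuple(populations),
        expression_bindings=(
            ("Tregs", "Ths", "Foxp3"),
            ("CTLA-4+ CTLs", "CTLs", "CTLA-4"),
            ("PD-1+ CTLs", "CTLs", "PD-1"),
            ("Tim-3+ CTLs", "CTLs", "Tim-3"),
            ("PD-1+ Ths", "Ths", "PD-1"),
            ("Tim-3+ Ths", "Ths", "Tim-3"),
        ),
        report_rows=tuple(rows),
        fixed_stats={"Leukocytes": (SPLEEN_LEUKOCYTE_PCT, 0.0)},
        coupling=_exhaustion_coupling,
    )


_PANELS: dict[str, PanelDefinition] = {
    "1": _lymphoid_overview("1", SPLEEN_LEUKOCYTE_PCT),
    "1t": _lymphoid_overview("1t", TUMOR_LEUKOCYTE_PCT),
    "2": PanelDefinition(
        panel="2",
        markers=("CD45", "PD-L1"),
        populations=(
            PopulationSpec("Tumor cells", None, {"CD45": 0.0}),
            PopulationSpec("Leukocytes", None, {"CD45": 1.0}),
        ),
        expression_bindings=(("PD-L1", "Tumor cells", "PD-L1"),),
        report_rows=("PD-L1",),
        fixed_stats={
            "Tumor cells": (TUMOR_CELL_PCT, 0.0),
            "Leukocytes": (TUMOR_LEUKOCYTE_PCT, 0.0),
        },
    ),
    "3": _exhaustion_panel("3", with_nk=True),
    "3mod": _exhaustion_panel("3mod", with_nk=False),
    "4": PanelDefinition(
        panel="4",
        markers=("CD45", "CD11b", "Ly6G", "Ly6C", "Cxcl9", "Nos2", "Tgm2", "Arg1"),
        populations=(
            PopulationSpec("Leukocytes", None, {"CD45": 1.0}),
            PopulationSpec("MLCs", "Leukocytes", {"CD11b": 1.0}),
            PopulationSpec("Monocytes/macrophages", "MLCs", {"Ly6C": 1.0}),
            PopulationSpec("Granulocytes", "MLCs", {"Ly6G": 1.0}),
        ),
        expression_bindings=(
            ("Tgm2+ macrophages", "Monocytes/macrophages", "Tgm2"),
            ("Arg1+ macrophages", "Monocytes/macrophages", "Arg1"),
            ("Cxcl9+ macrophages", "Monocytes/macrophages", "Cxcl9"),
            ("Nos2+ macrophages", "Monocytes/macrophages", "Nos2"),
        ),
        report_rows=(
            "MLCs",
            "Monocytes/macrophages",
            "Granulocytes",
            "Tgm2+ macrophages",
            "Arg1+ macrophages",
            "Cxcl9+ macrophages",
            "Nos2+ macrophages",
        ),
        fixed_stats={"Leukocytes": (SPLEEN_LEUKOCYTE_PCT, 0.0)},
    ),
}


def get_panel(panel: str) -> PanelDefinition:
    if panel not in _PANELS:
        raise KeyError(panel)
    return _PANELS[panel]


# ---------------------------------------------------------------------------
# Published cohort summaries
# ---------------------------------------------------------------------------

def builtin_cohort_presets() -> dict[tuple[str, str], CohortSpec]:
    """Map (cohort label, panel id) -> CohortSpec transcribing the summary tables."""

    def spec(cohort, panel, n, stats, derived=None):
        merged = dict(_PANELS[panel].fixed_stats)
        merged.update(stats)
        return CohortSpec(
            cohort_label=cohort,
            panel=panel,
            n_animals=n,
            population_stats=merged,
            derived_stats=derived or {},
        )

    presets: dict[tuple[str, str], CohortSpec] = {}

    # Panel 1 on tumor tissue: six populations, WT n=11 vs TF n=15
    presets[("WT", "1t")] = spec("WT", "1t", 11, {
        "NK cells": (19.76, 4.76),
        "CTLs": (5.45, 3.09),
        "Ths": (6.96, 1.69),
        "Tregs": (16.95, 10.44),
        "MLCs": (36.5, 23.12),
        "Granulocytes": (35.8, 18.32),
    })
    presets[("TF", "1t")] = spec("TF", "1t", 15, {
        "NK cells": (20.94, 12.67),
        "CTLs": (6.07, 7.55),
        "Ths": (5.42, 3.39),
        "Tregs": (24.02, 15.37),
        "MLCs": (34.74, 17.53),
        "Granulocytes": (36.59, 16.38),
    })

    # Panel 2: tumor-cell PD-L1 expression, WT n=11 vs TF n=15
    presets[("WT", "2")] = spec("WT", "2", 11, {"PD-L1": (1.96, 0.77)})
    presets[("TF", "2")] = spec("TF", "2", 15, {"PD-L1": (1.91, 1.28)})

    # Panel 1 on spleens: WT n=10 vs TF n=9
    presets[("WT", "1")] = spec("WT", "1", 10, {
        "NK cells": (5.35, 4.58),
        "CTLs": (7.23, 2.41),
        "Ths": (18.0, 13.61),
        "Tregs": (12.68, 6.01),
        "MLCs": (5.2, 11.41),
        "Granulocytes": (15.27, 21.82),
    })
    presets[("TF", "1")] = spec("TF", "1", 9, {
        "NK cells": (7.55, 5.0),
        "CTLs": (5.03, 2.64),
        "Ths": (11.71, 12.95),
        "Tregs": (16.19, 8.43),
        "MLCs": (9.76, 10.76),
        "Granulocytes": (52.33, 19.02),
    })

    # Panel 3 on spleens: TF n=5 vs SH n=4
    tf3 = {
        "NK cells": (10.78, 4.5),
        "CTLs": (2.73, 1.22),
        "Ths": (6.45, 3.08),
        "Tregs": (21.09, 5.12),
        "CTLA-4+ CTLs": (18.35, 10.12),
    }
    sh3 = {
        "NK cells": (1.85, 0.4),
        "CTLs": (3.72, 0.86),
        "Ths": (7.72, 1.1),
        "Tregs": (7.25, 0.23),
        "CTLA-4+ CTLs": (1.72, 0.42),
    }
    presets[("TF", "3")] = spec("TF", "3", 5, tf3, {TCES_LABEL: (18.23, 4.58)})
    presets[("SH", "3")] = spec("SH", "3", 4, sh3, {TCES_LABEL: (0.16, 0.054)})

    # Modified panel 3 (no NK identifier): untreated TF n=5 vs treated n=3
    tf3mod = {k: v for k, v in tf3.items() if k != "NK cells"}
    presets[("TF", "3mod")] = spec("TF", "3mod", 5, tf3mod, {TCES_LABEL: (18.23, 4.58)})
    presets[("TF_aPDL1", "3mod")] = spec("TF_aPDL1", "3mod", 3, {
        "CTLs": (2.85, 1.13),
        "Ths": (5.14, 3.74),
        "Tregs": (26.63, 7.02),
        "CTLA-4+ CTLs": (44.95, 37.19),
    }, {TCES_LABEL: (0.79, 0.71)})

    # Panel 4 on spleens: TF n=5 vs SH n=4, and treated TF n=3
    presets[("TF", "4")] = spec("TF", "4", 5, {
        "MLCs": (5.27, 1.11),
        "Monocytes/macrophages": (4.92, 1.29),
        "Granulocytes": (57.49, 9.62),
        "Tgm2+ macrophages": (18.58, 5.69),
        "Arg1+ macrophages": (0.3, 0.56),
        "Cxcl9+ macrophages": (18.28, 5.38),
        "Nos2+ macrophages": (97.99, 1.62),
    })
    presets[("SH", "4")] = spec("SH", "4", 4, {
        "MLCs": (1.39, 0.4),
        "Monocytes/macrophages": (7.49, 1.7),
        "Granulocytes": (74.69, 4.55),
        "Tgm2+ macrophages": (4.22, 2.66),
        "Arg1+ macrophages": (0.0, 0.0),
        "Cxcl9+ macrophages": (1.44, 1.23),
        "Nos2+ macrophages": (16.56, 10.19),
    })
    presets[("TF_aPDL1", "4")] = spec("TF_aPDL1", "4", 3, {
        "MLCs": (5.73, 1.68),
        "Monocytes/macrophages": (12.8, 2.92),
        "Granulocytes": (51.37, 9.11),
        "Tgm2+ macrophages": (2.1, 2.17),
        "Arg1+ macrophages": (0.23, 0.17),
        "Cxcl9+ macrophages": (1.52, 1.24),
        "Nos2+ macrophages": (50.89, 18.07),
    })

    return presets


#: Bonferroni family size used for each comparison table (row count)
FAMILY_SIZES = {"1": 6, "1t": 6, "2": 1, "3": 6, "3mod": 5, "4": 7}
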