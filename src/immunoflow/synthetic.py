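"""Synthetic per-animal flow-cytometry event generation.

Each marker has a two-component log-normal intensity model (a negative and
a positive mode, separable enough that a midpoint threshold is
unambiguous). Animals within a cohort vary according to per-population
(mean, SD) percentage statistics; events within an animal are assigned
multinomially to disjoint hierarchical populations and receive marker
intensities according to each population's marker-positivity profile.

Two between-animal sampling schemes are provided:

``quantile`` (default)
    Each animal receives a distinct normal quantile of the cohort
    distribution (stratified, moment-matched sampling): the cohort's
    sample mean equals the target mean exactly and the sample SD is within
    a few percent of the target SD at any cohort size. This is what makes
    cohort-level summary statistics of a finite simulated cohort track the
    configured (mean, SD) instead of merely being an unbiased draw.

``iid``
    Plain independent truncated-normal draws.

Both schemes are deterministic functions of ``(seed, animal_index)``,
independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import ConfigurationError

__all__ = [
    "MarkerModel",
    "PopulationSpec",
    "CohortSpec",
    "EventTable",
    "sample_animal_fractions",
    "generate_events",
    "generate_cohort",
    "builtin_cohort_presets",
]

SAMPLING_METHODS = ("quantile", "iid")
MARKER_ASSIGNMENTS = ("exact", "bernoulli")
PARTITION_ASSIGNMENTS = ("exact", "multinomial")


@dataclass(frozen=True)
class MarkerModel:
    """Two-mode log10-intensity model for one marker.

    ``negative_mode`` and ``positive_mode`` are ``(location, scale)`` of the
    log10 intensity for marker-negative and marker-positive events. The two
    locations must be separated by at least three times the larger scale so
    that the midpoint threshold classifies events essentially without error.
    """

    marker_name: str
    negative_mode: tuple[float, float] = (1.0, 0.15)
    positive_mode: tuple[float, float] = (3.0, 0.25)

    def __post_init__(self) -> None:
        (nl, ns), (pl, ps) = self.negative_mode, self.positive_mode
        if ns <= 0 or ps <= 0:
            raise ConfigurationError(f"{self.marker_name}: mode scales must be > 0")
        if pl <= nl:
            raise ConfigurationError(
                f"{self.marker_name}: positive mode location must exceed negative"
            )
        if pl - nl < 3.0 * max(ns, ps):
            raise ConfigurationError(
                f"{self.marker_name}: modes are not separable (gap < 3x larger scale)"
            )

    @property
    def log10_threshold(self) -> float:
        return 0.5 * (self.negative_mode[0] + self.positive_mode[0])

    @property
    def threshold(self) -> float:
        """Intensity cutoff at the midpoint between the two modes."""
        return float(10.0 ** self.log10_threshold)


@dataclass(frozen=True)
class PopulationSpec:
    """One disjoint population of the generative hierarchy.

    ``marker_profile`` maps marker name to the probability that an event of
    this population is positive for the marker (1.0/0.0 for identity
    markers, intermediate values for expression markers). Profiles are
    inherited: an event of this population is also subject to every
    ancestor's profile entries unless overridden here.

    ``target_fraction`` is the expected fraction of the *parent* population.
    """

    label: str
    parent: str | None
    marker_profile: Mapping[str, float] = field(default_factory=dict)
    target_fraction: float = 0.0

    def __post_init__(self) -> None:
        for marker, prob in self.marker_profile.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(
                    f"{self.label}: probability for {marker!r} outside [0, 1]"
                )
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigurationError(f"{self.label}: target_fraction outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level recipe: which panel, how many animals, what statistics.

    ``population_stats`` maps a population (or marker-expression) label to
    the (mean %, SD %) of its percent-of-parent across animals.
    ``derived_stats`` holds summary statistics of derived scores (e.g. the
    T-cell exhaustion score) that are not directly simulable populations.
    """

    cohort_label: str
    panel: str
    n_animals: int
    population_stats: Mapping[str, tuple[float, float]]
    events_per_animal: int = 50_000
    seed: int = 0
    sampling: str = "quantile"
    derived_stats: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals < 3:
            raise ConfigurationError("a cohort requires at least three animals")
        if self.events_per_animal < 1:
            raise ConfigurationError("events_per_animal must be >= 1")
        if self.sampling not in SAMPLING_METHODS:
            raise ConfigurationError(f"unknown sampling method {self.sampling!r}")
        for label, (mean, sd) in self.population_stats.items():
            if not 0.0 <= mean <= 100.0:
                raise ConfigurationError(f"{label}: mean % must lie in [0, 100]")
            if sd < 0.0:
                raise ConfigurationError(f"{label}: SD must be >= 0")


@dataclass
class EventTable:
    """Per-animal events-by-markers intensity matrix with optional truth."""

    animal_id: str
    intensities: pd.DataFrame
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.intensities) == 0:
            raise ConfigurationError(f"{self.animal_id}: event table is empty")
        if self.intensities.isna().any().any():
            raise ConfigurationError(f"{self.animal_id}: event table has missing values")
        if self.truth_labels is not None and len(self.truth_labels) != len(self.intensities):
            raise ConfigurationError(f"{self.animal_id}: truth labels length mismatch")

    @property
    def markers(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_events(self) -> int:
        return len(self.intensities)

    def to_csv(self, path, include_truth: bool = False) -> None:
        frame = self.intensities
        if include_truth and self.truth_labels is not None:
            frame = frame.assign(truth_label=self.truth_labels)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, animal_id: str | None = None) -> "EventTable":
        frame = pd.read_csv(path)
        truth = None
        if "truth_label" in frame.columns:
            truth = frame.pop("truth_label").to_numpy()
        name = animal_id if animal_id is not None else str(path)
        return cls(animal_id=name, intensities=frame, truth_labels=truth)


# ---------------------------------------------------------------------------
# Between-animal sampling
# ---------------------------------------------------------------------------

def _label_key(label: str) -> int:
    # stable across processes, unlike hash()
    return zlib.crc32(label.encode("utf-8"))


def _rank_permutation(seed: int, label: str, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, _label_key(label))))
    return rng.permutation(n)


def _sample_stat(
    cohort: CohortSpec, label: str, mean: float, sd: float, animal_index: int
) -> float:
    """One per-animal draw from Normal(mean, sd), deterministic in
    (seed, animal_index, label); quantile-stratified under the default scheme."""
    if cohort.sampling == "quantile":
        perm = _rank_permutation(cohort.seed, label, cohort.n_animals)
        q = (perm[animal_index] + 0.5) / cohort.n_animals
        return mean + sd * float(ndtri(q))
    rng = np.random.default_rng(
        np.random.SeedSequence((cohort.seed, animal_index, _label_key(label)))
    )
    return float(rng.normal(mean, sd))


def sample_animal_fractions(
    cohort: CohortSpec,
    animal_index: int,
    sibling_groups: Sequence[Sequence[str]] | None = None,
) -> dict[str, float]:
    """Per-animal fraction (0-1 of parent) for every entry of ``population_stats``.

    Deterministic in ``(cohort.seed, animal_index)``. Values are drawn from
    a normal with the cohort (mean, SD) — stratified by normal quantile
    under the default ``quantile`` scheme — truncated to [0, 100] on the
    percent scale, then divided by 100. Partition siblings whose sampled
    fractions sum above 1 are rescaled proportionally. Builtin panels may
    additionally couple derived-score statistics into marker fractions
    (the exhaustion panels derive their PD-1/Tim-3 probabilities from the
    cohort's exhaustion-score statistics).
    """
    if not 0 <= animal_index < cohort.n_animals:
        raise ConfigurationError(
            f"animal_index {animal_index} outside cohort of {cohort.n_animals}"
        )
    definition = _panel_definition(cohort)
    if sibling_groups is None:
        sibling_groups = (
            definition.partition_sibling_groups() if definition is not None else []
        )

    fractions: dict[str, float] = {}
    for label, (mean, sd) in cohort.population_stats.items():
        value = _sample_stat(cohort, label, mean, sd, animal_index)
        fractions[label] = min(max(value, 0.0), 100.0) / 100.0

    for group in sibling_groups:
        present = [lab for lab in group if lab in fractions]
        total = sum(fractions[lab] for lab in present)
        if total > 1.0:
            for lab in present:
                fractions[lab] /= total

    if definition is not None and definition.coupling is not None:
        definition.coupling(
            cohort,
            fractions,
            lambda label, mean, sd: _sample_stat(cohort, label, mean, sd, animal_index),
        )
    return fractions


def _panel_definition(cohort: CohortSpec):
    """Builtin panel definition, or None; validates stat labels when known."""
    from . import presets  # deferred: presets builds on this module's types

    try:
        definition = presets.get_panel(cohort.panel)
    except KeyError:
        return None
    known = definition.stat_labels()
    unknown = sorted(set(cohort.population_stats) - known)
    if unknown:
        raise ConfigurationError(
            f"unknown population labels for panel {cohort.panel!r}: {', '.join(unknown)}"
        )
    return definition


# ---------------------------------------------------------------------------
# Event generation
# ---------------------------------------------------------------------------

def _effective_profiles(
    specs: Sequence[PopulationSpec],
) -> dict[str, dict[str, float]]:
    by_label = {s.label: s for s in specs}
    if len(by_label) != len(specs):
        raise ConfigurationError("population labels are not unique")
    profiles: dict[str, dict[str, float]] = {}

    def build(label: str, seen: tuple[str, ...] = ()) -> dict[str, float]:
        if label in profiles:
            return profiles[label]
        if label in seen:
            raise ConfigurationError(f"population tree has a cycle at {label!r}")
        spec = by_label[label]
        base: dict[str, float] = {}
        if spec.parent is not None:
            if spec.parent not in by_label:
                raise ConfigurationError(
                    f"population {label!r} has unknown parent {spec.parent!r}"
                )
            base = dict(build(spec.parent, seen + (label,)))
        base.update(spec.marker_profile)
        profiles[label] = base
        return base

    for spec in specs:
        build(spec.label)
    return profiles


def _largest_remainder_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Deterministic apportionment of ``n`` events proportional to ``probs``."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_events(
    fractions: Mapping[str, float],
    marker_models: Sequence[MarkerModel],
    population_specs: Sequence[PopulationSpec],
    n_events: int,
    seed,
    animal_id: str = "animal",
    marker_assignment: str = "bernoulli",
    partition_assignment: str = "multinomial",
) -> EventTable:
    """Simulate one animal's event table.

    Events are first assigned to the disjoint populations of the hierarchy
    (fractions are percent-of-parent on the 0-1 scale; unassigned events
    remain at their deepest internal node) — multinomially by default, or
    by deterministic largest-remainder apportionment under
    ``partition_assignment='exact'``. Marker positivity within a
    population follows its effective (inherited) profile: under
    ``marker_assignment='bernoulli'`` each event is positive independently
    with probability ``p``; under ``'exact'`` the number of positive
    events equals ``round(p * n)`` (positions randomized). Intensities are
    then drawn from each marker's positive or negative log-normal mode.

    The ``exact`` modes realize the same marginal probabilities but
    suppress within-animal counting noise, so cohort-level summary
    statistics track the between-animal (mean, SD) targets; they are the
    defaults of :func:`generate_cohort`.
    """
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    if marker_assignment not in MARKER_ASSIGNMENTS:
        raise ConfigurationError(f"unknown marker_assignment {marker_assignment!r}")
    if partition_assignment not in PARTITION_ASSIGNMENTS:
        raise ConfigurationError(f"unknown partition_assignment {partition_assignment!r}")
    models = {m.marker_name: m for m in marker_models}
    profiles = _effective_profiles(population_specs)
    for label, profile in profiles.items():
        missing = sorted(set(profile) - set(models))
        if missing:
            raise ConfigurationError(
                f"population {label!r} references unknown markers: {', '.join(missing)}"
            )

    by_label = {s.label: s for s in population_specs}
    children: dict[str | None, list[str]] = {}
    for spec in population_specs:
        children.setdefault(spec.parent, []).append(spec.label)
    roots = children.get(None, [])

    def get_fraction(label: str) -> float:
        if label in fractions:
            return float(fractions[label])
        return by_label[label].target_fraction

    # absolute fraction of each population's *own* events (excluding events
    # claimed by its partition children)
    own_fraction: dict[str, float] = {}

    def walk(labels: list[str], parent_abs: float) -> float:
        """Assign absolute fractions below one parent; returns claimed total."""
        fracs = np.array([get_fraction(lab) for lab in labels], dtype=float)
        total = fracs.sum()
        if total > 1.0:  # proportional rescale, preserving composition
            fracs = fracs / total
        claimed = 0.0
        for lab, frac in zip(labels, fracs):
            node_abs = parent_abs * float(frac)
            child_claimed = walk(children.get(lab, []), node_abs)
            own_fraction[lab] = node_abs - child_claimed
            claimed += node_abs
        return claimed

    residual_root = 1.0 - walk(roots, 1.0)

    unit_labels = list(own_fraction)
    probs = np.array([own_fraction[lab] for lab in unit_labels], dtype=float)
    probs = np.clip(probs, 0.0, None)
    unit_labels.append("__unassigned__")
    probs = np.append(probs, max(residual_root, 0.0))
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    if partition_assignment == "multinomial":
        counts = rng.multinomial(n_events, probs)
    else:
        counts = _largest_remainder_counts(n_events, probs)
    order = rng.permutation(n_events)
    truth = np.empty(n_events, dtype=object)
    positive = {marker: np.zeros(n_events, dtype=bool) for marker in models}
    start = 0
    for label, count in zip(unit_labels, counts):
        if count == 0:
            continue
        idx = order[start : start + count]
        start += count
        truth[idx] = label
        if label == "__unassigned__":
            continue
        for marker, prob in profiles[label].items():
            if prob <= 0.0:
                continue
            if prob >= 1.0:
                positive[marker][idx] = True
            elif marker_assignment == "exact":
                k = int(round(prob * count))
                k = min(max(k, 0), count)
                if k:
                    positive[marker][rng.permutation(idx)[:k]] = True
            else:
                positive[marker][idx[rng.random(count) < prob]] = True

    data = {}
    for marker in models:
        model = models[marker]
        pos = positive[marker]
        loc = np.where(pos, model.positive_mode[0], model.negative_mode[0])
        scale = np.where(pos, model.positive_mode[1], model.negative_mode[1])
        data[marker] = 10.0 ** rng.normal(loc, scale)
    frame = pd.DataFrame(data, columns=list(models))
    return EventTable(animal_id=animal_id, intensities=frame, truth_labels=truth)


def generate_cohort(
    cohort: CohortSpec,
    assignment: str = "exact",
    events_per_animal: int | None = None,
) -> list[EventTable]:
    """Simulate every animal of a builtin-panel cohort.

    ``assignment='exact'`` (default) apportions events and marker
    positivity deterministically given the sampled per-animal fractions;
    ``'stochastic'`` uses multinomial/Bernoulli draws. Identical
    ``CohortSpec`` (including its seed) yields byte-identical event tables.
    """
    from . import presets

    if assignment not in ("exact", "stochastic"):
        raise ConfigurationError(f"unknown assignment mode {assignment!r}")
    marker_mode = "exact" if assignment == "exact" else "bernoulli"
    partition_mode = "exact" if assignment == "exact" else "multinomial"
    definition = presets.get_panel(cohort.panel)
    n_events = events_per_animal or cohort.events_per_animal
    tables = []
    for i in range(cohort.n_animals):
        fractions = sample_animal_fractions(cohort, i)
        specs = definition.concretize(fractions)
        seed = np.random.SeedSequence((cohort.seed, i, 0xEE))
        tables.append(
            generate_events(
                fractions,
                definition.marker_models(),
                specs,
                n_events,
                seed,
                animal_id=f"{cohort.cohort_label}_{cohort.panel}_{i:02d}",
                marker_assignment=marker_mode,
                partition_assignment=partition_mode,
            )
        )
    return tables


def builtin_cohort_presets() -> dict[tuple[str, str], CohortSpec]:
    """Cohort presets transcribing the published group summary tables."""
    from . import presets

    return presets.builtin_cohort_presets()


def with_overrides(cohort: CohortSpec, **kwargs) -> CohortSpec:
    """Convenience wrapper around ``dataclasses.replace``."""
    return replace(cohort, **kwargs)
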