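"""Hierarchical boolean gating of flow-cytometry event tables.

Events are classified by conjunctions of single-marker threshold gates
arranged in a tree; each node reports its event count together with
percent-of-parent and percent-of-root statistics.

Boundary convention: an event exactly at a threshold is *negative*
(positivity requires a strictly greater intensity), so at any fixed
threshold the positive and negative gates partition their parent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigurationError, GatingError

__all__ = [
    "GateDefinition",
    "GateTree",
    "PopulationResult",
    "classify_events",
    "apply_gate_tree",
    "builtin_panels",
    "estimate_thresholds",
    "tree_to_json",
    "tree_from_json",
    "DEFAULT_LOG10_THRESHOLD",
    "DEFAULT_THRESHOLD",
]

#: Default log10-intensity cutoff separating the builtin negative and
#: positive marker modes (midpoint of the two mode locations).
DEFAULT_LOG10_THRESHOLD = 2.0
DEFAULT_THRESHOLD = 10.0 ** DEFAULT_LOG10_THRESHOLD

_SIGNS = ("+", "-")


@dataclass(frozen=True)
class GateDefinition:
    """One boolean gate: is ``marker`` above (``+``) or at/below (``-``) ``threshold``."""

    marker: str
    sign: str
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise ConfigurationError(f"gate sign must be '+' or '-', got {self.sign!r}")
        if not math.isfinite(self.threshold):
            raise ConfigurationError(f"gate threshold for {self.marker!r} must be finite")


@dataclass(frozen=True)
class PopulationResult:
    label: str
    event_count: int
    pct_of_parent: float
    pct_of_root: float


class GateTree:
    """A rooted tree of gated populations.

    ``nodes`` maps a population label to ``(parent_label, gates)``; the root
    node has parent ``None`` and (conventionally) no gates. A node's full
    gate is the conjunction of its own gates with all ancestor gates.
    """

    def __init__(self, nodes: Mapping[str, tuple[str | None, Sequence[GateDefinition]]], root: str):
        self.nodes: dict[str, tuple[str | None, tuple[GateDefinition, ...]]] = {
            label: (parent, tuple(gates)) for label, (parent, gates) in nodes.items()
        }
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise ConfigurationError(f"root {self.root!r} is not a node of the tree")
        root_parent = self.nodes[self.root][0]
        if root_parent is not None:
            raise ConfigurationError(f"root {self.root!r} must have parent None")
        for label, (parent, _) in self.nodes.items():
            if label == self.root:
                continue
            if parent not in self.nodes:
                raise ConfigurationError(f"node {label!r} has unknown parent {parent!r}")
        # every node must reach the root without revisiting a label
        for label in self.nodes:
            seen: set[str] = set()
            cur: str | None = label
            while cur is not None:
                if cur in seen:
                    raise ConfigurationError(f"cycle detected at node {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur][0]
            if self.root not in seen:
                raise ConfigurationError(f"node {label!r} is not reachable from the root")

    def topological_order(self) -> list[str]:
        """Labels ordered parents-first, preserving insertion order among siblings."""
        depth = {}
        for label in self.nodes:
            d, cur = 0, self.nodes[label][0]
            while cur is not None:
                d += 1
                cur = self.nodes[cur][0]
            depth[label] = d
        order = list(self.nodes)
        order.sort(key=lambda lab: depth[lab])
        return order

    def children(self, label: str) -> list[str]:
        return [lab for lab, (parent, _) in self.nodes.items() if parent == label]

    def markers(self) -> set[str]:
        return {g.marker for _, gates in self.nodes.values() for g in gates}

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GateTree)
            and self.root == other.root
            and self.nodes == other.nodes
        )

    def __repr__(self) -> str:
        return f"GateTree(root={self.root!r}, n_nodes={len(self.nodes)})"


def _intensity_frame(events) -> pd.DataFrame:
    frame = getattr(events, "intensities", events)
    if not isinstance(frame, pd.DataFrame):
        raise GatingError("events must be an EventTable or a pandas DataFrame")
    return frame


def classify_events(events, gates: Iterable[GateDefinition]) -> np.ndarray:
    """Boolean mask of events satisfying *every* gate (AND semantics).

    An empty gate list is a vacuous conjunction: all events pass.
    """
    frame = _intensity_frame(events)
    mask = np.ones(len(frame), dtype=bool)
    for gate in gates:
        if gate.marker not in frame.columns:
            raise GatingError(f"marker {gate.marker!r} is not present in the event table")
        values = frame[gate.marker].to_numpy()
        if gate.sign == "+":
            mask &= values > gate.threshold
        else:
            mask &= values <= gate.threshold
    return mask


def apply_gate_tree(events, tree: GateTree) -> list[PopulationResult]:
    """Evaluate every node of ``tree``; masks are inherited down the tree."""
    frame = _intensity_frame(events)
    missing = sorted(m for m in tree.markers() if m not in frame.columns)
    if missing:
        raise GatingError(f"markers missing from event table: {', '.join(missing)}")

    masks: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    results: list[PopulationResult] = []
    root_count = len(frame)
    for label in tree.topological_order():
        parent, gates = tree.nodes[label]
        own = classify_events(frame, gates)
        mask = own if parent is None else (masks[parent] & own)
        masks[label] = mask
        count = int(mask.sum())
        counts[label] = count
        parent_count = root_count if parent is None else counts[parent]
        pct_parent = 100.0 * count / parent_count if parent_count else 0.0
        pct_root = 100.0 * count / counts[tree.root] if counts[tree.root] else 0.0
        if parent is None:
            pct_parent = 100.0 * count / root_count if root_count else 0.0
        results.append(PopulationResult(label, count, pct_parent, pct_root))
    return results


def results_by_label(results: Iterable[PopulationResult]) -> dict[str, PopulationResult]:
    return {r.label: r for r in results}


# ---------------------------------------------------------------------------
# Builtin antibody panels
# ---------------------------------------------------------------------------

ROOT_LABEL = "All events"

# (label, parent, ((marker, sign), ...))
_PANEL_NODES: dict[str, tuple[tuple[str, str | None, tuple[tuple[str, str], ...]], ...]] = {
    "1": (
        (ROOT_LABEL, None, ()),
        ("Leukocytes", ROOT_LABEL, (("CD45", "+"),)),
        ("NK cells", "Leukocytes", (("NKp46", "+"),)),
        ("CTLs", "Leukocytes", (("CD8", "+"),)),
        ("Ths", "Leukocytes", (("CD4", "+"),)),
        ("MLCs", "Leukocytes", (("CD11b", "+"),)),
        ("Tregs", "Ths", (("Foxp3", "+"),)),
        ("Granulocytes", "MLCs", (("Ly6G", "+"),)),
    ),
    "2": (
        (ROOT_LABEL, None, ()),
        ("Tumor cells", ROOT_LABEL, (("CD45", "-"),)),
        ("PD-L1", "Tumor cells", (("PD-L1", "+"),)),
    ),
    "3": (
        (ROOT_LABEL, None, ()),
        ("Leukocytes", ROOT_LABEL, (("CD45", "+"),)),
        ("NK cells", "Leukocytes", (("NKp46", "+"),)),
        ("CTLs", "Leukocytes", (("CD8", "+"),)),
        ("Ths", "Leukocytes", (("CD4", "+"),)),
        ("PD-1+ CTLs", "CTLs", (("PD-1", "+"),)),
        ("Tim-3+ CTLs", "CTLs", (("Tim-3", "+"),)),
        ("CTLA-4+ CTLs", "CTLs", (("CTLA-4", "+"),)),
        ("Tregs", "Ths", (("Foxp3", "+"),)),
        ("PD-1+ Ths", "Ths", (("PD-1", "+"),)),
        ("Tim-3+ Ths", "Ths", (("Tim-3", "+"),)),
    ),
    "4": (
        (ROOT_LABEL, None, ()),
        ("Leukocytes", ROOT_LABEL, (("CD45", "+"),)),
        ("MLCs", "Leukocytes", (("CD11b", "+"),)),
        ("Monocytes/macrophages", "MLCs", (("Ly6C", "+"), ("Ly6G", "-"))),
        ("Granulocytes", "MLCs", (("Ly6G", "+"), ("Ly6C", "-"))),
        ("Tgm2+ macrophages", "Monocytes/macrophages", (("Tgm2", "+"),)),
        ("Arg1+ macrophages", "Monocytes/macrophages", (("Arg1", "+"),)),
        ("Cxcl9+ macrophages", "Monocytes/macrophages", (("Cxcl9", "+"),)),
        ("Nos2+ macrophages", "Monocytes/macrophages", (("Nos2", "+"),)),
    ),
}
# the modified lymphoid panel drops the NK identifier entirely
_PANEL_NODES["3mod"] = tuple(
    node for node in _PANEL_NODES["3"] if node[0] != "NK cells"
)
# the tumor-tissue variant of panel 1 shares its gate structure
_PANEL_NODES["1t"] = _PANEL_NODES["1"]


def builtin_panels(thresholds: Mapping[str, float] | float | None = None) -> dict[str, GateTree]:
    """Gate trees for the builtin antibody panels (ids 1, 1t, 2, 3, 3mod, 4).

    ``thresholds`` may be a single cutoff for every marker or a per-marker
    mapping; markers not covered fall back to the default cutoff that
    matches the builtin synthetic marker models.
    """
    def cutoff(marker: str) -> float:
        if thresholds is None:
            return DEFAULT_THRESHOLD
        if isinstance(thresholds, Mapping):
            return float(thresholds.get(marker, DEFAULT_THRESHOLD))
        return float(thresholds)

    panels: dict[str, GateTree] = {}
    for panel, node_spec in _PANEL_NODES.items():
        nodes = {
            label: (parent, tuple(GateDefinition(m, s, cutoff(m)) for m, s in gates))
            for label, parent, gates in node_spec
        }
        panels[panel] = GateTree(nodes, root=ROOT_LABEL)
    return panels


# ---------------------------------------------------------------------------
# Threshold estimation for external event tables
# ---------------------------------------------------------------------------

def estimate_thresholds(events, bins: int = 128, smooth: int = 5) -> dict[str, float]:
    """Per-marker cutoff at the density valley between the two largest modes.

    Deterministic replacement for manual gating: log10 intensities are
    histogrammed, lightly smoothed, and the threshold is placed at the
    minimum between the two most prominent peaks. Markers whose histogram
    shows a single mode fall back to the midpoint of the intensity range.
    """
    frame = _intensity_frame(events)
    out: dict[str, float] = {}
    for marker in frame.columns:
        values = frame[marker].to_numpy(dtype=float)
        values = values[values > 0]
        if values.size == 0:
            raise GatingError(f"marker {marker!r} has no positive intensities")
        log_vals = np.log10(values)
        hist, edges = np.histogram(log_vals, bins=bins)
        kernel = np.ones(smooth) / smooth
        density = np.convolve(hist, kernel, mode="same")
        peaks, props = signal.find_peaks(density, prominence=density.max() * 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if len(peaks) < 2:
            out[marker] = float(10 ** (0.5 * (log_vals.min() + log_vals.max())))
            continue
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        valley = lo + int(np.argmin(density[lo : hi + 1]))
        out[marker] = float(10 ** centers[valley])
    return out


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------

def tree_to_json(tree: GateTree) -> str:
    payload = {
        "root": tree.root,
        "nodes": [
            {
                "label": label,
                "parent": parent,
                "gates": [
                    {"marker": g.marker, "sign": g.sign, "threshold": g.threshold}
                    for g in gates
                ],
            }
            for label, (parent, gates) in tree.nodes.items()
        ],
    }
    return json.dumps(payload, indent=2)


def tree_from_json(text: str) -> GateTree:
    payload = json.loads(text)
    nodes = {
        node["label"]: (
            node["parent"],
            tuple(
                GateDefinition(g["marker"], g["sign"], g.get("threshold", DEFAULT_THRESHOLD))
                for g in node["gates"]
            ),
        )
        for node in payload["nodes"]
    }
    return GateTree(nodes, root=payload["root"])
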