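import numpy as np
import pandas as pd
import pytest

from immunoflow.gating import GateTree


@pytest.fixture
def two_marker_models():
    from immunoflow.synthetic import MarkerModel

    return [MarkerModel("A"), MarkerModel("B")]


@pytest.fixture
def toy_events():
    """10 hand-written events: 5 CD45-high, 5 CD45-low."""
    frame = pd.DataFrame(
        {
            "CD45": [1000.0, 900.0, 1100.0, 980.0, 1050.0, 10.0, 12.0, 9.0, 11.0, 8.0],
            "CD8": [1000.0, 10.0, 1000.0, 10.0, 1000.0, 10.0, 10.0, 10.0, 10.0, 10.0],
        }
    )
    return frame


def brute_force_gate(frame: pd.DataFrame, tree: GateTree) -> dict[str, int]:
    """Independent per-event oracle: walk the tree for every event separately."""
    counts = {label: 0 for label in tree.nodes}
    for _, row in frame.iterrows():
        for label in tree.nodes:
            ok = True
            cur = label
            while cur is not None and ok:
                parent, gates = tree.nodes[cur]
                for g in gates:
                    value = row[g.marker]
                    sat = value > g.threshold if g.sign == "+" else value <= g.threshold
                    if not sat:
                        ok = False
                        break
                cur = parent
            if ok:
                counts[label] += 1
    return counts


def random_event_frame(rng: np.random.Generator, n_events: int, markers) -> pd.DataFrame:
    """Bimodal random intensities spanning both sides of the default cutoff."""
    data = {}
    for m in markers:
        positive = rng.random(n_events) < rng.random()
        loc = np.where(positive, 3.0, 1.0)
        data[m] = 10.0 ** rng.normal(loc, 0.2)
    return pd.DataFrame(data)
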