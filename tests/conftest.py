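import numpy as np
import pandas as pd
import pytest

from irtnorm.calibration import precursor_id


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def replicate_table(rng):
    """Three replicate runs of 200 precursors plus the two kit anchors.

    Apex RTs vary by a small per-run jitter around a common mean; the kit
    peptides elute at ~10 and ~70 minutes.
    """
    n = 200
    rts = np.sort(rng.uniform(5.0, 115.0, n))
    rows = []
    for run in range(3):
        for i, rt in enumerate(rts):
            rows.append({
                "run_id": f"r{run}",
                "precursor_id": precursor_id(f"PEP{i}", 2),
                "rt_apex": rt + rng.normal(0.0, 0.05),
            })
        rows.append({"run_id": f"r{run}", "precursor_id": "iRT-pep-b/2",
                     "rt_apex": 10.0 + rng.normal(0.0, 0.01)})
        rows.append({"run_id": f"r{run}", "precursor_id": "iRT-pep-l/2",
                     "rt_apex": 70.0 + rng.normal(0.0, 0.01)})
    return pd.DataFrame(rows)


def make_fragment_rows(run_id, pid, n_fragments=5, mz0=350.0, top=1000.0):
    """Annotated fragment rows that all pass the library filters."""
    series = [("y", 3), ("y", 4), ("b", 3), ("b", 4), ("y", 5), ("b", 5),
              ("y", 6), ("b", 6), ("y", 7)]
    return [{
        "run_id": run_id, "precursor_id": pid, "series": s, "ordinal": o,
        "fragment_charge": 1, "mz": mz0 + 90.0 * k, "intensity": top - 90.0 * k,
    } for k, (s, o) in enumerate(series[:n_fragments])]
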