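import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from allokin import (
    ShiftTable,
    SyntheticShiftConfig,
    generate_shift_dataset,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

STATES = ["apo", "ADP", "ATPgN", "ATPgN+PKI"]


def make_table(trajectories, states=None, lw=(0.02, 0.2)):
    """Build a ShiftTable from {residue_id: [(dH, dN), ...]} in state order."""
    states = states or STATES
    rows = []
    for rid, pts in trajectories.items():
        assert len(pts) == len(states)
        for s, (dh, dn) in zip(states, pts):
            rows.append(
                dict(residue_id=rid, residue_label=f"R{rid}", state=s,
                     delta_H=dh, delta_N=dn, lw_H=lw[0], lw_N=lw[1])
            )
    return ShiftTable(pd.DataFrame(rows), states=states)


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = SyntheticShiftConfig(
        n_residues=40, networked_fraction=0.6, noise_sd_H=0.0, noise_sd_N=0.0, seed=3
    )
    return generate_shift_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    # noise at 10% of the response scale
    cfg = SyntheticShiftConfig(
        n_residues=100, networked_fraction=0.6,
        noise_sd_H=0.015, noise_sd_N=0.1, seed=7,
    )
    return generate_shift_dataset(cfg)


def brute_force_abs_pearson(traces: np.ndarray) -> np.ndarray:
    """Hand-coded |Pearson| over rows of `traces` (independent oracle)."""
    n = traces.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            x = traces[i] - traces[i].mean()
            y = traces[j] - traces[j].mean()
            out[i, j] = abs(float(x @ y) / np.sqrt(float(x @ x) * float(y @ y)))
    return out
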