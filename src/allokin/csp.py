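"""Combined ¹H/¹⁵N chemical-shift perturbations between two ligation states.

The combined CSP weights the ¹⁵N shift change to put both nuclei on a common
ppm scale:  Δδ = √((ΔδH)² + (w·ΔδN)²) with w = 0.154, the standard amide
scaling factor.  A residue is flagged significant when its Δδ exceeds the
profile mean by a configurable number of standard deviations (default 1 SD,
the conventional responder threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .shift_io import ShiftTable, complete_residues

logger = logging.getLogger(__name__)

#: ¹⁵N scaling weight in the combined CSP.
N_WEIGHT = 0.154


@dataclass(frozen=True)
class CSPResult:
    residue_id: int
    delta_dH: float
    delta_dN: float
    combined: float
    significant: bool


def combined_csp(dH: float, dN: float, n_weight: float = N_WEIGHT) -> float:
    """Combined amide CSP in ppm: √(dH² + (n_weight·dN)²)."""
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise DomainError("CSP inputs must be finite")
    out = np.sqrt(dH**2 + (n_weight * dN) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_profile(
    table: ShiftTable,
    state_a: str,
    state_b: str,
    sd_multiplier: float = 1.0,
    n_weight: float = N_WEIGHT,
) -> list[CSPResult]:
    """Per-residue combined CSPs between two states, with significance flags.

    Significance: Δδ > mean(Δδ) + sd_multiplier · SD(Δδ) over the profile.
    Only residues complete in both states enter; fewer than 3 is an error.
    """
    table._check_states([state_a, state_b])
    residues = complete_residues(table, [state_a, state_b])
    if len(residues) < 3:
        raise InsufficientDataError(
            f"need >= 3 residues complete in {state_a!r} and {state_b!r}; got {len(residues)}"
        )
    recs = table.records.set_index(["residue_id", "state"])
    dH = np.array(
        [recs.loc[(r, state_b), "delta_H"] - recs.loc[(r, state_a), "delta_H"] for r in residues]
    )
    dN = np.array(
        [recs.loc[(r, state_b), "delta_N"] - recs.loc[(r, state_a), "delta_N"] for r in residues]
    )
    combined = np.sqrt(dH**2 + (n_weight * dN) ** 2)
    threshold = combined.mean() + sd_multiplier * combined.std(ddof=1)
    logger.info(
        "CSP %s→%s: %d residues, mean %.4f ppm, threshold %.4f ppm",
        state_a, state_b, len(residues), combined.mean(), threshold,
    )
    return [
        CSPResult(int(r), float(h), float(n), float(c), bool(c > threshold))
        for r, h, n, c in zip(residues, dH, dN, combined)
    ]


def profile_frame(results: list[CSPResult]) -> pd.DataFrame:
    """Tabulate a CSP profile."""
    return pd.DataFrame([vars(r) for r in results])
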