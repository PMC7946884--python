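"""CONCISE: PCA placement of ligation states along a conformational equilibrium.

Each residue whose shifts respond linearly to the open↔closed transition is
projected onto the first principal component of its per-state (δH, w·δN)
points (w = 0.154).  The per-residue score traces are standardized, aligned to
a consensus direction, and pooled per state; the per-state Gaussian fit of the
pooled scores gives the state's position ⟨PC⟩ on the equilibrium axis and its
width (how coordinated the residue-level responses are — poorly coordinated
responses give broader densities).  The axis is oriented so the apo (open)
state sits at the minimum ⟨PC⟩.

⟨PC⟩ positions convert to an extent of closure (% closed) by linear
interpolation between an open and a closed reference state, and then to
binding free-energy differences ΔΔG by an affine map anchored at
(0 % closed, 0 kcal/mol) and (100 % closed, ΔΔG_ref); the default reference
ΔΔG_ref = −15 kcal/mol is the summed RT·ln Kd of the wild-type kinase's two
sequential binding steps (nucleotide, then pseudo-substrate) at 300 K.
Uncertainties propagate from the Gaussian SDs of the densities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chesca import project_trajectory
from .csp import N_WEIGHT
from .errors import DomainError, InsufficientDataError
from .shift_io import CommunityMap, ShiftTable, complete_residues

logger = logging.getLogger(__name__)

DEFAULT_LINEARITY_MIN = 3.0
#: reference anchor: fully closed state of the wild-type enzyme
DEFAULT_DDG_CLOSED = -15.0


@dataclass
class ConciseResult:
    """Per-residue PC scores per state plus pooled per-state densities."""

    residues_used: list[int]
    scores: pd.DataFrame            # residues × states, standardized PC1 scores
    mean_pc: dict[str, float]       # state → ⟨PC⟩ (Gaussian mean)
    sd_pc: dict[str, float]         # state → Gaussian SD
    states: list[str]

    def density(self, state: str) -> tuple[float, float]:
        return self.mean_pc[state], self.sd_pc[state]


def concise_scores(
    table: ShiftTable,
    states: Sequence[str] | None = None,
    linearity_min: float = DEFAULT_LINEARITY_MIN,
    n_weight: float = N_WEIGHT,
) -> ConciseResult:
    """Run the PCA equilibrium analysis over the given state order.

    Per residue: PCA (SVD) of the mean-centered per-state (δH, w·δN) points;
    residues with singular-value ratio s₁/s₂ below ``linearity_min`` — i.e.
    trajectories that are not close to a line — are excluded.  Scores are
    standardized per residue, per-residue axes are flipped to agree with the
    consensus direction, and the global axis is oriented with the first state
    (apo) at the minimum ⟨PC⟩.
    """
    states = table._check_states(states or table.states)
    if len(states) < 3:
        raise InsufficientDataError("CONCISE requires >= 3 states")
    residues = complete_residues(table, states)
    used, traces = [], []
    for r in residues:
        traj = project_trajectory(table.trajectory(r, states), r, n_weight)
        if traj.linearity < linearity_min:
            continue
        t = traj.projected_trace
        sd = t.std(ddof=1)
        if sd == 0:
            continue  # static residue: no information about the equilibrium
        used.append(r)
        traces.append((t - t.mean()) / sd)
    if not used:
        raise InsufficientDataError(
            f"no residue passed the linearity filter (s1/s2 >= {linearity_min})"
        )
    T = np.asarray(traces)  # (n_residues, n_states)

    # Align per-residue axes (SVD sign is arbitrary): two passes — first align
    # to one reference trace, then to the consensus mean trace.
    ref = T[0]
    signs = np.sign(T @ ref)
    signs[signs == 0] = 1.0
    T = T * signs[:, None]
    consensus = T.mean(axis=0)
    signs = np.sign(T @ consensus)
    signs[signs == 0] = 1.0
    T = T * signs[:, None]

    # Global orientation: apo (first state) at the minimum mean score.
    if T[:, 0].mean() > T[:, -1].mean():
        T = -T

    scores = pd.DataFrame(T, index=used, columns=states)
    mean_pc = {s: float(scores[s].mean()) for s in states}
    # Gaussian fit by maximum likelihood: mean = sample mean, SD = sample SD
    sd_pc = {s: float(scores[s].std(ddof=0)) for s in states}
    logger.info(
        "CONCISE: %d/%d residues passed linearity >= %.1f; <PC> %s",
        len(used), len(residues), linearity_min,
        {s: round(m, 3) for s, m in mean_pc.items()},
    )
    return ConciseResult(
        residues_used=used, scores=scores, mean_pc=mean_pc, sd_pc=sd_pc,
        states=list(states),
    )


def community_concise(
    table: ShiftTable,
    cmap: CommunityMap,
    states: Sequence[str] | None = None,
    min_size: int = 3,
    **kwargs,
) -> dict[str, ConciseResult | None]:
    """Independent CONCISE run restricted to each community's residues.

    Communities with fewer than ``min_size`` usable residues are reported as
    None (undefined) with a warning.
    """
    states = table._check_states(states or table.states)
    complete = set(complete_residues(table, states))
    out: dict[str, ConciseResult | None] = {}
    for community in cmap.communities:
        members = [r for r in cmap.members(community) if r in complete]
        if len(members) < min_size:
            warnings.warn(
                f"community {community}: only {len(members)} usable residues "
                f"(< {min_size}); CONCISE undefined", stacklevel=2,
            )
            out[community] = None
            continue
        sub = table.records[
            table.records["residue_id"].isin(members)
            & table.records["state"].isin(states)
        ]
        sub_table = ShiftTable(sub, states=states, protein_id=table.protein_id)
        try:
            out[community] = concise_scores(sub_table, states, **kwargs)
        except InsufficientDataError as exc:
            warnings.warn(f"community {community}: {exc}", stacklevel=2)
            out[community] = None
    return out


def percent_closed(
    mean_pc: Mapping[str, float],
    open_ref: str,
    closed_ref: str,
) -> dict[str, float]:
    """Extent of closure per state by linear interpolation between references.

    100·(⟨PC⟩_s − ⟨PC⟩_open)/(⟨PC⟩_closed − ⟨PC⟩_open); values outside
    [0, 100] are allowed (reported with a warning).
    """
    if open_ref == closed_ref:
        raise DomainError("open and closed references must differ")
    lo, hi = mean_pc[open_ref], mean_pc[closed_ref]
    if hi == lo:
        raise DomainError("degenerate references: equal <PC> values")
    out = {s: 100.0 * (v - lo) / (hi - lo) for s, v in mean_pc.items()}
    stray = {s: p for s, p in out.items() if not 0.0 <= p <= 100.0}
    if stray:
        warnings.warn(f"percent-closed outside [0, 100] for: {stray}", stacklevel=2)
    return out


def ddg_from_closure(
    pct: float,
    ddg_closed: float = DEFAULT_DDG_CLOSED,
    ddg_open: float = 0.0,
) -> float:
    """Affine map from extent of closure to ΔΔG (kcal/mol).

    Anchored at (0 %, ddg_open) and (100 %, ddg_closed).
    """
    return ddg_open + (ddg_closed - ddg_open) * (pct / 100.0)


@dataclass
class FreeEnergyMap:
    """%-closed and ΔΔG per state with propagated uncertainties."""

    percent_closed: dict[str, float]
    ddg: dict[str, float]                  # kcal/mol
    ddg_sd: dict[str, float]               # kcal/mol, from density SDs
    anchors: dict[str, tuple[float, float]]  # state → (% closed, ΔΔG)

    def to_frame(self) -> pd.DataFrame:
        states = list(self.percent_closed)
        return pd.DataFrame(
            {
                "state": states,
                "percent_closed": [self.percent_closed[s] for s in states],
                "ddg_kcal_mol": [self.ddg[s] for s in states],
                "ddg_sd_kcal_mol": [self.ddg_sd[s] for s in states],
            }
        )


def free_energy_map(
    result: ConciseResult,
    open_ref: str | None = None,
    closed_ref: str | None = None,
    ddg_closed: float = DEFAULT_DDG_CLOSED,
    ddg_open: float = 0.0,
) -> FreeEnergyMap:
    """Map a CONCISE result onto the %-closed / ΔΔG scale.

    Defaults anchor the first state (apo, open) at 0 % / ddg_open and the last
    state (ternary, closed) at 100 % / ddg_closed.  Per-state uncertainty is
    the Gaussian density SD pushed through the same affine maps.
    """
    open_ref = open_ref or result.states[0]
    closed_ref = closed_ref or result.states[-1]
    pct = percent_closed(result.mean_pc, open_ref, closed_ref)
    span = result.mean_pc[closed_ref] - result.mean_pc[open_ref]
    ddg = {s: ddg_from_closure(p, ddg_closed, ddg_open) for s, p in pct.items()}
    scale = abs(ddg_closed - ddg_open) / abs(span)
    ddg_sd = {s: result.sd_pc[s] * scale for s in pct}
    return FreeEnergyMap(
        percent_closed=pct,
        ddg=ddg,
        ddg_sd=ddg_sd,
        anchors={open_ref: (0.0, ddg_open), closed_ref: (100.0, ddg_closed)},
    )
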