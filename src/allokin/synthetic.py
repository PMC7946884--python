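"""Ground-truth generators for multi-state shift tables, ITC isotherms and
steady-state kinetics.

The shift generator emulates a two-state open↔closed conformational exchange
in the fast NMR regime: every ligation state ``s`` sits at a latent closure
coordinate λ_s ∈ [0, 1] (apo = 0 open, nucleotide/pseudo-substrate ternary = 1
closed), and each residue on the allosteric network responds linearly,

    δ_i(s) = δ_i⁰ + a_i · λ_s + ε,   ε ~ N(0, noise_sd),

with a residue-specific response vector a_i = (a_H, a_N) in ppm.  Residues off
the network receive independent small per-state displacements drawn from the
same noise model, so they exercise the linewidth-based inclusion filter
without carrying a coordinated signal.  Before noise, all networked residues
are therefore pairwise collinear across states (|Pearson| = 1).

Default λ values (apo 0.0, ADP 0.45, ATPγN 0.55, ternary 1.0) place the two
binary complexes near the middle of the equilibrium, matching the qualitative
open/intermediate/closed progression of the kinase catalytic cycle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .shift_io import COMMUNITY_LABELS, DEFAULT_STATES, CommunityMap, ShiftTable

logger = logging.getLogger(__name__)

DEFAULT_LAMBDAS: dict[str, float] = {
    "apo": 0.0,
    "ADP": 0.45,
    "ATPgN": 0.55,
    "ATPgN+PKI": 1.0,
}


@dataclass
class SyntheticShiftConfig:
    """Parameters of the synthetic multi-state shift dataset.

    Units are ppm throughout.  ``response_scale_*`` sets the magnitude of the
    full open→closed shift change of networked residues (amide CSPs of the
    kinase are of order 0.05–0.3 ppm in ¹H and up to ~1–2 ppm in ¹⁵N);
    ``noise_sd_*`` is the per-record measurement noise, and ``linewidth_*``
    the constant Δν written into the table (typical TROSY-HSQC linewidths at
    high field are ~0.02 ppm ¹H and ~0.2 ppm ¹⁵N).
    """

    n_residues: int = 100
    state_lambdas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAMBDAS))
    networked_fraction: float = 0.6
    community_count: int = 9
    response_scale_H: float = 0.15
    response_scale_N: float = 1.0
    noise_sd_H: float = 0.005
    noise_sd_N: float = 0.05
    linewidth_H: float = 0.02
    linewidth_N: float = 0.2
    seed: int = 0
    #: optional per-community λ overrides (community → state → λ), applied to
    #: networked residues of that community only; models communities that do
    #: not reach the fully closed state.
    community_lambdas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_residues < 2:
            raise ConfigError("n_residues must be >= 2")
        if not 0.0 <= self.networked_fraction <= 1.0:
            raise ConfigError("networked_fraction must lie in [0, 1]")
        for s, lam in self.state_lambdas.items():
            if not 0.0 <= lam <= 1.0:
                raise ConfigError(f"lambda for state {s!r} must lie in [0, 1]")
        if min(self.noise_sd_H, self.noise_sd_N) < 0:
            raise ConfigError("noise SDs must be >= 0")

    @property
    def states(self) -> list[str]:
        return list(self.state_lambdas)


@dataclass
class GroundTruth:
    """Generator parameters retained for recovery tests."""

    network_members: list[int]
    response_H: dict[int, float]
    response_N: dict[int, float]
    community: dict[int, str]
    state_lambdas: dict[str, float]

    def is_networked(self, residue_id: int) -> bool:
        return residue_id in set(self.network_members)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "network_members": list(self.network_members),
            "response_H": {str(k): v for k, v in self.response_H.items()},
            "response_N": {str(k): v for k, v in self.response_N.items()},
            "community": {str(k): v for k, v in self.community.items()},
            "state_lambdas": self.state_lambdas,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            network_members=[int(r) for r in d["network_members"]],
            response_H={int(k): v for k, v in d["response_H"].items()},
            response_N={int(k): v for k, v in d["response_N"].items()},
            community={int(k): v for k, v in d["community"].items()},
            state_lambdas=d["state_lambdas"],
        )


def generate_shift_dataset(
    config: SyntheticShiftConfig,
) -> tuple[ShiftTable, CommunityMap, GroundTruth]:
    """Generate a multi-state shift table with known allosteric network.

    Deterministic under a fixed ``config.seed``: a single global seed spawns
    one sub-stream per residue, so outputs are byte-stable and independent of
    evaluation order.
    """
    cfg = config
    states = cfg.states
    rng = np.random.default_rng(cfg.seed)
    n_net = int(round(cfg.networked_fraction * cfg.n_residues))
    residue_ids = np.arange(1, cfg.n_residues + 1)
    members = np.sort(rng.choice(residue_ids, size=n_net, replace=False))
    member_set = set(int(r) for r in members)

    labels = list(COMMUNITY_LABELS[: cfg.community_count])
    if cfg.community_count > len(COMMUNITY_LABELS):
        labels += [f"Com{i}" for i in range(len(COMMUNITY_LABELS), cfg.community_count)]
    community = {int(r): labels[(int(r) - 1) % len(labels)] for r in residue_ids}

    rows = []
    resp_H: dict[int, float] = {}
    resp_N: dict[int, float] = {}
    for r in residue_ids:
        r = int(r)
        sub = np.random.default_rng([cfg.seed, r])
        base_H = sub.uniform(7.0, 10.0)
        base_N = sub.uniform(105.0, 135.0)
        if r in member_set:
            a_H = sub.choice([-1.0, 1.0]) * sub.uniform(0.5, 1.5) * cfg.response_scale_H
            a_N = sub.choice([-1.0, 1.0]) * sub.uniform(0.5, 1.5) * cfg.response_scale_N
            resp_H[r], resp_N[r] = float(a_H), float(a_N)
            lambdas = cfg.state_lambdas
            override = cfg.community_lambdas.get(community[r])
            if override:
                lambdas = {**lambdas, **override}
            for s in states:
                lam = lambdas[s]
                dH = base_H + a_H * lam + sub.normal(0.0, cfg.noise_sd_H)
                dN = base_N + a_N * lam + sub.normal(0.0, cfg.noise_sd_N)
                rows.append((r, f"R{r}", s, dH, dN))
        else:
            # off-network: independent per-state displacement, same noise model
            for s in states:
                dH = base_H + sub.normal(0.0, cfg.noise_sd_H)
                dN = base_N + sub.normal(0.0, cfg.noise_sd_N)
                rows.append((r, f"R{r}", s, dH, dN))

    df = pd.DataFrame(
        rows, columns=["residue_id", "residue_label", "state", "delta_H", "delta_N"]
    )
    df["lw_H"] = cfg.linewidth_H
    df["lw_N"] = cfg.linewidth_N
    table = ShiftTable(df, states=states, protein_id="synthetic")
    cmap = CommunityMap(assignments=community)
    truth = GroundTruth(
        network_members=[int(r) for r in members],
        response_H=resp_H,
        response_N=resp_N,
        community=community,
        state_lambdas=dict(cfg.state_lambdas),
    )
    logger.info(
        "synthetic shifts: %d residues (%d networked), %d states, seed %d",
        cfg.n_residues, n_net, len(states), cfg.seed,
    )
    return table, cmap, truth


def generate_itc_isotherm(
    kd: float,
    dh: float,
    n_inject: int = 25,
    cell_conc: float = 100.0,
    syringe_conc: float | None = None,
    v0: float = 1.0,
    noise_sd: float = 0.0,
    noise_frac: float = 0.0,
    seed: int = 0,
    rm_min: float = 0.05,
    rm_max: float = 2.5,
    temperature: float = 300.0,
):
    """Simulate a 1:1 Wiseman-model titration.

    Heats are the analytic binding-isotherm derivative evaluated at each
    injection's molar ratio Rm, optionally perturbed by additive
    (``noise_sd``, heat units) and/or multiplicative (``noise_frac``,
    fractional) Gaussian noise.  ``kd`` and ``cell_conc`` in μM, ``dh`` in
    kcal/mol.  When ``syringe_conc`` is given, the Rm grid follows equal
    injections of v0/50 each; otherwise Rm is linear on [rm_min, rm_max].
    """
    from .thermo import ITCIsotherm, wiseman_derivative  # local import: no cycle at module load

    if kd <= 0:
        raise DomainError("kd must be > 0")
    if min(cell_conc, v0) <= 0:
        raise DomainError("cell_conc and v0 must be > 0")
    if n_inject < 2:
        raise ConfigError("need at least 2 injections")
    if syringe_conc is not None:
        v_inj = v0 / 50.0
        rm = np.arange(1, n_inject + 1) * syringe_conc * v_inj / (cell_conc * v0)
    else:
        rm = np.linspace(rm_min, rm_max, n_inject)
    r = kd / cell_conc
    heats = wiseman_derivative(rm, r, dh, v0)
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        heats = heats * (1.0 + rng.normal(0.0, noise_frac, size=heats.shape))
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return ITCIsotherm(
        molar_ratio=rm,
        heats=heats,
        cell_conc=cell_conc,
        v0=v0,
        temperature=temperature,
        true_kd=kd,
        true_dh=dh,
    )


@dataclass
class _MMTruth:
    vmax: float
    km: float


def generate_mm_dataset(
    vmax: float,
    km: float,
    s_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    enzyme_conc: float | None = None,
):
    """Simulate Michaelis–Menten initial velocities v = Vmax·S/(KM+S) + ε."""
    from .kinetics import VelocityDataset

    if vmax <= 0 or km <= 0:
        raise DomainError("vmax and km must be > 0")
    s = np.asarray(list(s_grid), dtype=float)
    if s.size == 0:
        raise ConfigError("s_grid must not be empty")
    v = vmax * s / (km + s)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return VelocityDataset(
        substrate_conc=s, velocity=v, enzyme_conc=enzyme_conc,
        true_vmax=vmax, true_km=km,
    )
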