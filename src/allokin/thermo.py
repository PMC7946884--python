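"""ITC binding thermodynamics: Wiseman isotherm, ΔG/TΔS, cooperativity σ.

A 1:1 titration measured by ITC yields, per injection, the heat per mole of
injectant.  For total protein (cell) concentration [M]tot, r = Kd/[M]tot and
molar ratio Rm = [X]tot/[M]tot, the analytic isotherm derivative is

    d[MX]/d[Xtot] = ΔH°·V₀·[ 1/2 + (1 − (1−r)/2 − Rm/2)
                              / √(Rm² − 2Rm(1−r) + (1+r)²) ],

a sigmoid in Rm whose steepness encodes Kd and whose amplitude encodes ΔH°.
Fitting (Kd, ΔH°) to the measured heats, the thermodynamic decomposition is
ΔG = RT·ln Kd (Kd molar) and TΔS = ΔH − ΔG.

K-type binding cooperativity between a nucleotide and a (pseudo-)substrate is
quantified by σ = Kd(apo)/Kd(nucleotide-bound): σ > 1 means the nucleotide
enhances substrate affinity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InsufficientDataError

logger = logging.getLogger(__name__)

#: universal gas constant, kcal/(mol·K)
R_KCAL = 1.9872e-3
#: default measurement temperature, K
DEFAULT_TEMPERATURE = 300.0


@dataclass
class ITCIsotherm:
    """Injection-wise normalized heats of a 1:1 titration."""

    molar_ratio: np.ndarray     # Rm = [X]tot/[M]tot, strictly increasing
    heats: np.ndarray           # heat per mole injectant (ΔH units × V0)
    cell_conc: float            # [M]tot, μM
    v0: float = 1.0             # cell volume (arbitrary consistent units)
    temperature: float = DEFAULT_TEMPERATURE
    true_kd: float | None = None  # ground truth when simulated
    true_dh: float | None = None

    def __post_init__(self):
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.molar_ratio.shape != self.heats.shape:
            raise DomainError("molar_ratio and heats must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise DomainError("molar ratios must be strictly increasing")
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0")

    def __len__(self) -> int:
        return len(self.heats)


def wiseman_derivative(rm, r: float, dh: float, v0: float = 1.0):
    """Analytic 1:1 isotherm derivative (heat per mole injectant) at Rm.

    ``r`` is Kd/[M]tot (dimensionless), ``dh`` the molar binding enthalpy.
    Derived from the 1:1 mass balance Θ² − Θ(1 + Rm + r) + Rm = 0:

        dΘ/dRm = 1/2 + (1 − (1+r)/2 − Rm/2) / √(Rm² − 2Rm(1−r) + (1+r)²).

    The discriminant must be positive (it always is for r > 0; at r = 0 it
    vanishes at Rm = 1).  Limits: value 1·ΔH°V₀ at Rm = 0, r = 0 (every
    injected mole binds); → 0 at saturation (Rm → ∞) and for very weak
    binding (r → ∞).
    """
    rm = np.asarray(rm, dtype=float)
    if r < 0:
        raise DomainError("r must be >= 0")
    disc = rm**2 - 2.0 * rm * (1.0 - r) + (1.0 + r) ** 2
    if np.any(disc <= 0):
        raise DomainError("non-positive discriminant in the isotherm derivative")
    bracket = 0.5 + (1.0 - (1.0 + r) / 2.0 - rm / 2.0) / np.sqrt(disc)
    out = dh * v0 * bracket
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingFit:
    """Fitted 1:1 binding parameters."""

    kd: float                   # μM
    dh: float                   # kcal/mol
    n_sites: float = 1.0
    r: float = float("nan")     # Kd/[M]tot
    residual_norm: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.kd) and self.kd <= 0:
            raise DomainError("fitted kd must be > 0")


_KD_BOUNDS = (1e-6, 1e6)  # μM, generous physical window


def fit_isotherm(iso: ITCIsotherm, init: tuple[float, float] | None = None,
                 fix_n: bool = True) -> BindingFit:
    """Least-squares fit of (Kd, ΔH°) — optionally also n — to an isotherm.

    Requires at least 8 injections spanning molar ratios below and above 1.
    ``init`` is an optional (kd μM, dh) starting guess; otherwise ΔH° starts
    at the first heat and Kd at the best point of a log-spaced scan, making
    the fit deterministic.  All-zero heats are degenerate (ΔH° → 0, Kd
    unidentifiable): a warning is issued and kd is returned as NaN.
    """
    rm, h = iso.molar_ratio, iso.heats
    if len(iso) < 8:
        raise InsufficientDataError("need >= 8 injections")
    if not (rm.min() < 1.0 < rm.max()):
        raise InsufficientDataError("injections must span molar ratios below and above 1")
    scale = np.max(np.abs(h))
    if scale == 0 or not np.isfinite(scale):
        warnings.warn("all heats are zero: ΔH°→0 and Kd is unidentifiable", stacklevel=2)
        return BindingFit(kd=float("nan"), dh=0.0, residual_norm=0.0)

    def model(log_kd, dh, n=1.0):
        r = math.exp(log_kd) / iso.cell_conc
        return wiseman_derivative(rm / n, r, dh, iso.v0)

    if init is None:
        dh0 = h[0] / iso.v0
        grid = np.log(np.geomspace(1e-3, 10.0, 25) * iso.cell_conc)
        sse = [np.sum((model(lk, dh0) - h) ** 2) for lk in grid]
        log_kd0 = float(grid[int(np.argmin(sse))])
    else:
        log_kd0 = math.log(init[0])
        dh0 = init[1]

    lo, hi = math.log(_KD_BOUNDS[0]), math.log(_KD_BOUNDS[1])
    if fix_n:
        x0 = [log_kd0, dh0]
        bounds = ([lo, -np.inf], [hi, np.inf])
        fun = lambda x: model(x[0], x[1]) - h
    else:
        x0 = [log_kd0, dh0, 1.0]
        bounds = ([lo, -np.inf, 0.1], [hi, np.inf, 10.0])
        fun = lambda x: model(x[0], x[1], x[2]) - h
    sol = least_squares(fun, x0=x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise FitError(f"isotherm fit did not converge: {sol.message}")
    kd = math.exp(sol.x[0])
    if kd <= _KD_BOUNDS[0] * 1.01 or kd >= _KD_BOUNDS[1] * 0.99:
        warnings.warn(f"fitted Kd pinned near bound ({kd:.3g} μM)", stacklevel=2)
    fit = BindingFit(
        kd=kd,
        dh=float(sol.x[1]),
        n_sites=1.0 if fix_n else float(sol.x[2]),
        r=kd / iso.cell_conc,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )
    logger.info("isotherm fit: Kd %.4g μM, ΔH %.4g, residual %.3g",
                fit.kd, fit.dh, fit.residual_norm)
    return fit


@dataclass(frozen=True)
class ThermoDecomposition:
    dG: float           # kcal/mol
    dH: float           # kcal/mol
    TdS: float          # kcal/mol, = dH − dG exactly
    temperature: float  # K
    gas_constant: float = R_KCAL


def delta_g(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy ΔG = RT·ln Kd in kcal/mol (``kd`` in μM)."""
    if kd <= 0:
        raise DomainError("kd must be > 0")
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    return R_KCAL * temperature * math.log(kd * 1e-6)


def t_delta_s(dh: float, dg: float) -> float:
    """Entropic contribution TΔS = ΔH − ΔG (kcal/mol)."""
    if not (np.isfinite(dh) and np.isfinite(dg)):
        raise DomainError("inputs must be finite")
    return dh - dg


def decompose(kd: float, dh: float, temperature: float = DEFAULT_TEMPERATURE) -> ThermoDecomposition:
    dg = delta_g(kd, temperature)
    return ThermoDecomposition(dG=dg, dH=dh, TdS=t_delta_s(dh, dg), temperature=temperature)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CooperativityResult:
    kd_apo: float        # μM
    kd_nucleotide: float  # μM
    sigma: float         # dimensionless, Kd_apo/Kd_nucleotide
    fold_label: int      # nearest-integer fold


def cooperativity_sigma(kd_apo: float, kd_nucleotide: float) -> CooperativityResult:
    """Binding cooperativity constant σ = Kd(apo)/Kd(nucleotide-bound).

    σ > 1 indicates positive K-type cooperativity (nucleotide binding
    enhances the substrate's affinity).
    """
    if kd_apo <= 0 or kd_nucleotide <= 0:
        raise DomainError("dissociation constants must be > 0")
    sigma = kd_apo / kd_nucleotide
    return CooperativityResult(
        kd_apo=kd_apo, kd_nucleotide=kd_nucleotide,
        sigma=sigma, fold_label=_round_half_away(sigma),
    )


def fold_change(value_a: float, value_b: float) -> tuple[float, int]:
    """Ratio a/b with a nearest-integer fold label (round half away from zero)."""
    if value_b == 0:
        raise DomainError("zero denominator in fold change")
    if value_a <= 0 or value_b <= 0:
        raise DomainError("fold change requires positive values")
    ratio = value_a / value_b
    return ratio, _round_half_away(ratio)
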