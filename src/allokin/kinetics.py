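"""Steady-state Michaelis–Menten kinetics and catalytic efficiency.

Initial velocities v(S) = Vmax·S/(KM + S) are fit by unweighted non-linear
least squares; standard errors come from the fit covariance.  Catalytic
efficiency kcat/KM (with kcat = Vmax/[E]) carries an error propagated in
quadrature from the kcat and KM standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class VelocityDataset:
    """Substrate-concentration / initial-velocity table (μM, μM/s)."""

    substrate_conc: np.ndarray
    velocity: np.ndarray
    enzyme_conc: float | None = None   # μM
    replicate_id: np.ndarray | None = None
    true_vmax: float | None = None     # ground truth when simulated
    true_km: float | None = None

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_conc.shape != self.velocity.shape:
            raise DomainError("substrate and velocity arrays must have equal length")
        if np.any(self.substrate_conc < 0):
            raise DomainError("substrate concentrations must be >= 0")

    def averaged(self) -> "VelocityDataset":
        """Average replicate velocities at identical substrate concentrations."""
        df = pd.DataFrame({"s": self.substrate_conc, "v": self.velocity})
        g = df.groupby("s", sort=True)["v"].mean().reset_index()
        return VelocityDataset(
            substrate_conc=g["s"].to_numpy(), velocity=g["v"].to_numpy(),
            enzyme_conc=self.enzyme_conc,
            true_vmax=self.true_vmax, true_km=self.true_km,
        )


def _mm(s, vmax, km):
    return vmax * s / (km + s)


@dataclass
class MMFit:
    vmax: float        # μM/s
    vmax_se: float
    km: float          # μM
    km_se: float
    residual_norm: float = float("nan")


def fit_mm(
    data: VelocityDataset,
    init: tuple[float, float] | None = None,
    average_replicates: bool = False,
) -> MMFit:
    """Unweighted least-squares fit of (Vmax, KM) to initial velocities.

    Requires at least 4 distinct substrate concentrations spanning both sides
    of KM (checked post hoc with a warning, since KM is unknown a priori).
    Near-zero KM estimates (velocity saturated over the whole grid) get a
    boundary warning.
    """
    if average_replicates:
        data = data.averaged()
    s, v = data.substrate_conc, data.velocity
    if len(np.unique(s)) < 4:
        raise InsufficientDataError("need >= 4 distinct substrate concentrations")
    if init is None:
        vmax0 = float(np.max(v))
        if vmax0 <= 0:
            raise FitError("all velocities are non-positive")
        half = np.abs(v - vmax0 / 2.0)
        km0 = float(max(s[int(np.argmin(half))], np.min(s[s > 0], initial=1.0)))
        init = (vmax0, km0)
    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=init, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = (float(x) for x in popt)
    if vmax <= 0 or km < 0:
        raise FitError(f"unphysical estimates: Vmax={vmax:.3g}, KM={km:.3g}")
    if km < np.min(s[s > 0]) / 100.0:
        warnings.warn(
            f"KM estimate ({km:.3g} μM) far below the substrate grid: saturated data",
            stacklevel=2,
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = float(np.linalg.norm(_mm(s, vmax, km) - v))
    if not (s.min() < km < s.max()):
        warnings.warn("substrate grid does not bracket the fitted KM", stacklevel=2)
    logger.info("MM fit: Vmax %.4g μM/s, KM %.4g μM", vmax, km)
    return MMFit(vmax=vmax, vmax_se=float(se[0]), km=km, km_se=float(se[1]),
                 residual_norm=resid)


@dataclass(frozen=True)
class CatalyticEfficiency:
    kcat: float            # 1/s
    kcat_se: float
    efficiency: float      # kcat/KM, 1/(μM·s)
    efficiency_se: float


def catalytic_efficiency(fit: MMFit, enzyme_conc: float) -> CatalyticEfficiency:
    """kcat = Vmax/[E] and kcat/KM with quadrature error propagation.

    Relative error of kcat/KM is √((SE_kcat/kcat)² + (SE_KM/KM)²); the enzyme
    concentration is treated as exact.
    """
    if enzyme_conc <= 0:
        raise DomainError("enzyme concentration must be > 0")
    if fit.km == 0:
        raise DomainError("zero KM: efficiency undefined")
    kcat = fit.vmax / enzyme_conc
    kcat_se = fit.vmax_se / enzyme_conc
    eff = kcat / fit.km
    rel = np.hypot(
        kcat_se / kcat if kcat != 0 else 0.0,
        fit.km_se / fit.km,
    )
    return CatalyticEfficiency(
        kcat=kcat, kcat_se=kcat_se, efficiency=eff, efficiency_se=eff * rel
    )
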