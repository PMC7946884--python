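"""Chemical-shift covariance analysis (CHESCA) across ligation states.

For a binding process in the fast NMR exchange regime, residues that belong
to one allosteric network trace out collinear chemical-shift trajectories as
the ligation state changes; their state-to-state shift changes are therefore
linearly correlated.  The analysis proceeds in four stages:

1. *Inclusion filter* — a residue enters only if, for some pair of states
   (A, B), its shift change in the ¹H or ¹⁵N dimension exceeds the mean of
   its two linewidths in that dimension, Δδ > ½Δν_A + ½Δν_B (which pair
   satisfies it is irrelevant).
2. *Projection* — each residue's per-state (δH, w·δN) points (w = 0.154) are
   mean-centered and projected on their first right singular vector, giving a
   1-D trace per state; the ratio of the first two singular values measures
   how linear the trajectory is.
3. *Correlation matrix* — R_ij = |Pearson| between projected traces; pairs
   with R_ij above a cutoff (default 0.98) count as networked.  Per-residue
   correlation scores divide each residue's partner count by a fixed
   denominator (the number of analyzed residues by default).
4. *Aggregation* — agglomerative clustering on distance 1 − R_ij, and the
   community-level matrix R_X,Y = #(R_ij > R_cutoff)/(n_X·n_Y) at a relaxed
   cutoff (default 0.8).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .csp import N_WEIGHT
from .errors import ConfigError, DomainError, InsufficientDataError
from .shift_io import CommunityMap, ShiftTable, complete_residues

logger = logging.getLogger(__name__)

#: strict |Pearson| cutoff for residue-pair correlations
DEFAULT_CUTOFF = 0.98
#: relaxed cutoff for community-level scoring
DEFAULT_COMMUNITY_CUTOFF = 0.8
#: fallback linewidths (ppm) when a table carries none
DEFAULT_FALLBACK_LW = (0.03, 0.3)


# ---------------------------------------------------------------------------
# inclusion filter
# ---------------------------------------------------------------------------

def filter_responsive_residues(
    table: ShiftTable,
    states: Sequence[str] | None = None,
    fallback_lw: tuple[float, float] | None = DEFAULT_FALLBACK_LW,
) -> list[int]:
    """Residues whose shift response exceeds their linewidths.

    A residue is kept iff for some state pair (A, B) and some dimension
    (¹H or ¹⁵N) the shift change exceeds the mean of its linewidths in the
    two states:  |δ(A) − δ(B)| > (Δν_A + Δν_B)/2.

    Tables without linewidths fall back to ``fallback_lw = (lw_H, lw_N)``
    with a warning; pass ``fallback_lw=None`` to make that an error.
    """
    states = table._check_states(states or table.states)
    residues = complete_residues(table, states)
    recs = table.records[table.records["state"].isin(states)]
    have_lw = np.isfinite(recs[["lw_H", "lw_N"]].to_numpy()).all()
    if not have_lw:
        if fallback_lw is None:
            raise ConfigError(
                "table has no linewidths and no fallback linewidths configured"
            )
        warnings.warn(
            f"no linewidths in table; using fallback Δν = {fallback_lw} ppm (H, N)",
            stacklevel=2,
        )
    kept = []
    recs = recs.set_index(["residue_id", "state"])
    for r in residues:
        sub = recs.loc[r].loc[states]
        dh = sub["delta_H"].to_numpy(float)
        dn = sub["delta_N"].to_numpy(float)
        lwh = sub["lw_H"].to_numpy(float)
        lwn = sub["lw_N"].to_numpy(float)
        if not have_lw:
            lwh = np.full_like(dh, fallback_lw[0])
            lwn = np.full_like(dn, fallback_lw[1])
        ok = False
        for a, b in combinations(range(len(states)), 2):
            if abs(dh[a] - dh[b]) > 0.5 * (lwh[a] + lwh[b]):
                ok = True
                break
            if abs(dn[a] - dn[b]) > 0.5 * (lwn[a] + lwn[b]):
                ok = True
                break
        if ok:
            kept.append(int(r))
    logger.info(
        "inclusion filter: %d of %d complete residues responsive across %d states",
        len(kept), len(residues), len(states),
    )
    return kept


# ---------------------------------------------------------------------------
# per-residue trajectory projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueTrajectory:
    """1-D projection of one residue's per-state (δH, δN) trajectory."""

    residue_id: int
    points: np.ndarray           # (n_states, 2) raw (δH, δN)
    projected_trace: np.ndarray  # (n_states,) scores on the first singular vector
    linearity: float             # s1/s2 of the centered weighted points (inf if s2=0)


def project_trajectory(
    points: np.ndarray,
    residue_id: int = -1,
    n_weight: float = N_WEIGHT,
) -> ResidueTrajectory:
    """Project per-state (δH, δN) points onto their principal direction.

    The ¹⁵N coordinate is scaled by ``n_weight`` so both dimensions share a
    common ppm scale, points are mean-centered, and an SVD supplies the first
    right singular vector.  Linearity is the singular-value ratio s₁/s₂
    (infinite for perfectly collinear trajectories).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 states of (δH, δN) points")
    scaled = pts * np.array([1.0, n_weight])
    centered = scaled - scaled.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    trace = centered @ vt[0]
    # s2 at rounding-noise level means the points are collinear
    linearity = float("inf") if s[1] <= s[0] * 1e-9 else float(s[0] / s[1])
    return ResidueTrajectory(
        residue_id=int(residue_id), points=pts, projected_trace=trace, linearity=linearity
    )


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Symmetric |Pearson| matrix over residue traces."""

    residues: list[int]
    R: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.residues)
        if self.R.shape != (n, n):
            raise DomainError("R must be square over the residue list")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise DomainError("R must be symmetric")
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-12):
            raise DomainError("entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.residues, columns=self.residues)

    def value(self, i: int, j: int) -> float:
        return float(self.R[self.residues.index(i), self.residues.index(j)])


def _traces(
    table: ShiftTable,
    residues: Sequence[int],
    states: Sequence[str],
    method: str,
    n_weight: float,
) -> tuple[list[int], np.ndarray]:
    """Per-residue 1-D state traces; zero-variance residues dropped."""
    kept, rows = [], []
    for r in residues:
        pts = table.trajectory(r, states)
        if method == "svd":
            trace = project_trajectory(pts, r, n_weight).projected_trace
        elif method == "proton":
            trace = pts[:, 0] - pts[:, 0].mean()
        elif method == "nitrogen":
            trace = pts[:, 1] - pts[:, 1].mean()
        else:
            raise ConfigError(f"unknown trace method {method!r}")
        if np.allclose(trace, 0.0):
            warnings.warn(
                f"residue {r}: zero-variance trace, Pearson undefined; dropped",
                stacklevel=3,
            )
            continue
        kept.append(int(r))
        rows.append(trace)
    return kept, np.asarray(rows)


def correlation_matrix(
    table: ShiftTable,
    residues: Sequence[int] | None = None,
    states: Sequence[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "svd",
    n_weight: float = N_WEIGHT,
) -> CorrelationMatrix:
    """|Pearson| correlation matrix between residue shift trajectories.

    ``method='svd'`` (default) correlates the 1-D SVD-projected traces;
    ``'proton'``/``'nitrogen'`` correlate a single dimension instead.
    Requires at least 4 states for a meaningful correlation over states.
    """
    states = table._check_states(states or table.states)
    if len(states) < 4:
        raise InsufficientDataError("CHESCA correlations require >= 4 states")
    if residues is None:
        residues = filter_responsive_residues(table, states)
    kept, traces = _traces(table, residues, states, method, n_weight)
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 residues with usable traces")
    R = np.abs(np.corrcoef(traces))
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, 0.0, 1.0)
    return CorrelationMatrix(residues=kept, R=R, cutoff=cutoff)


# ---------------------------------------------------------------------------
# per-residue scores
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScoreProfile:
    scores: dict[int, float]
    denominator: int
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.scores.items()), columns=["residue_id", "score"]
        )


def correlation_scores(
    matrix: CorrelationMatrix,
    denominator: int | None = None,
    cutoff: float | None = None,
) -> CorrelationScoreProfile:
    """Per-residue correlation score: partners with R_ij > cutoff, divided by
    a fixed denominator (number of analyzed residues unless specified, e.g.
    350 for the full kinase)."""
    if denominator is None:
        denominator = len(matrix.residues)
    if denominator <= 0:
        raise DomainError("denominator must be > 0")
    cutoff = matrix.cutoff if cutoff is None else cutoff
    R = matrix.R.copy()
    np.fill_diagonal(R, 0.0)  # exclude self
    counts = (R > cutoff).sum(axis=1)
    scores = {r: float(c) / denominator for r, c in zip(matrix.residues, counts)}
    return CorrelationScoreProfile(scores=scores, denominator=denominator, cutoff=cutoff)


# ---------------------------------------------------------------------------
# agglomerative clustering
# ---------------------------------------------------------------------------

def cluster_residues(
    matrix: CorrelationMatrix,
    linkage: str = "average",
    threshold: float | None = None,
) -> dict[int, int]:
    """Agglomerative clustering of residues on distance 1 − R_ij.

    Returns residue → cluster id; clusters keep ids only if they hold >= 2
    members, singletons are labelled 0.  Default threshold is 1 − cutoff.
    """
    if linkage not in ("average", "complete"):
        raise ConfigError("linkage must be 'average' or 'complete'")
    if threshold is None:
        threshold = 1.0 - matrix.cutoff
    n = len(matrix.residues)
    if n == 1:
        return {matrix.residues[0]: 0}
    D = 1.0 - matrix.R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    raw = fcluster(Z, t=threshold, criterion="distance")
    # renumber: multi-member clusters get 1..k in order of appearance, singletons 0
    sizes = pd.Series(raw).value_counts()
    mapping, next_id = {}, 1
    out = {}
    for res, lab in zip(matrix.residues, raw):
        if sizes[lab] < 2:
            out[res] = 0
            continue
        if lab not in mapping:
            mapping[lab] = next_id
            next_id += 1
        out[res] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# community-level matrix
# ---------------------------------------------------------------------------

@dataclass
class CommunityCorrelationMatrix:
    communities: list[str]
    R: pd.DataFrame           # community × community, NaN where undefined
    n: dict[str, int]
    cutoff: float = DEFAULT_COMMUNITY_CUTOFF

    def value(self, x: str, y: str) -> float:
        return float(self.R.loc[x, y])


def community_correlation(
    matrix: CorrelationMatrix,
    cmap: CommunityMap,
    r_cutoff: float = DEFAULT_COMMUNITY_CUTOFF,
) -> CommunityCorrelationMatrix:
    """Community-pair correlation scores.

    Cross term:  R_X,Y = #{(i ∈ X, j ∈ Y) : R_ij > r_cutoff} / (n_X·n_Y).
    Diagonal:    unordered distinct pairs within X divided by n_X(n_X−1)/2.
    Residues without a community assignment are excluded from counts and n;
    entries whose denominator vanishes are NaN (undefined, not 0).
    """
    idx_of = {r: k for k, r in enumerate(matrix.residues)}
    members: dict[str, list[int]] = {}
    for r in matrix.residues:
        c = cmap.assignments.get(r)
        if c is not None:
            members.setdefault(c, []).append(r)
    communities = sorted(members)
    if not communities:
        raise InsufficientDataError("no scored residue maps to any community")
    n = {c: len(members[c]) for c in communities}
    out = pd.DataFrame(np.nan, index=communities, columns=communities, dtype=float)
    for a, X in enumerate(communities):
        for Y in communities[a:]:
            ix = [idx_of[r] for r in members[X]]
            iy = [idx_of[r] for r in members[Y]]
            block = matrix.R[np.ix_(ix, iy)]
            if X == Y:
                denom = n[X] * (n[X] - 1) / 2
                if denom == 0:
                    warnings.warn(f"community {X}: fewer than 2 residues, R_X,X undefined",
                                  stacklevel=2)
                    continue
                iu = np.triu_indices(n[X], k=1)
                count = int((block[iu] > r_cutoff).sum())
            else:
                denom = n[X] * n[Y]
                count = int((block > r_cutoff).sum())
            out.loc[X, Y] = out.loc[Y, X] = count / denom
    return CommunityCorrelationMatrix(communities=communities, R=out, n=n, cutoff=r_cutoff)
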