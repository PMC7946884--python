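"""I/O and containers for multi-state amide chemical-shift tables.

The central container is :class:`ShiftTable`: one row per (residue, ligation
state) holding the amide ¹H and ¹⁵N chemical shifts in ppm, with optional
linewidths (Δν, ppm).  Ligation states carry an explicit order — by convention
the apo (open) form first and the nucleotide/pseudo-substrate ternary (closed)
form last — because downstream covariance and equilibrium analyses interpret
the state axis as a progression along the open↔closed coordinate.

Residue→community maps group residues into functional communities (the nine
ComA…ComH/ComF1 groups commonly used for the PKA-C kinase core) for
community-level correlation scoring.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, LookupStateError

logger = logging.getLogger(__name__)

#: Canonical order of the four ligation states used throughout: apo (open),
#: ADP-bound, ATPγN-bound and the ATPγN/PKI ternary complex (closed).
DEFAULT_STATES: tuple[str, ...] = ("apo", "ADP", "ATPgN", "ATPgN+PKI")

#: The nine structural/functional communities of the kinase core.
COMMUNITY_LABELS: tuple[str, ...] = (
    "ComA", "ComB", "ComC", "ComD", "ComE", "ComF", "ComF1", "ComG", "ComH",
)

REQUIRED_COLUMNS = ("residue_id", "state", "delta_H", "delta_N")
OPTIONAL_COLUMNS = ("residue_label", "lw_H", "lw_N")

# Sparky-style amide assignment, e.g. "G55N-H" or "A124N-HN"
_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z]{1,3})(\d+)N-H?N?$")


@dataclass(frozen=True)
class ShiftRecord:
    """One amide resonance of one residue in one ligation state."""

    residue_id: int
    state: str
    delta_H: float
    delta_N: float
    residue_label: str = ""
    lw_H: float | None = None
    lw_N: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.delta_H) and np.isfinite(self.delta_N)):
            raise IntegrityError(
                f"non-finite shift for residue {self.residue_id} ({self.state})"
            )
        for lw in (self.lw_H, self.lw_N):
            if lw is not None and not (np.isfinite(lw) and lw > 0):
                raise IntegrityError(
                    f"linewidth must be > 0 (residue {self.residue_id}, {self.state})"
                )


class ShiftTable:
    """Residues × states table of amide (δH, δN) shifts with optional Δν.

    Parameters
    ----------
    records
        DataFrame with columns ``residue_id, state, delta_H, delta_N``
        (plus optional ``residue_label, lw_H, lw_N``), or an iterable of
        :class:`ShiftRecord`.
    states
        Explicit state order.  Defaults to order of first appearance.
    protein_id
        Free-form identifier of the protein/construct.
    """

    def __init__(
        self,
        records: pd.DataFrame | Iterable[ShiftRecord],
        states: Sequence[str] | None = None,
        protein_id: str = "",
    ):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame([vars(r) for r in records])
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col == "residue_label" else np.nan
        df = df[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)]
        df["residue_id"] = df["residue_id"].astype(int)
        df["state"] = df["state"].astype(str)
        for col in ("delta_H", "delta_N", "lw_H", "lw_N"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        if not np.isfinite(df[["delta_H", "delta_N"]].to_numpy()).all():
            raise IntegrityError("chemical shifts must be finite")
        lw = df[["lw_H", "lw_N"]].to_numpy(dtype=float)
        if np.any(lw[np.isfinite(lw)] <= 0):
            raise IntegrityError("linewidths, when present, must be > 0")
        dup = df.duplicated(subset=["residue_id", "state"])
        if dup.any():
            bad = df.loc[dup, ["residue_id", "state"]].iloc[0]
            raise IntegrityError(
                f"duplicate (residue, state) pair: ({bad.residue_id}, {bad.state!r})"
            )

        seen = list(dict.fromkeys(df["state"]))
        if states is None:
            states = seen
        else:
            states = list(states)
            unknown = set(seen) - set(states)
            if unknown:
                raise IntegrityError(f"records contain states not in state order: {unknown}")
        self.records = df.sort_values(["residue_id", "state"], kind="stable").reset_index(drop=True)
        self.states: list[str] = list(states)
        self.protein_id = protein_id

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return (
            f"ShiftTable({self.records.residue_id.nunique()} residues, "
            f"{len(self.states)} states, {len(self)} records)"
        )

    @property
    def residues(self) -> list[int]:
        return sorted(self.records["residue_id"].unique().tolist())

    def has_linewidths(self) -> bool:
        return bool(np.isfinite(self.records[["lw_H", "lw_N"]].to_numpy()).all())

    def _check_states(self, states: Sequence[str]) -> list[str]:
        unknown = [s for s in states if s not in self.states]
        if unknown:
            raise LookupStateError(f"unknown state label(s): {unknown}")
        return list(states)

    def subset(self, states: Sequence[str]) -> "ShiftTable":
        states = self._check_states(states)
        df = self.records[self.records["state"].isin(states)]
        return ShiftTable(df, states=states, protein_id=self.protein_id)

    def trajectory(self, residue_id: int, states: Sequence[str] | None = None) -> np.ndarray:
        """(n_states, 2) array of (δH, δN) for one residue in state order."""
        states = self._check_states(states or self.states)
        sub = self.records[self.records["residue_id"] == residue_id].set_index("state")
        try:
            return sub.loc[states, ["delta_H", "delta_N"]].to_numpy(dtype=float)
        except KeyError as exc:
            raise LookupStateError(
                f"residue {residue_id} is not complete in states {states}"
            ) from exc

    def pivot(self, column: str, states: Sequence[str] | None = None) -> pd.DataFrame:
        """Residues × states matrix of one column, complete residues only."""
        states = self._check_states(states or self.states)
        wide = self.records.pivot(index="residue_id", columns="state", values=column)
        wide = wide.reindex(columns=states).dropna()
        return wide

    def write(self, path: str | Path) -> None:
        """Write as the canonical CSV dialect (round-trips all record values)."""
        out = self.records.copy()
        out.to_csv(path, index=False)


def complete_residues(table: ShiftTable, states: Sequence[str] | None = None) -> list[int]:
    """Residues having a record in every requested state, sorted ascending."""
    states = table._check_states(states or table.states)
    sub = table.records[table.records["state"].isin(states)]
    counts = sub.groupby("residue_id")["state"].nunique()
    return sorted(counts.index[counts == len(states)].tolist())


def read_shift_table(
    path: str | Path,
    format: str = "csv",
    state: str | None = None,
    states: Sequence[str] | None = None,
    protein_id: str = "",
) -> ShiftTable:
    """Read a shift table from CSV/TSV or a Sparky-style peak list.

    CSV/TSV files carry a header with at least
    ``residue_id,state,delta_H,delta_N``.  Sparky ``.list`` files hold one
    state per file (supply ``state``); lines look like ``G55N-H 119.42 8.31``
    with the ¹⁵N frequency first.  Unparseable Sparky lines are skipped and
    counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t")
        df.columns = [c.strip() for c in df.columns]
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        n_raw = len(df)
        for col in ("delta_H", "delta_N"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df = df.dropna(subset=["delta_H", "delta_N"])
        dropped = n_raw - len(df)
        if dropped:
            logger.warning("%s: dropped %d rows with unparseable shifts", path, dropped)
        return ShiftTable(df, states=states, protein_id=protein_id)
    if format == "sparky":
        if state is None:
            raise FormatError("Sparky peak lists hold one state per file; supply `state`")
        rows, skipped = [], 0
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            m = _SPARKY_ASSIGNMENT.match(parts[0]) if parts else None
            if m is None or len(parts) < 3:
                skipped += 1
                continue
            try:
                w1, w2 = float(parts[1]), float(parts[2])  # w1 = ¹⁵N, w2 = ¹H
            except ValueError:
                skipped += 1
                continue
            rows.append(
                dict(
                    residue_id=int(m.group(2)),
                    residue_label=f"{m.group(1)}{m.group(2)}",
                    state=state,
                    delta_H=w2,
                    delta_N=w1,
                )
            )
        if skipped:
            logger.warning("%s: skipped %d unparseable Sparky lines", path, skipped)
        if not rows:
            raise FormatError(f"{path}: no parseable Sparky assignments")
        return ShiftTable(pd.DataFrame(rows), states=states, protein_id=protein_id)
    raise FormatError(f"unknown format {format!r}; expected csv, tsv or sparky")


@dataclass
class CommunityMap:
    """Residue → functional-community assignment."""

    assignments: dict[int, str] = field(default_factory=dict)
    community_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.assignments = {int(k): str(v) for k, v in self.assignments.items()}

    @property
    def communities(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def members(self, community: str) -> list[int]:
        return sorted(r for r, c in self.assignments.items() if c == community)

    def size(self, community: str) -> int:
        return len(self.members(community))

    def __len__(self) -> int:
        return len(self.assignments)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.assignments.items()), columns=["residue_id", "community"]
        )
        df.to_csv(path, index=False)


def read_community_map(path: str | Path) -> CommunityMap:
    """Read a two-column ``residue_id,community`` CSV.

    A residue assigned to two different communities is an integrity error;
    an empty file yields an empty map with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if df.empty:
        logger.warning("%s: empty community map", path)
        return CommunityMap()
    if not {"residue_id", "community"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns residue_id,community")
    dup = df.groupby("residue_id")["community"].nunique()
    conflicted = dup.index[dup > 1].tolist()
    if conflicted:
        raise IntegrityError(f"{path}: residues assigned to >1 community: {conflicted}")
    assignments = dict(zip(df["residue_id"].astype(int), df["community"].astype(str)))
    return CommunityMap(assignments=assignments)


def map_from_series(assignments: Mapping[int, str]) -> CommunityMap:
    return CommunityMap(assignments=dict(assignments))
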