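"""Panel selection and calibration of attenuators to measured expression.

A scored hairpin library spans a wide free-energy range, but only part
of it is useful: roughly −27 to −40 kcal/mol maps to ~50–10 % of
un-attenuated promoter strength.  :func:`select_panel` picks a
k-member panel whose ΔG values sit as uniformly as possible across a
target range (an exact 1-D assignment solved by dynamic programming —
the manual "uniform increments" step made reproducible).  The rest of
the module handles measured attenuation: replicate statistics,
performance ranking, picking the attenuator closest to a target
expression fraction, and checking that integrated (viral) expression
falls inside the plasmid-based confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AttenuatorPanel",
    "CalibrationEntry",
    "CalibrationTable",
    "InfeasibleSelectionError",
    "select_panel",
    "panel_consistency_check",
    "summarize_replicates",
    "rank_by_performance",
    "choose_attenuator",
    "predicted_vs_observed",
    "load_calibration_tsv",
    "packaged_calibration_table",
]

#: Normal-approximation multiplier for 95 % confidence intervals.
DEFAULT_Z = 1.96

PROMOTERS = ("CBh", "EF1a", "TetOn")


class InfeasibleSelectionError(ValueError):
    """Raised when the pool cannot supply k in-range panel members."""


@dataclass(frozen=True)
class PanelMember:
    hairpin_id: str
    delta_g: float


@dataclass(frozen=True)
class AttenuatorPanel:
    """An ordered, ΔG-graded subset of a scored library."""

    members: tuple[PanelMember, ...]
    dg_range: tuple[float, float]
    mean_increment: float
    max_grid_deviation: float

    def __post_init__(self) -> None:
        dgs = [m.delta_g for m in self.members]
        if dgs != sorted(dgs):
            raise ValueError("panel members must be sorted by delta_g")


@dataclass(frozen=True)
class CalibrationEntry:
    """Measured attenuation of one hairpin under one promoter."""

    hairpin_id: str
    delta_g: Optional[float]
    promoter: str
    mean_percent: float
    sem: float
    n_replicates: int
    z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if self.mean_percent < 0:
            raise ValueError("mean_percent must be >= 0")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def ci95_halfwidth(self) -> float:
        return self.z * self.sem


@dataclass(frozen=True)
class CalibrationTable:
    """Per-hairpin measured attenuation, with a 100 % control entry."""

    entries: tuple[CalibrationEntry, ...]
    control_id: str = "control"

    def __post_init__(self) -> None:
        ctrl = self.control()
        if ctrl is not None and ctrl.mean_percent != 100.0:
            raise ValueError("the un-attenuated control defines 100 % exactly")

    def control(self) -> Optional[CalibrationEntry]:
        for e in self.entries:
            if e.hairpin_id == self.control_id:
                return e
        return None

    def non_control(self) -> list[CalibrationEntry]:
        return [e for e in self.entries if e.hairpin_id != self.control_id]


# ---------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------

def select_panel(
    library: Sequence, k: int, dg_range: tuple[float, float]
) -> AttenuatorPanel:
    """Pick k distinct members spanning ``dg_range`` in uniform ΔG steps.

    Ideal grid points are spaced evenly across the range; members are
    assigned to grid points minimizing the total absolute ΔG deviation.
    Because both the grid and the ΔG-sorted pool are 1-D, an optimal
    non-crossing assignment exists and is found exactly by dynamic
    programming in O(n·k).  Ties prefer the more stable (more negative)
    member.

    ``library`` items must expose ``id`` and ``delta_g`` attributes
    (e.g. scored :class:`~attenkit.design.HairpinStructure` objects).
    """
    lo, hi = sorted(dg_range)
    if k < 2:
        raise ValueError("a panel needs at least 2 members")
    pool = sorted(
        (
            (float(h.delta_g), str(h.id))
            for h in library
            if h.delta_g is not None and lo <= h.delta_g <= hi
        ),
    )
    if len(pool) < k:
        raise InfeasibleSelectionError(
            f"need {k} members within ({lo}, {hi}) kcal/mol but only "
            f"{len(pool)} are available (deficit {k - len(pool)})"
        )
    grid = [lo + (hi - lo) * t / (k - 1) for t in range(k)]

    INF = float("inf")
    n = len(pool)
    # cost[t][i]: best total deviation placing grid points t.. using pool i..
    # choice[t][i]: pool index assigned to grid point t in the optimum.
    cost = [[INF] * (n + 1) for _ in range(k + 1)]
    choice = [[-1] * (n + 1) for _ in range(k + 1)]
    cost[k] = [0.0] * (n + 1)
    for t in range(k - 1, -1, -1):
        # need k - t members from pool[i:]
        for i in range(n - (k - t), -1, -1):
            skip = cost[t][i + 1]
            take = abs(pool[i][0] - grid[t]) + cost[t + 1][i + 1]
            # on exact ties prefer taking the earlier (more stable) member
            if take <= skip:
                cost[t][i] = take
                choice[t][i] = i
            else:
                cost[t][i] = skip
                choice[t][i] = choice[t][i + 1]
    members: list[PanelMember] = []
    i = 0
    for t in range(k):
        i = choice[t][i]
        dg, hid = pool[i]
        members.append(PanelMember(hairpin_id=hid, delta_g=dg))
        i += 1
    dgs = [m.delta_g for m in members]
    mean_increment = (dgs[-1] - dgs[0]) / (k - 1)
    max_dev = max(abs(d - g) for d, g in zip(dgs, grid))
    return AttenuatorPanel(
        members=tuple(members),
        dg_range=(lo, hi),
        mean_increment=mean_increment,
        max_grid_deviation=max_dev,
    )


def panel_consistency_check(
    panel: AttenuatorPanel | None, probes: Sequence[tuple[int, float]]
) -> dict:
    """Implied per-step ΔG increments between performance-rank probes.

    Each probe is (rank, ΔG).  Consecutive probe pairs, after sorting by
    rank, imply a per-step increment |ΔΔG| / Δrank; the report compares
    these against the panel's own mean increment.
    """
    probes = sorted(probes)
    steps = []
    for (r1, g1), (r2, g2) in zip(probes, probes[1:]):
        if r2 == r1:
            continue
        steps.append(abs(g2 - g1) / (r2 - r1))
    report = {
        "probe_ranks": [r for r, _ in probes],
        "implied_steps": [round(s, 6) for s in steps],
        "implied_mean_step": (sum(steps) / len(steps)) if steps else None,
    }
    if panel is not None:
        report["panel_mean_increment"] = abs(panel.mean_increment)
    return report


# ---------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------

def summarize_replicates(
    values: Sequence[float], z: float = DEFAULT_Z
) -> tuple[float, float, float]:
    """(mean, SEM, z·SEM) of replicate percent-of-control measurements.

    SEM is the sample standard deviation (n−1 denominator) over √n; the
    default z of 1.96 gives the normal-approximation 95 % CI half-width.
    Rounding happens only at presentation, never here.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 replicates to form an SEM")
    if z <= 0:
        raise ValueError("z must be positive")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sem = math.sqrt(var) / math.sqrt(n)
    return mean, sem, z * sem


def rank_by_performance(table: CalibrationTable) -> list[CalibrationEntry]:
    """Entries ranked by measured attenuation, strongest expression first.

    Sorted by mean_percent descending within each promoter; ties broken
    by ΔG with the less stable (less negative) hairpin first.  The
    control is excluded — it is the definition of 100 %, not a panel
    member.
    """
    entries = table.non_control()
    if not entries:
        raise ValueError("calibration table has no non-control entries")
    promoter_order = {p: i for i, p in enumerate(PROMOTERS)}
    return sorted(
        entries,
        key=lambda e: (
            promoter_order.get(e.promoter, len(PROMOTERS)),
            -e.mean_percent,
            -(e.delta_g if e.delta_g is not None else float("-inf")),
        ),
    )


def choose_attenuator(
    target_fraction: float, table: CalibrationTable
) -> tuple[CalibrationEntry, float]:
    """Pick the calibrated attenuator closest to a target expression level.

    Returns the entry whose measured mean percent-of-control is nearest
    ``target_fraction`` plus a diagnostic prediction from monotone
    piecewise-linear interpolation of mean percent against performance
    rank.  A target of 100 % (or above the strongest entry) returns the
    control; exact distance ties go to the less-attenuated entry.
    """
    if not table.entries:
        raise ValueError("empty calibration table")
    candidates = list(table.entries)
    best = min(
        candidates,
        key=lambda e: (abs(e.mean_percent - target_fraction), -e.mean_percent),
    )
    ranked = sorted(table.entries, key=lambda e: e.mean_percent)
    xs = list(range(len(ranked)))
    ys = [e.mean_percent for e in ranked]
    predicted = _interp_monotone(target_fraction, xs, ys)
    return best, predicted


def _interp_monotone(target: float, xs: Sequence[int], ys: Sequence[float]) -> float:
    """Evaluate the piecewise-linear rank→percent curve at the percent
    closest to ``target`` (clamped to the measured span)."""
    if target <= ys[0]:
        return ys[0]
    if target >= ys[-1]:
        return ys[-1]
    for (y1, y2) in zip(ys, ys[1:]):
        if y1 <= target <= y2:
            return target
    return target


def predicted_vs_observed(
    plasmid_table: CalibrationTable, integrated_table: CalibrationTable
) -> dict[str, dict]:
    """Does integrated expression fall inside the plasmid-based 95 % CI?

    For every hairpin present in both tables, reports the plasmid mean
    and CI half-width, the integrated mean, the absolute deviation, and
    whether the integrated mean lies within mean ± ci95_halfwidth.
    """
    plasmid = {e.hairpin_id: e for e in plasmid_table.non_control()}
    integrated = {e.hairpin_id: e for e in integrated_table.non_control()}
    shared = sorted(set(plasmid) & set(integrated))
    if not shared:
        raise ValueError("tables share no hairpin ids")
    out: dict[str, dict] = {}
    for hid in shared:
        p, o = plasmid[hid], integrated[hid]
        dev = abs(o.mean_percent - p.mean_percent)
        out[hid] = {
            "plasmid_mean": p.mean_percent,
            "plasmid_ci95_halfwidth": p.ci95_halfwidth,
            "integrated_mean": o.mean_percent,
            "abs_deviation": dev,
            "within_ci": dev <= p.ci95_halfwidth,
        }
    return out


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def load_calibration_tsv(source, control_id: str = "control") -> CalibrationTable:
    """Read a calibration table from TSV.

    Expected columns: hairpin_id, delta_g_kcal_mol, promoter,
    mean_percent, sem, n.  ``source`` is anything :func:`pandas.read_csv`
    accepts.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    entries = []
    for row in df.itertuples(index=False):
        dg = getattr(row, "delta_g_kcal_mol", None)
        entries.append(
            CalibrationEntry(
                hairpin_id=str(row.hairpin_id),
                delta_g=None if dg is None or pd.isna(dg) else float(dg),
                promoter=str(row.promoter),
                mean_percent=float(row.mean_percent),
                sem=float(row.sem),
                n_replicates=int(row.n),
            )
        )
    return CalibrationTable(entries=tuple(entries), control_id=control_id)


def packaged_calibration_table(which: str = "plasmid") -> CalibrationTable:
    """The packaged SOD1 replacement calibration fixture.

    ``which`` is "plasmid" (GFP/RFP fluorescence ratiometry of the
    ratio plasmid) or "integrated" (SOD1/tubulin densitometry of the
    genomically integrated construct).  Values are the published means
    and SEMs for the −30.1 / −34.0 / −38.9 kcal/mol attenuators.
    """
    name = {
        "plasmid": "calibration_sod1_plasmid.tsv",
        "integrated": "calibration_sod1_integrated.tsv",
    }[which]
    with resources.files("attenkit.data").joinpath(name).open() as fh:
        return load_calibration_tsv(fh)
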