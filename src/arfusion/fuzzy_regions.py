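"""Fuzzified confidence-region grids over the learning graphs.

Each learning graph (significance/position, occurrence/density, f1/f2) is
covered by a grid of confidence regions.  Both axes carry a trapezoidal fuzzy
partition forming a partition of unity, so a feature point belongs gradually
to neighbouring regions and the mass assigned to it varies continuously —
there is no jump when a point crosses a region boundary.

Each region learns a *proposition* from the membership-weighted fraction of
true binding sites among its training points, on a gradual-doubt ladder:

=============  ======================================  ==================
proposition    meaning                                 (m(H1), m(H2), m(theta))
=============  ======================================  ==================
P1(H1,H2)      total ignorance                         (0,    0,    1)
P2(Hi,Hj)      low preference for Hi, high doubt       (0.33, 0,    0.67)
P3(Hi,Hj)      strong preference for Hi, low doubt     (0.67, 0,    0.33)
P4(Hi)         total confidence in Hi                  (1,    0,    0)
=============  ======================================  ==================

(H2-preferring rows put the 0.33/0.67/1 on m(H2) instead.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ds_engine import MassFunction

__all__ = [
    "Trapezoid",
    "FuzzyPartition",
    "Proposition",
    "proposition_mass",
    "RegionThresholds",
    "RegionGrid",
    "GridTemplate",
    "membership",
    "fit_regions",
    "fuzzy_mass",
    "quantile_partition",
    "default_grids",
]

_INF = float("inf")


@dataclass(frozen=True)
class Trapezoid:
    """One trapezoidal fuzzy set with breakpoints a <= b <= c <= d.

    Membership is 0 left of ``a``, rises linearly on [a, b], is 1 on [b, c],
    falls linearly on [c, d].  Infinite ``a``/``b`` (``c``/``d``) give a
    left (right) shoulder set.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"unordered trapezoid breakpoints {(self.a, self.b, self.c, self.d)}")

    def membership(self, v: float) -> float:
        v = float(v)
        if self.b <= v <= self.c:
            return 1.0
        if v <= self.a or v >= self.d:
            return 0.0
        if v < self.b:
            return (v - self.a) / (self.b - self.a)
        return (self.d - v) / (self.d - self.c)


def membership(trapezoid: Trapezoid, v: float) -> float:
    """Piecewise-linear trapezoid evaluation (module-level convenience)."""
    return trapezoid.membership(v)


@dataclass(frozen=True)
class FuzzyPartition:
    """An ordered family of trapezoids forming a partition of unity.

    Adjacent sets share their ramp interval (``c_i = a_{i+1}``,
    ``d_i = b_{i+1}``); the first set is a left shoulder and the last a right
    shoulder, so every real value has memberships summing to exactly 1.
    """

    sets: tuple[Trapezoid, ...]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("partition needs at least one set")
        first, last = self.sets[0], self.sets[-1]
        if not (math.isinf(first.a) and math.isinf(first.b)):
            raise ValueError("first set must be a left shoulder")
        if not (math.isinf(last.c) and math.isinf(last.d)):
            raise ValueError("last set must be a right shoulder")
        for left, right in zip(self.sets, self.sets[1:]):
            if left.c != right.a or left.d != right.b:
                raise ValueError("adjacent sets must share their ramp interval")
            if left.c >= left.d:
                raise ValueError("ramp interval must have positive width")

    def __len__(self) -> int:
        return len(self.sets)

    def memberships(self, v: float) -> np.ndarray:
        return np.array([t.membership(v) for t in self.sets])

    @classmethod
    def from_ramps(cls, ramps: Sequence[tuple[float, float]]) -> "FuzzyPartition":
        """Build an n-set partition from the n-1 ordered ramp intervals."""
        n = len(ramps) + 1
        sets = []
        for i in range(n):
            a, b = (-_INF, -_INF) if i == 0 else ramps[i - 1]
            c, d = (_INF, _INF) if i == n - 1 else ramps[i]
            sets.append(Trapezoid(a, b, c, d))
        return cls(tuple(sets))

    def to_dict(self) -> dict:
        return {"ramps": [[t.c, t.d] for t in self.sets[:-1]]}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyPartition":
        return cls.from_ramps([tuple(r) for r in d["ramps"]])


def quantile_partition(values, n_sets: int, ramp_fraction: float = 0.2) -> FuzzyPartition:
    """Data-adaptive partition: boundaries at the k/n training quantiles.

    Each interior boundary becomes a ramp of width ``ramp_fraction`` times the
    smaller adjacent inter-quantile gap, centred on the boundary; tied or
    collapsed quantiles are nudged apart by a scale-relative epsilon so the
    region count is preserved.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to build a partition from")
    if n_sets == 1:
        return FuzzyPartition.from_ramps([])
    qs = np.quantile(values, np.linspace(0, 1, n_sets + 1))
    scale = max(float(qs[-1] - qs[0]), 1.0)
    eps = 1e-9 * scale
    # enforce strictly increasing quantile anchors
    for i in range(1, len(qs)):
        if qs[i] <= qs[i - 1]:
            qs[i] = qs[i - 1] + eps
    ramps = []
    prev_hi = -_INF
    for k in range(1, n_sets):
        gap = min(qs[k] - qs[k - 1], qs[k + 1] - qs[k])
        half = max(0.5 * ramp_fraction * gap, eps)
        lo, hi = qs[k] - half, qs[k] + half
        if lo <= prev_hi:  # keep ramps disjoint
            lo = prev_hi + eps
            hi = max(hi, lo + eps)
        ramps.append((lo, hi))
        prev_hi = hi
    return FuzzyPartition.from_ramps(ramps)


# ---------------------------------------------------------------------------
# Propositions (the gradual-doubt ladder)

_LEVELS = {"P1", "P2", "P3", "P4"}
# (mass on the preferred hypothesis, mass on the ignorance set), stored
# exactly as printed so 0.33 + 0.67 round-trips without drift
_LADDER = {"P1": (0.0, 1.0), "P2": (0.33, 0.67), "P3": (0.67, 0.33), "P4": (1.0, 0.0)}


@dataclass(frozen=True)
class Proposition:
    """One rung of the gradual-doubt ladder: a level and a preferred hypothesis."""

    level: str
    preferred: str | None = None  # "H1", "H2", or None for P1

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"unknown proposition level {self.level!r}")
        if self.level == "P1":
            if self.preferred is not None:
                raise ValueError("P1 (total ignorance) has no preferred hypothesis")
        elif self.preferred not in {"H1", "H2"}:
            raise ValueError(f"{self.level} requires preferred hypothesis H1 or H2")

    def __str__(self) -> str:
        if self.level == "P1":
            return "P1(H1,H2)"
        if self.level == "P4":
            return f"P4({self.preferred})"
        other = "H2" if self.preferred == "H1" else "H1"
        return f"{self.level}({self.preferred},{other})"


def proposition_mass(p: Proposition) -> MassFunction:
    """The basic probability assignment of a proposition (preference levels
    P1..P4 carry gradual masses 0, 0.33, 0.67, 1 on the preferred hypothesis,
    the remainder on the ignorance set)."""
    m, theta = _LADDER[p.level]
    if p.level == "P1":
        return MassFunction(0.0, 0.0, 1.0)
    if p.preferred == "H1":
        return MassFunction(m, 0.0, theta)
    return MassFunction(0.0, m, theta)


@dataclass(frozen=True)
class RegionThresholds:
    """Bands mapping a region's positive fraction p to a proposition.

    Defaults: p >= p4 -> P4(H1); [p3, p4) -> P3; [p2, p3) -> P2; the open
    band (1-p2, p2)... around 0.5 -> P1; mirrored bands prefer H2.  Regions
    whose effective support falls below ``min_support`` are forced to P1.
    """

    p4: float = 0.90
    p3: float = 0.70
    p2: float = 0.55
    min_support: float = 5.0

    def __post_init__(self) -> None:
        if not (0.5 < self.p2 < self.p3 < self.p4 <= 1.0):
            raise ValueError("require 0.5 < p2 < p3 < p4 <= 1")

    def proposition(self, positive_fraction: float, support: float) -> Proposition:
        if support < self.min_support:
            return Proposition("P1")
        p = positive_fraction
        # fold onto the preferred-hypothesis scale so the bands are exactly
        # mirror-symmetric under an H1/H2 label flip
        preferred = "H1" if p >= 0.5 else "H2"
        q = p if p >= 0.5 else 1.0 - p
        if q >= self.p4:
            return Proposition("P4", preferred)
        if q >= self.p3:
            return Proposition("P3", preferred)
        if q >= self.p2:
            return Proposition("P2", preferred)
        return Proposition("P1")


@dataclass
class RegionGrid:
    """A fuzzified learning graph: two partitions plus per-region evidence."""

    partition_x: FuzzyPartition
    partition_y: FuzzyPartition
    propositions: list[list[Proposition]]
    masses: np.ndarray  # shape (nx, ny, 3): m(H1), m(H2), m(theta) per region
    positive_fraction: np.ndarray  # shape (nx, ny)
    support: np.ndarray  # shape (nx, ny), membership-weighted point count
    name: str = ""

    @property
    def region_count(self) -> int:
        return len(self.partition_x) * len(self.partition_y)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "partition_x": self.partition_x.to_dict(),
            "partition_y": self.partition_y.to_dict(),
            "propositions": [[str(p) for p in row] for row in self.propositions],
            "masses": self.masses.tolist(),
            "positive_fraction": self.positive_fraction.tolist(),
            "support": self.support.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionGrid":
        props = [[_parse_proposition(s) for s in row] for row in d["propositions"]]
        return cls(
            partition_x=FuzzyPartition.from_dict(d["partition_x"]),
            partition_y=FuzzyPartition.from_dict(d["partition_y"]),
            propositions=props,
            masses=np.asarray(d["masses"], dtype=float),
            positive_fraction=np.asarray(d["positive_fraction"], dtype=float),
            support=np.asarray(d["support"], dtype=float),
            name=d.get("name", ""),
        )


def _parse_proposition(s: str) -> Proposition:
    level = s[: s.index("(")]
    inner = s[s.index("(") + 1 : s.index(")")].split(",")
    if level == "P1":
        return Proposition("P1")
    return Proposition(level, inner[0])


def fit_regions(
    points: Iterable[tuple[float, float, int]],
    partition_x: FuzzyPartition,
    partition_y: FuzzyPartition,
    thresholds: RegionThresholds = RegionThresholds(),
    name: str = "",
) -> RegionGrid:
    """Learn each region's proposition from labelled training points.

    A point contributes to region (i, j) with weight ``mu_x(i) * mu_y(j)``;
    the region's positive fraction is the weighted share of label-1 points and
    its support the total weight.  Thresholds then map the fraction to a rung
    of the gradual-doubt ladder, low-support regions defaulting to ignorance.
    """
    pts = list(points)
    if not pts:
        raise ValueError("empty training set")
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    labels = np.array([p[2] for p in pts], dtype=float)
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    Mx = np.column_stack([[t.membership(v) for v in xs] for t in partition_x.sets])
    My = np.column_stack([[t.membership(v) for v in ys] for t in partition_y.sets])
    nx, ny = len(partition_x), len(partition_y)
    support = np.einsum("pi,pj->ij", Mx, My)
    pos = np.einsum("pi,pj,p->ij", Mx, My, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(support > 0, pos / np.maximum(support, 1e-300), 0.5)
    propositions: list[list[Proposition]] = []
    masses = np.zeros((nx, ny, 3))
    for i in range(nx):
        row = []
        for j in range(ny):
            prop = thresholds.proposition(float(frac[i, j]), float(support[i, j]))
            row.append(prop)
            mf = proposition_mass(prop)
            masses[i, j] = (mf.h1, mf.h2, mf.theta)
        propositions.append(row)
    return RegionGrid(
        partition_x=partition_x,
        partition_y=partition_y,
        propositions=propositions,
        masses=masses,
        positive_fraction=frac,
        support=support,
        name=name,
    )


def fuzzy_mass(x: float, y: float, grid: RegionGrid) -> MassFunction:
    """Membership-weighted mass at a feature point:
    ``m(S) = sum_ij mu_x(i)(x) * mu_y(j)(y) * m_Rij(S)`` — a convex
    combination of region BPAs, hence itself a valid BPA, continuous in (x, y).
    """
    mx = grid.partition_x.memberships(x)
    my = grid.partition_y.memberships(y)
    if mx.sum() <= 0 or my.sum() <= 0:
        raise ValueError(f"point ({x}, {y}) has no membership in the grid domain")
    w = np.einsum("i,j->ij", mx, my)
    m = np.einsum("ij,ijk->k", w, grid.masses)
    return MassFunction(float(m[0]), float(m[1]), float(m[2]))


# ---------------------------------------------------------------------------
# Default grid geometry


@dataclass(frozen=True)
class GridTemplate:
    """Shape of one learning-graph grid: axis names and fuzzy-set counts."""

    name: str
    axis_x: str
    axis_y: str
    n_x: int
    n_y: int

    @property
    def region_count(self) -> int:
        return self.n_x * self.n_y

    def build(self, x_values, y_values) -> tuple[FuzzyPartition, FuzzyPartition]:
        """Materialize the two partitions from training values (quantile-based)."""
        return (
            quantile_partition(x_values, self.n_x),
            quantile_partition(y_values, self.n_y),
        )


def default_grids() -> dict[str, GridTemplate]:
    """The three learning-graph templates: significance/position (3x3 = 9
    regions), occurrence/density (3x4 = 12 regions), f1/f2 (3x3 = 9 regions)."""
    return {
        "sc_p": GridTemplate("sc_p", "sc", "position", 3, 3),
        "o_d": GridTemplate("o_d", "occurrence", "density", 3, 4),
        "f1_f2": GridTemplate("f1_f2", "f1", "f2", 3, 3),
    }
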