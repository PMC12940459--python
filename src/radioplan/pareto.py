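"""Bi-objective Pareto analysis in the (P_I, 1 - P_B) plane.

A plan is better when its injury probability P_I is lower and its benefit
probability P_B is higher, so the analysis minimises both coordinates of
(P_I, 1 - P_B).  This module extracts the non-dominated front from an
archive of evaluated plans, computes the utopia (illusion) point of
coordinatewise minima, interpolates the front piecewise-linearly to locate
the theoretical P_+ optimum, and selects the archive member with the
highest P_+ = P_B * (1 - P_I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ParetoPoint",
    "ParetoFront",
    "non_dominated",
    "utopia_point",
    "interpolated_global_optimum",
    "select_highest_pplus",
    "front_table",
]

#: Float tie tolerance on dominance comparisons.
_EPS = 1e-12


@dataclass(frozen=True)
class ParetoPoint:
    """One plan's image in objective space, with a reference to the plan."""

    p_injury: float
    one_minus_p_benefit: float
    plan: object | None = None

    def __post_init__(self) -> None:
        for v in (self.p_injury, self.one_minus_p_benefit):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"objective coordinate out of [0,1]: {v}")

    @property
    def p_benefit(self) -> float:
        return 1.0 - self.one_minus_p_benefit

    @property
    def p_plus(self) -> float:
        return self.p_benefit * (1.0 - self.p_injury)


@dataclass(frozen=True)
class ParetoFront:
    """Ordered non-dominated set with its derived summary points.

    Points are sorted by increasing P_I (hence strictly decreasing
    1 - P_B); ``utopia`` is the coordinatewise minimum over the archive,
    ``interpolated_optimum`` the P_+-maximal point on the piecewise-linear
    interpolant of the front, and ``highest`` the archive member with
    maximal P_+.
    """

    points: Tuple[ParetoPoint, ...]
    utopia: Tuple[float, float]
    interpolated_optimum: Tuple[float, float, float]  # (P_I, 1-P_B, P_+)
    highest: ParetoPoint


def _coords(points: Sequence[ParetoPoint]) -> np.ndarray:
    return np.array([[p.p_injury, p.one_minus_p_benefit] for p in points])


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """a dominates b: no worse in both coordinates, strictly better in one."""
    return bool(
        (a[0] <= b[0] + _EPS)
        and (a[1] <= b[1] + _EPS)
        and ((a[0] < b[0] - _EPS) or (a[1] < b[1] - _EPS))
    )


def non_dominated(
    points: Sequence[ParetoPoint], literal_predicate: bool = False
) -> List[ParetoPoint]:
    """Extract the non-dominated subset, sorted by increasing P_I.

    Exact coordinate duplicates are kept once (first occurrence).  With
    ``literal_predicate=True`` the stricter published predicate is applied
    instead — a point must itself dominate (or tie) every other point —
    which generally selects at most one plan; it is provided for
    comparison only.
    """
    if not points:
        raise ValueError("empty plan set")
    xy = _coords(points)

    if literal_predicate:
        keep = []
        for i in range(len(points)):
            others = [j for j in range(len(points)) if j != i]
            if all(
                xy[i, 0] <= xy[j, 0] + _EPS
                and xy[i, 1] <= xy[j, 1] + _EPS
                and (xy[i, 0] < xy[j, 0] - _EPS or xy[i, 1] < xy[j, 1] - _EPS)
                for j in others
            ):
                keep.append(i)
        return [points[i] for i in keep]

    # sweep: sort by P_I asc then (1-P_B) asc; keep strictly improving 1-P_B
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    front_idx: List[int] = []
    seen = set()
    best_y = np.inf
    for i in order:
        x, y = xy[i]
        key = (round(x / _EPS), round(y / _EPS))
        if key in seen:
            continue
        if y < best_y - _EPS:
            # not dominated by any point with smaller-or-equal P_I
            front_idx.append(i)
            seen.add(key)
            best_y = y
        elif abs(y - best_y) <= _EPS and front_idx:
            # equal 1-P_B at larger P_I -> dominated unless exact duplicate
            continue
    return [points[i] for i in front_idx]


def utopia_point(points: Sequence[ParetoPoint]) -> Tuple[float, float]:
    """Illusion point: coordinatewise minima over the archive."""
    if not points:
        raise ValueError("empty plan set")
    xy = _coords(points)
    return float(xy[:, 0].min()), float(xy[:, 1].min())


def interpolated_global_optimum(
    front_points: Sequence[ParetoPoint],
) -> Tuple[float, float, float]:
    """The P_+-maximal point on the piecewise-linear front interpolant.

    P_+ as a function of the objective coordinates is (1 - y) * (1 - x);
    along each front segment it is a concave quadratic in the segment
    parameter, so the per-segment maximum has a closed form.  Returns
    (P_I, 1 - P_B, P_+).
    """
    if not front_points:
        raise ValueError("empty front")
    pts = sorted(front_points, key=lambda p: p.p_injury)
    best = None
    for p in pts:
        cand = (p.p_injury, p.one_minus_p_benefit, p.p_plus)
        if best is None or cand[2] > best[2]:
            best = cand
    for p0, p1 in zip(pts[:-1], pts[1:]):
        dx = p1.p_injury - p0.p_injury
        dy = p1.one_minus_p_benefit - p0.one_minus_p_benefit
        a0 = 1.0 - p0.p_injury
        b0 = 1.0 - p0.one_minus_p_benefit
        # f(t) = (a0 - t dx)(b0 - t dy); interior max where f'(t) = 0
        if dx * dy < 0:  # concave along a properly decreasing segment
            t = (dx * b0 + dy * a0) / (2.0 * dx * dy)
            if 0.0 < t < 1.0:
                x = p0.p_injury + t * dx
                y = p0.one_minus_p_benefit + t * dy
                f = (1.0 - x) * (1.0 - y)
                if f > best[2]:
                    best = (x, y, f)
    return best


def select_highest_pplus(points: Sequence[ParetoPoint]) -> ParetoPoint:
    """The archive member with maximal P_+ (ties broken by lowest P_I).

    Because P_+ improves when either objective improves, this member
    always lies on the non-dominated front.
    """
    if not points:
        raise ValueError("empty plan set")
    return max(points, key=lambda p: (p.p_plus, -p.p_injury))


def build_front(points: Sequence[ParetoPoint]) -> ParetoFront:
    """Full Pareto analysis of an archive of feasible plans."""
    front_pts = non_dominated(points)
    return ParetoFront(
        points=tuple(front_pts),
        utopia=utopia_point(points),
        interpolated_optimum=interpolated_global_optimum(front_pts),
        highest=select_highest_pplus(points),
    )


def front_table(front: ParetoFront) -> pd.DataFrame:
    """Delimited-text-friendly front export: one row per front point with
    P_I, 1-P_B, P_+ and the highest-P_+ marker."""
    rows = []
    for p in front.points:
        rows.append(
            {
                "p_injury": p.p_injury,
                "one_minus_p_benefit": p.one_minus_p_benefit,
                "p_plus": p.p_plus,
                "is_highest": p is front.highest
                or (
                    abs(p.p_injury - front.highest.p_injury) <= _EPS
                    and abs(
                        p.one_minus_p_benefit - front.highest.one_minus_p_benefit
                    )
                    <= _EPS
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_front(front: ParetoFront, ax=None):
    """Plot the front, utopia point and highest-P_+ marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = _coords(front.points)
    ax.plot(xy[:, 0], xy[:, 1], "o-", label="Pareto front")
    ax.plot(*front.utopia, "k*", markersize=12, label="utopia point")
    ax.plot(
        front.highest.p_injury,
        front.highest.one_minus_p_benefit,
        "s",
        color="crimson",
        label=f"highest P+ = {front.highest.p_plus:.4f}",
    )
    ax.set_xlabel("$P_I$")
    ax.set_ylabel("$1 - P_B$")
    ax.legend()
    return ax
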