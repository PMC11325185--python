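"""Manual-vs-automatic centroid agreement: matching taxonomy and rates.

Each manual point binds to its nearest automatic point within the match
radius (greedy ascending-distance matching; automatic points may collect
more than one manual point, which records a merge). Unbound manual points
are false negatives; automatic points with no bound manual point are false
positives. Rates are expressed as percentages of the manual count, rounded
half-up the way the source counts were reported; truncation is available as
an alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from quadmosaic.image_io import CentroidSet

__all__ = [
    "MatchResult",
    "match_centroids",
    "summarize_match",
    "default_match_radius",
]


@dataclass
class MatchResult:
    """Counts from comparing automatic centroids against manual annotation.

    Invariants: ``true_positives + false_negatives == n_manual`` (a merged
    automatic point contributes one true positive per bound manual point);
    ``fn_rate``/``fp_rate`` are unrounded percentages of ``n_manual``.
    """

    n_manual: int
    n_auto: int
    true_positives: int
    false_negatives: int
    false_positives: int
    merged: int
    match_radius: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("n_manual", "n_auto", "true_positives", "false_negatives",
                     "false_positives", "merged"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.true_positives + self.false_negatives != self.n_manual:
            raise ValueError(
                "true_positives + false_negatives must equal n_manual "
                f"({self.true_positives} + {self.false_negatives} != {self.n_manual})"
            )

    @classmethod
    def from_counts(
        cls,
        n_manual: int,
        false_negatives: int = 0,
        false_positives: int = 0,
        merged: int = 0,
        n_auto: Optional[int] = None,
        match_radius: Optional[float] = None,
    ) -> "MatchResult":
        """Build a result directly from reported counts."""
        tp = n_manual - false_negatives
        if n_auto is None:
            # each merge binds one extra manual point to an existing auto point
            n_auto = tp - merged + false_positives
        return cls(
            n_manual=n_manual,
            n_auto=n_auto,
            true_positives=tp,
            false_negatives=false_negatives,
            false_positives=false_positives,
            merged=merged,
            match_radius=match_radius,
        )

    @property
    def fn_rate(self) -> float:
        """False negatives as an (unrounded) percentage of the manual count."""
        return 100.0 * self.false_negatives / self.n_manual if self.n_manual else 0.0

    @property
    def fp_rate(self) -> float:
        """False positives as an (unrounded) percentage of the manual count."""
        return 100.0 * self.false_positives / self.n_manual if self.n_manual else 0.0


def default_match_radius(manual: CentroidSet) -> float:
    """Half the median nearest-neighbour distance of the manual set.

    A spacing-relative radius adapts across cone/rod densities.
    """
    if len(manual) < 2:
        raise ValueError("need at least two manual points for an automatic radius")
    tree = cKDTree(manual.points)
    dists, _ = tree.query(manual.points, k=2)
    return 0.5 * float(np.median(dists[:, 1]))


def match_centroids(auto: CentroidSet, manual: CentroidSet, radius: float) -> MatchResult:
    """Match automatic to manual centroids within ``radius`` pixels.

    All candidate pairs with distance <= radius are visited in ascending
    order of distance; a pair is accepted when its manual point is still
    unbound, so each manual point binds to its nearest acceptable automatic
    point. Automatic points bound by two or more manual points are counted
    once in ``merged``.
    """
    if radius <= 0:
        raise ValueError(f"match radius must be positive, got {radius}")
    n_manual, n_auto = len(manual), len(auto)
    bound_to = np.full(n_manual, -1, dtype=int)
    if n_manual and n_auto:
        tree = cKDTree(auto.points)
        pairs = []  # (distance, manual index, auto index)
        for mi, neighbours in enumerate(tree.query_ball_point(manual.points, radius)):
            for ai in neighbours:
                d = float(np.hypot(*(manual.points[mi] - auto.points[ai])))
                pairs.append((d, mi, ai))
        pairs.sort()
        for _, mi, ai in pairs:
            if bound_to[mi] < 0:
                bound_to[mi] = ai
    per_auto = np.bincount(bound_to[bound_to >= 0], minlength=n_auto)
    tp = int((bound_to >= 0).sum())
    return MatchResult(
        n_manual=n_manual,
        n_auto=n_auto,
        true_positives=tp,
        false_negatives=n_manual - tp,
        false_positives=int((per_auto == 0).sum()),
        merged=int((per_auto >= 2).sum()),
        match_radius=float(radius),
    )


def _round_rate(numerator: int, denominator: int, decimals: int, mode: str) -> float:
    """Exact-rational percentage rounding (avoids binary-float artefacts)."""
    rate = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "half-up" else ROUND_DOWN
    return float(rate.quantize(quantum, rounding=rounding))


def _format_rate(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}%" if decimals else f"{int(value)}%"


def summarize_match(m: MatchResult, decimals: int = 1, include_truncated: bool = False) -> dict:
    """JSON-serialisable agreement report with percentages rounded half-up.

    ``decimals`` is 0 or 1, matching the mixed precision of typical reports.
    ``include_truncated`` adds the round-toward-zero variants, an alternative
    convention some reported rates follow.
    """
    if m.n_manual == 0:
        raise ValueError("cannot summarise a match with zero manual points")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    fn = _round_rate(m.false_negatives, m.n_manual, decimals, "half-up")
    fp = _round_rate(m.false_positives, m.n_manual, decimals, "half-up")
    report = {
        "n_manual": m.n_manual,
        "n_auto": m.n_auto,
        "true_positives": m.true_positives,
        "false_negatives": m.false_negatives,
        "false_positives": m.false_positives,
        "merged": m.merged,
        "match_radius": m.match_radius,
        "fn_rate": fn,
        "fp_rate": fp,
        "fn_rate_str": _format_rate(fn, decimals),
        "fp_rate_str": _format_rate(fp, decimals),
    }
    if include_truncated:
        report["fn_rate_truncated"] = _round_rate(m.false_negatives, m.n_manual, decimals, "down")
        report["fp_rate_truncated"] = _round_rate(m.false_positives, m.n_manual, decimals, "down")
    return report
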