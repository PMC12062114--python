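"""Target-site accessibility scoring against an empirical rRNA class map.

Accessibility of an rRNA region for FISH probes is commonly summarized by
empirical brightness classes I-VI (I brightest) measured on a reference 18S
molecule.  The map is user-supplied data (a TSV of intervals); this module
only performs the overlap bookkeeping.  The worst (numerically highest)
class over a probe's site governs, with the mean class rank kept for
finer-grained ranking.  Positions outside every interval score "unknown".
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError, ValidationError
from .probe_design import Probe
from .seq_io import CoordinateMap

__all__ = ["AccessibilityMap", "AccessibilityScore", "CLASS_RANK",
           "load_accessibility_map", "site_accessibility"]

CLASS_RANK = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
RANK_CLASS = {v: k for k, v in CLASS_RANK.items()}

#: rank assigned to probes with no known accessibility, sorts after class VI
UNKNOWN_RANK = len(CLASS_RANK) + 1


@dataclass(frozen=True)
class AccessibilityMap:
    """Non-overlapping 1-based closed intervals labeled with classes I-VI."""

    reference_name: str
    intervals: tuple[tuple[int, int, str], ...]  # sorted by start

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, cls in self.intervals:
            if cls not in CLASS_RANK:
                raise ValidationError(f"unknown accessibility class {cls!r}")
            if start > end:
                raise ValidationError(f"inverted interval ({start}, {end})")
            if start <= prev_end:
                raise ValidationError(
                    f"overlapping accessibility intervals at position {start}"
                )
            prev_end = end

    def class_at(self, position: int) -> str | None:
        starts = [iv[0] for iv in self.intervals]
        i = bisect_right(starts, position) - 1
        if i >= 0 and self.intervals[i][0] <= position <= self.intervals[i][1]:
            return self.intervals[i][2]
        return None


@dataclass(frozen=True)
class AccessibilityScore:
    probe_name: str
    classes_covered: tuple[tuple[str, int], ...]  # (class, n positions), by rank
    worst_class: str | None  # None when the whole site is unmapped
    mean_class_rank: float | None
    n_unknown_positions: int = 0

    @property
    def worst_rank(self) -> int:
        return CLASS_RANK[self.worst_class] if self.worst_class else UNKNOWN_RANK


def load_accessibility_map(
    path: str | Path, reference_name: str = "reference"
) -> AccessibilityMap:
    """Load an interval map TSV with header ``start  end  class``."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return AccessibilityMap(reference_name=reference_name, intervals=())
    if table.empty:
        return AccessibilityMap(reference_name=reference_name, intervals=())
    missing = [c for c in ("start", "end", "class") if c not in table.columns]
    if missing:
        raise InputError(f"accessibility map missing columns: {missing}")
    intervals = sorted(
        (int(r["start"]), int(r["end"]), str(r["class"]).strip())
        for _, r in table.iterrows()
    )
    return AccessibilityMap(reference_name=reference_name, intervals=tuple(intervals))


def site_accessibility(
    probe: Probe,
    amap: AccessibilityMap,
    offset_map: CoordinateMap | None = None,
) -> AccessibilityScore:
    """Accessibility classes overlapped by a probe's target site.

    ``offset_map`` translates probe-reference positions onto the map's own
    reference (e.g. from a pairwise alignment of the two 18S molecules);
    identity is assumed when omitted.  Positions that do not translate, or
    fall outside every interval, count as unknown.
    """
    classes: Counter[str] = Counter()
    n_unknown = 0
    for pos in range(probe.target_start, probe.target_end + 1):
        if offset_map is not None:
            try:
                pos = offset_map.ref_to_col(pos)
            except Exception:
                n_unknown += 1
                continue
        cls = amap.class_at(pos)
        if cls is None:
            n_unknown += 1
        else:
            classes[cls] += 1
    if classes:
        worst = RANK_CLASS[max(CLASS_RANK[c] for c in classes)]
        known = sum(classes.values())
        mean_rank = sum(CLASS_RANK[c] * n for c, n in classes.items()) / known
    else:
        worst, mean_rank = None, None
    ordered = tuple(sorted(classes.items(), key=lambda kv: CLASS_RANK[kv[0]]))
    return AccessibilityScore(
        probe_name=probe.name,
        classes_covered=ordered,
        worst_class=worst,
        mean_class_rank=mean_rank,
        n_unknown_positions=n_unknown,
    )
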