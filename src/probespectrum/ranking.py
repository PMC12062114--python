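"""Ranked probe reports combining specificity, accessibility and Tm.

Probe selection mimics manual curation: prefer the largest off-target
mismatch floor (hardest to cross-hybridize), then the best (lowest) worst
accessibility class, then the Tm closest to a working temperature, with the
probe name as final tiebreak so the order is a deterministic total order.
An optional weighted scalar score is available for exploration, but the
lexicographic ranking is the headline because no principled weights exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .accessibility import UNKNOWN_RANK, AccessibilityScore
from .specificity import CallThresholds, SpecificityMatrix, predict_spectrum

__all__ = ["ProbeReport", "rank_probes", "report_table"]


@dataclass
class ProbeReport:
    probe_name: str
    min_offtarget: int
    n_zero_mm_offtargets: int
    positive_taxa: tuple[str, ...]
    weak_taxa: tuple[str, ...]
    worst_accessibility_class: str | None
    accessibility_rank: int
    tm_celsius: float
    specific: bool  # no off-target sequence matches exactly
    rank: int = 0

    @property
    def spectrum_summary(self) -> str:
        pos = ",".join(self.positive_taxa) or "-"
        weak = ",".join(self.weak_taxa) or "-"
        return f"positive:{pos};weak:{weak}"


def rank_probes(
    matrix: SpecificityMatrix,
    accessibility: Mapping[str, AccessibilityScore] | None = None,
    tm_by_probe: Mapping[str, float] | None = None,
    tm_target: float = 57.0,
    thresholds: CallThresholds = CallThresholds(),
    weights: tuple[float, float, float] | None = None,
) -> list[ProbeReport]:
    """Build deterministic ranked reports for all probes of a matrix.

    Sort keys: descending ``min_offtarget``; ascending worst accessibility
    class rank (unknown after class VI); ascending |Tm - tm_target|; name.
    With ``weights`` (w_specificity, w_accessibility, w_tm) a scalar score
    ``w1*min_offtarget - w2*access_rank - w3*|Tm - target|`` replaces the
    lexicographic key (descending), name still breaking ties.
    """
    accessibility = accessibility or {}
    tm_by_probe = tm_by_probe or {}
    predictions = predict_spectrum(matrix, thresholds)
    reports = []
    for name in matrix.probe_names:
        access = accessibility.get(name)
        access_rank = access.worst_rank if access else UNKNOWN_RANK
        target_taxa = {r.taxon or r.id for r in matrix.panel.target_records}
        calls = [p for p in predictions if p.probe_name == name]
        reports.append(
            ProbeReport(
                probe_name=name,
                min_offtarget=matrix.min_offtarget(name),
                n_zero_mm_offtargets=matrix.n_zero_mismatch_offtargets(name),
                positive_taxa=tuple(p.taxon for p in calls if p.call == "positive"),
                weak_taxa=tuple(p.taxon for p in calls if p.call == "weak"),
                worst_accessibility_class=access.worst_class if access else None,
                accessibility_rank=access_rank,
                tm_celsius=float(tm_by_probe.get(name, 0.0)),
                specific=matrix.min_offtarget(name) >= 1,
            )
        )
    if weights is None:
        def key(r: ProbeReport):
            return (-r.min_offtarget, r.accessibility_rank,
                    abs(r.tm_celsius - tm_target), r.probe_name)
    else:
        w1, w2, w3 = weights

        def key(r: ProbeReport):
            score = (w1 * r.min_offtarget - w2 * r.accessibility_rank
                     - w3 * abs(r.tm_celsius - tm_target))
            return (-score, r.probe_name)

    reports.sort(key=key)
    for i, r in enumerate(reports, start=1):
        r.rank = i
    return reports


REPORT_COLUMNS = ["rank", "probe", "min_offtarget", "n_zero_mm_offtargets",
                  "specific", "worst_access_class", "tm", "spectrum"]


def report_table(reports: Sequence[ProbeReport]) -> pd.DataFrame:
    rows = [
        {"rank": r.rank, "probe": r.probe_name, "min_offtarget": r.min_offtarget,
         "n_zero_mm_offtargets": r.n_zero_mm_offtargets,
         "specific": r.specific,
         "worst_access_class": r.worst_accessibility_class or "unknown",
         "tm": round(r.tm_celsius, 2), "spectrum": r.spectrum_summary}
        for r in reports
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
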