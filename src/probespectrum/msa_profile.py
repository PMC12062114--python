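"""Column profiling and discriminative-region discovery.

A column is *discriminative* when the target group is monomorphic there
(one base, no gap, optionally tolerating a fraction of deviant target
records) and at least one off-target sequence differs.  Windows holding
enough discriminative columns — and no target-group gap, which a probe
cannot span — are merged into maximal candidate regions, the "variable
domains" from which taxon-specific probes are designed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConfigurationError, InputError
from .seq_io import GAP, AlignedPanel, Group

__all__ = ["ColumnProfile", "CandidateRegion", "column_profiles",
           "find_discriminative_regions"]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-group base composition of one alignment column (1-based)."""

    column: int
    counts_by_group: dict[Group, dict[str, int]]
    target_consensus: str | None
    target_has_gap: bool
    is_discriminative: bool
    #: number of off-target records whose base differs from the target consensus
    discrimination_margin: int

    @property
    def total_count(self) -> int:
        return sum(n for g in self.counts_by_group.values() for n in g.values())


@dataclass
class CandidateRegion:
    """A maximal run of alignment columns covered by qualifying windows."""

    start: int  # alignment columns, 1-based closed
    end: int
    discriminative_columns: list[int]
    #: off-target record id -> number of discriminative columns where it differs
    per_sequence_diff_counts: dict[str, int] = field(default_factory=dict)
    #: taxon -> minimum diff count over that taxon's records
    per_taxon_min_diff: dict[str, int] = field(default_factory=dict)

    @property
    def n_discriminative(self) -> int:
        return len(self.discriminative_columns)

    def __contains__(self, column: int) -> bool:
        return self.start <= column <= self.end


def _target_consensus(bases: list[str], tolerance: float) -> tuple[str | None, bool]:
    """(consensus base or None, any-gap flag) for the target group at a column.

    Consensus exists when the most common non-gap base accounts for at least
    (1 - tolerance) of target records and no target record has a gap.
    """
    has_gap = GAP in bases
    if has_gap:
        return None, True
    counter = Counter(bases)
    base, count = counter.most_common(1)[0]
    if count >= (1.0 - tolerance) * len(bases) and base != GAP:
        return base, False
    return None, False


def column_profiles(
    panel: AlignedPanel, target_tolerance: float = 0.0
) -> list[ColumnProfile]:
    """Profile every alignment column by group.

    ``target_tolerance`` is the fraction of target records allowed to deviate
    from the consensus base while the column still counts as monomorphic
    (default 0: strict monomorphism, a probe must match every target strain).
    """
    targets = panel.target_records
    offtargets = panel.offtarget_records
    if not targets:
        raise ConfigurationError("panel has no target-group records")
    profiles = []
    for col in range(1, panel.length + 1):
        i = col - 1
        counts: dict[Group, dict[str, int]] = {}
        for rec in panel:
            counts.setdefault(rec.group, {})
            base = rec.residues[i]
            counts[rec.group][base] = counts[rec.group].get(base, 0) + 1
        consensus, has_gap = _target_consensus(
            [r.residues[i] for r in targets], target_tolerance
        )
        if consensus is None:
            margin = 0
            discriminative = False
        else:
            margin = sum(1 for r in offtargets if r.residues[i] != consensus)
            discriminative = margin >= 1
        profiles.append(
            ColumnProfile(
                column=col,
                counts_by_group=counts,
                target_consensus=consensus,
                target_has_gap=has_gap,
                is_discriminative=discriminative,
                discrimination_margin=margin,
            )
        )
    return profiles


def _merge_covered(starts: list[int], window_length: int) -> list[tuple[int, int]]:
    """Union of windows [s, s+w-1] as maximal runs of covered columns."""
    regions: list[tuple[int, int]] = []
    for s in starts:
        e = s + window_length - 1
        if regions and s <= regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], max(regions[-1][1], e))
        else:
            regions.append((s, e))
    return regions


def find_discriminative_regions(
    panel: AlignedPanel,
    window_length: int = 18,
    min_discriminative: int = 1,
    target_tolerance: float = 0.0,
    profiles: list[ColumnProfile] | None = None,
) -> list[CandidateRegion]:
    """Discover candidate probe regions.

    A window of ``window_length`` columns qualifies when it contains at least
    ``min_discriminative`` discriminative columns and no column where any
    target record has a gap; overlapping or adjacent qualifying windows merge
    into maximal regions, reported by ascending start column.
    """
    if window_length < 1 or min_discriminative < 1:
        raise InputError("window_length and min_discriminative must be >= 1")
    if window_length > panel.length:
        raise InputError(
            f"window_length {window_length} exceeds alignment length {panel.length}"
        )
    if profiles is None:
        profiles = column_profiles(panel, target_tolerance)

    disc = [1 if p.is_discriminative else 0 for p in profiles]
    gap = [1 if p.target_has_gap else 0 for p in profiles]
    # prefix sums over columns 1..L
    cum_d = [0]
    cum_g = [0]
    for d, g in zip(disc, gap):
        cum_d.append(cum_d[-1] + d)
        cum_g.append(cum_g[-1] + g)

    qualifying = []
    for s in range(1, panel.length - window_length + 2):
        e = s + window_length - 1
        if cum_g[e] - cum_g[s - 1] > 0:
            continue
        if cum_d[e] - cum_d[s - 1] >= min_discriminative:
            qualifying.append(s)

    consensus_at = {p.column: p.target_consensus for p in profiles}
    regions = []
    for start, end in _merge_covered(qualifying, window_length):
        cols = [p.column for p in profiles[start - 1 : end]
                if p.is_discriminative]
        region = CandidateRegion(start=start, end=end, discriminative_columns=cols)
        for rec in panel.offtarget_records:
            n = sum(
                1 for c in cols if rec.residues[c - 1] != consensus_at[c]
            )
            region.per_sequence_diff_counts[rec.id] = n
            prev = region.per_taxon_min_diff.get(rec.taxon)
            region.per_taxon_min_diff[rec.taxon] = n if prev is None else min(prev, n)
        regions.append(region)
    return regions
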