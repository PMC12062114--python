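"""Probe construction, physical properties and anti-sense controls.

A probe is stored 5'->3' in the orientation that hybridizes the rRNA, i.e.
as the reverse complement of the target-site sense sequence.  Coordinates
are 1-based closed intervals on the ungapped designated reference, and the
default naming convention is ``<prefix><target_start>``.

Melting temperature uses the classic salt- and formamide-corrected
empirical formula for DNA duplexes,

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*(%GC) - 675/length - 0.62*(%formamide)

with [Na+] in mol/L, %GC and %formamide in percent.  Default conditions
follow a standard FISH buffer (0.9 M Na+, 30% formamide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DesignError, InputError
from .msa_profile import CandidateRegion, column_profiles
from .seq_io import (
    AlignedPanel,
    CoordinateMap,
    build_coordinate_map,
    reverse_complement,
)

__all__ = [
    "Probe", "HybridizationConditions", "DesignConstraints",
    "physical_properties", "melting_temperature", "probe_from_site",
    "enumerate_probes", "antisense_control", "read_probe_table",
    "write_probe_table", "write_probe_fasta",
]


@dataclass(frozen=True)
class HybridizationConditions:
    """Buffer conditions entering the Tm correction."""

    na_molar: float = 0.9          # monovalent cation concentration, mol/L
    formamide_percent: float = 30.0

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise InputError("Na+ molarity must be positive")
        if not 0 <= self.formamide_percent <= 100:
            raise InputError("formamide percentage must be in [0, 100]")


@dataclass
class Probe:
    """An oligonucleotide probe complementary to the rRNA target site."""

    name: str
    sequence: str  # 5'->3', reverse complement of the target-site sense strand
    target_start: int  # 1-based closed, on the ungapped reference
    target_end: int
    gc_fraction: float = 0.0
    tm_celsius: float = 0.0
    role: str = "sense"  # "sense" | "antisense_control"
    label: str | None = None  # fluorophore tag, metadata only
    region: tuple[int, int] | None = None  # originating alignment region

    def __post_init__(self) -> None:
        if self.target_end - self.target_start + 1 != len(self.sequence):
            raise DesignError(
                f"probe {self.name!r}: coordinates [{self.target_start},"
                f"{self.target_end}] inconsistent with length {len(self.sequence)}"
            )
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise DesignError(f"probe {self.name!r} has non-ACGT bases: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def site_sense(self) -> str:
        """The target-site sense sequence the probe base-pairs with."""
        return reverse_complement(self.sequence)


@dataclass
class DesignConstraints:
    """Physical constraints applied when enumerating candidate probes.

    Defaults: 18-mers (the length of the canonical Euk516 probe family),
    GC 0.40-0.65, homopolymer runs capped at 4, Tm unconstrained but
    computed under FISH buffer conditions.  All overridable.
    """

    length_range: tuple[int, int] = (18, 18)
    gc_range: tuple[float, float] = (0.40, 0.65)
    tm_range: tuple[float, float] | None = None
    max_homopolymer: int = 4
    conditions: HybridizationConditions = field(default_factory=HybridizationConditions)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise InputError("empty probe length range")
        if not (0 <= self.gc_range[0] <= self.gc_range[1] <= 1):
            raise InputError("invalid GC range")
        if self.tm_range is not None and self.tm_range[0] > self.tm_range[1]:
            raise InputError("empty Tm range")


def _max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def melting_temperature(
    sequence: str, conditions: HybridizationConditions = HybridizationConditions()
) -> float:
    """Salt/formamide-corrected empirical duplex Tm in Celsius."""
    if not sequence:
        raise InputError("cannot compute Tm of an empty sequence")
    gc_pct = 100.0 * sum(sequence.count(b) for b in "GC") / len(sequence)
    return (
        81.5
        + 16.6 * math.log10(conditions.na_molar)
        + 0.41 * gc_pct
        - 675.0 / len(sequence)
        - 0.62 * conditions.formamide_percent
    )


def physical_properties(
    sequence: str, conditions: HybridizationConditions = HybridizationConditions()
) -> tuple[float, float]:
    """(GC fraction, Tm in Celsius) of a probe sequence."""
    if not sequence:
        raise InputError("empty probe sequence")
    gc = sum(sequence.count(b) for b in "GC") / len(sequence)
    return gc, melting_temperature(sequence, conditions)


def probe_from_site(
    panel: AlignedPanel,
    start: int,
    length: int,
    prefix: str = "probe",
    conditions: HybridizationConditions = HybridizationConditions(),
    coord_map: CoordinateMap | None = None,
    region: tuple[int, int] | None = None,
) -> Probe:
    """Design the probe complementary to reference positions [start, start+length-1].

    The target group must be monomorphic and ungapped over every alignment
    column of the site; offending columns are listed in the error.
    """
    if length < 1:
        raise InputError("probe length must be >= 1")
    if coord_map is None:
        coord_map = build_coordinate_map(panel, panel.reference_id)
    end = start + length - 1
    cols = [coord_map.ref_to_col(p) for p in range(start, end + 1)]
    profiles = column_profiles(panel)
    bad = [
        c for c in cols
        if profiles[c - 1].target_consensus is None
    ]
    if bad:
        raise DesignError(
            f"site [{start},{end}] spans target-group polymorphism or gap "
            f"at alignment columns {bad}"
        )
    sense = "".join(profiles[c - 1].target_consensus for c in cols)
    sequence = reverse_complement(sense)
    gc, tm = physical_properties(sequence, conditions)
    return Probe(
        name=f"{prefix}{start}",
        sequence=sequence,
        target_start=start,
        target_end=end,
        gc_fraction=gc,
        tm_celsius=tm,
        region=region,
    )


def enumerate_probes(
    panel: AlignedPanel,
    regions: Sequence[CandidateRegion],
    constraints: DesignConstraints = DesignConstraints(),
    prefix: str = "probe",
) -> list[Probe]:
    """Enumerate all constraint-satisfying probes over candidate regions.

    Deterministic order: ascending target_start, then length.  Sites whose
    target group is polymorphic or gapped are silently skipped (regions
    guarantee no target gaps but not full monomorphism between
    discriminative columns).
    """
    coord_map = build_coordinate_map(panel, panel.reference_id)
    profiles = column_profiles(panel)
    lo, hi = constraints.length_range
    candidates: list[Probe] = []
    seen: set[tuple[int, int]] = set()
    for region in regions:
        for col_start in range(region.start, region.end + 1):
            try:
                start = coord_map.col_to_ref(col_start)
            except Exception:
                continue  # reference gap column
            for length in range(lo, hi + 1):
                end_col = None
                if start + length - 1 > len(coord_map):
                    continue
                end_col = coord_map.ref_to_col(start + length - 1)
                if end_col > region.end:
                    continue
                if (start, length) in seen:
                    continue
                seen.add((start, length))
                try:
                    probe = probe_from_site(
                        panel, start, length, prefix=prefix,
                        conditions=constraints.conditions,
                        coord_map=coord_map,
                        region=(region.start, region.end),
                    )
                except DesignError:
                    continue
                if not (constraints.gc_range[0] <= probe.gc_fraction
                        <= constraints.gc_range[1]):
                    continue
                if constraints.tm_range is not None and not (
                    constraints.tm_range[0] <= probe.tm_celsius
                    <= constraints.tm_range[1]
                ):
                    continue
                if _max_homopolymer_run(probe.sequence) > constraints.max_homopolymer:
                    continue
                candidates.append(probe)
    candidates.sort(key=lambda p: (p.target_start, p.length))
    return candidates


def antisense_control(probe: Probe) -> Probe:
    """Reverse-complemented, non-binding negative-control version of a probe.

    The control carries the target-site sense sequence and therefore cannot
    base-pair with the rRNA; controls are never chained.
    """
    if probe.role != "sense":
        raise DesignError(
            f"anti-sense control requested for non-sense probe {probe.name!r}"
        )
    sequence = reverse_complement(probe.sequence)
    gc, tm = physical_properties(sequence)
    return replace(
        probe,
        name=f"AS-{probe.name}",
        sequence=sequence,
        gc_fraction=gc,
        tm_celsius=tm,
        role="antisense_control",
    )


PROBE_COLUMNS = ["name", "sequence", "target_start", "target_end",
                 "gc", "tm", "role", "label"]


def write_probe_table(probes: Sequence[Probe], path: str | Path) -> None:
    rows = [
        {"name": p.name, "sequence": p.sequence, "target_start": p.target_start,
         "target_end": p.target_end, "gc": round(p.gc_fraction, 4),
         "tm": round(p.tm_celsius, 2), "role": p.role, "label": p.label or ""}
        for p in probes
    ]
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[Probe]:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    probes = []
    for _, row in table.iterrows():
        probes.append(
            Probe(
                name=row["name"],
                sequence=row["sequence"].upper(),
                target_start=int(row["target_start"]),
                target_end=int(row["target_end"]),
                gc_fraction=float(row["gc"]) if row.get("gc") else 0.0,
                tm_celsius=float(row["tm"]) if row.get("tm") else 0.0,
                role=row.get("role") or "sense",
                label=row.get("label") or None,
            )
        )
    return probes


def write_probe_fasta(probes: Sequence[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.name}\n{p.sequence}\n")
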