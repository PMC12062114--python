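"""Mismatch profiling, specificity matrices, spectrum prediction, screening.

This is the in-silico counterpart of low-stringency database searching:
instead of heuristic seeded alignment, every probe is compared exhaustively
(Hamming distance, no indels) against panel sequences over its target-site
alignment columns, and against arbitrary FASTA collections window by
window.  Exhaustive scanning is deterministic and directly testable against
a naive oracle, and SSU-scale inputs make it cheap.

Orientation contract: probes are stored 5'->3' complementary to the rRNA,
so a probe hybridizes wherever a subject's sense strand matches the probe's
*site-sense* sequence (the probe's reverse complement).  Anti-sense control
probes consequently hit nothing on sense-strand rRNA.

Per-taxon calls aggregate multiple sequences of one taxon by the MINIMUM
mismatch count (any matching strain can light up) and map counts to calls
via thresholds, by default 0 -> positive, 1 -> weak, >=2 -> negative.
Mismatch-position effects on duplex stability are not modeled; a 1-mismatch
"weak" call is a conservative flag, not a quantitative intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, InputError
from .probe_design import Probe
from .seq_io import (
    GAP,
    AlignedPanel,
    CoordinateMap,
    SequenceRecord,
    base_matches,
    build_coordinate_map,
    logger,
)

__all__ = [
    "MismatchProfile", "SpecificityMatrix", "CallThresholds",
    "SpectrumPrediction", "ScreenHit", "mismatch_profile",
    "specificity_matrix", "min_offtarget_distance", "predict_spectrum",
    "spectrum_table", "screen_collection",
]


@dataclass(frozen=True)
class MismatchProfile:
    """Mismatch evidence for one (probe, panel sequence) pair.

    ``mismatch_positions`` are probe-local 1-based substitution positions;
    gap-induced mismatches are counted in ``n_mismatches`` but listed
    separately via ``n_gap_mismatches``.
    """

    probe_name: str
    sequence_id: str
    taxon: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]
    n_gap_mismatches: int = 0

    @property
    def has_gap(self) -> bool:
        return self.n_gap_mismatches > 0


@dataclass(frozen=True)
class CallThresholds:
    """Mismatch-count cutoffs for hybridization calls."""

    positive_max: int = 0  # counts <= this -> positive
    weak_max: int = 1      # counts <= this (and > positive_max) -> weak

    def __post_init__(self) -> None:
        if not 0 <= self.positive_max <= self.weak_max:
            raise InputError("need 0 <= positive_max <= weak_max")

    def call(self, n_mismatches: int) -> str:
        if n_mismatches <= self.positive_max:
            return "positive"
        if n_mismatches <= self.weak_max:
            return "weak"
        return "negative"


@dataclass(frozen=True)
class SpectrumPrediction:
    """Predicted hybridization outcome of one probe for one taxon."""

    probe_name: str
    taxon: str
    min_mismatches: int
    call: str


@dataclass
class SpecificityMatrix:
    """Complete probes x panel-sequences mismatch matrix."""

    profiles: dict[tuple[str, str], MismatchProfile]  # (probe name, seq id) -> profile
    probe_names: list[str]
    panel: AlignedPanel

    def profile(self, probe_name: str, sequence_id: str) -> MismatchProfile:
        return self.profiles[(probe_name, sequence_id)]

    def profiles_for(self, probe_name: str) -> list[MismatchProfile]:
        return [self.profiles[(probe_name, r.id)] for r in self.panel]

    def min_offtarget(self, probe_name: str) -> int:
        offs = self.panel.offtarget_records
        if not offs:
            raise ConfigurationError("panel has no off-target records")
        return min(self.profiles[(probe_name, r.id)].n_mismatches for r in offs)

    def n_zero_mismatch_offtargets(self, probe_name: str) -> int:
        return sum(
            1 for r in self.panel.offtarget_records
            if self.profiles[(probe_name, r.id)].n_mismatches == 0
        )


def mismatch_profile(
    probe: Probe,
    record: SequenceRecord,
    coord_map: CoordinateMap,
) -> MismatchProfile:
    """Compare a probe's site-sense sequence to one aligned record.

    The comparison runs over the alignment columns that the reference
    coordinate map assigns to the probe's target interval.  Gaps in the
    record count as mismatches (flagged); IUPAC ambiguity codes mismatch
    unless they contain the expected base.
    """
    try:
        cols = [coord_map.ref_to_col(p)
                for p in range(probe.target_start, probe.target_end + 1)]
    except CoordinateError as exc:
        raise CoordinateError(
            f"probe {probe.name!r} site does not map into the alignment: {exc}"
        ) from exc
    expected = probe.site_sense
    positions: list[int] = []
    n_gaps = 0
    for i, col in enumerate(cols):
        observed = record.residues[col - 1]
        if observed == GAP:
            n_gaps += 1
        elif not base_matches(expected[i], observed):
            positions.append(i + 1)
    return MismatchProfile(
        probe_name=probe.name,
        sequence_id=record.id,
        taxon=record.taxon,
        n_mismatches=len(positions) + n_gaps,
        mismatch_positions=tuple(positions),
        n_gap_mismatches=n_gaps,
    )


def specificity_matrix(
    probes: Sequence[Probe], panel: AlignedPanel
) -> SpecificityMatrix:
    """Mismatch profiles of every probe against every panel sequence."""
    coord_map = build_coordinate_map(panel, panel.reference_id)
    profiles = {}
    for probe in probes:
        for record in panel:
            profiles[(probe.name, record.id)] = mismatch_profile(
                probe, record, coord_map
            )
    return SpecificityMatrix(
        profiles=profiles,
        probe_names=[p.name for p in probes],
        panel=panel,
    )


def min_offtarget_distance(probe: Probe, panel: AlignedPanel) -> int:
    """Minimum mismatch count of a probe over all off-target panel sequences."""
    return specificity_matrix([probe], panel).min_offtarget(probe.name)


def predict_spectrum(
    matrix: SpecificityMatrix,
    thresholds: CallThresholds = CallThresholds(),
    strict_gaps: bool = False,
) -> list[SpectrumPrediction]:
    """Per-taxon hybridization calls for every probe in the matrix.

    Taxa aggregate by minimum mismatch count over their sequences.  With
    ``strict_gaps`` profiles whose target site is gapped are excluded from
    the aggregation (a taxon left with no usable profile is called
    ``negative`` at its gap-inclusive count).  Output is sorted by probe
    (matrix order) then taxon.
    """
    predictions = []
    taxa = sorted({r.taxon or r.id for r in matrix.panel})
    by_taxon: dict[str, list[SequenceRecord]] = {}
    for r in matrix.panel:
        by_taxon.setdefault(r.taxon or r.id, []).append(r)
    for probe_name in matrix.probe_names:
        for taxon in taxa:
            profs = [matrix.profile(probe_name, r.id) for r in by_taxon[taxon]]
            usable = [p for p in profs if not (strict_gaps and p.has_gap)]
            pool = usable or profs
            n = min(p.n_mismatches for p in pool)
            call = thresholds.call(n) if usable else "negative"
            predictions.append(
                SpectrumPrediction(probe_name=probe_name, taxon=taxon,
                                   min_mismatches=n, call=call)
            )
    return predictions


SPECTRUM_COLUMNS = ["probe", "taxon", "min_mismatches", "call"]


def spectrum_table(predictions: Iterable[SpectrumPrediction]) -> pd.DataFrame:
    rows = [
        {"probe": p.probe_name, "taxon": p.taxon,
         "min_mismatches": p.min_mismatches, "call": p.call}
        for p in predictions
    ]
    return pd.DataFrame(rows, columns=SPECTRUM_COLUMNS)


@dataclass(frozen=True)
class ScreenHit:
    """One window of a screened subject within the mismatch budget."""

    probe_name: str
    subject_id: str
    subject_start: int  # 1-based start of the window on the subject
    strand: str         # '+': probe binds the subject's sense strand
    n_mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan(pattern: str, subject: np.ndarray, max_mismatches: int) -> np.ndarray:
    """Hamming distances of `pattern` against every window of `subject`."""
    m = len(pattern)
    n_win = subject.size - m + 1
    pat = _encode(pattern)
    counts = np.zeros(n_win, dtype=np.int32)
    for i in range(m):
        counts += subject[i : i + n_win] != pat[i]
    return counts


def screen_collection(
    probe: Probe,
    subjects: Iterable[tuple[str, str]] | str | Path,
    max_mismatches: int,
    both_strands: bool = False,
) -> list[ScreenHit]:
    """Exhaustively scan subjects for windows the probe would hybridize.

    In the default sense-only mode a hit is a subject window whose sense
    sequence is within ``max_mismatches`` Hamming distance of the probe's
    site-sense sequence; with ``both_strands`` windows matching the probe
    itself (binding to the reverse strand of a double-stranded subject) are
    also reported, with strand '-'.  Subjects shorter than the probe are
    skipped with a warning.  Hits are sorted by (subject id, start, strand).
    """
    if max_mismatches >= probe.length:
        raise InputError("max_mismatches must be smaller than the probe length")
    if isinstance(subjects, (str, Path)):
        from .seq_io import read_fasta_collection

        subjects = read_fasta_collection(subjects)
    hits: list[ScreenHit] = []
    patterns = [("+", probe.site_sense)]
    if both_strands:
        patterns.append(("-", probe.sequence))
    for subject_id, seq in subjects:
        seq = seq.upper().replace("U", "T")
        if len(seq) < probe.length:
            logger.warning(
                "subject %r (length %d) shorter than probe %r (length %d); skipped",
                subject_id, len(seq), probe.name, probe.length,
            )
            continue
        encoded = _encode(seq)
        for strand, pattern in patterns:
            counts = _scan(pattern, encoded, max_mismatches)
            for idx in np.nonzero(counts <= max_mismatches)[0]:
                hits.append(
                    ScreenHit(
                        probe_name=probe.name,
                        subject_id=subject_id,
                        subject_start=int(idx) + 1,
                        strand=strand,
                        n_mismatches=int(counts[idx]),
                    )
                )
    hits.sort(key=lambda h: (h.subject_id, h.subject_start, h.strand))
    return hits
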