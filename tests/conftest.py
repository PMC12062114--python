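"""Shared fixtures and independent oracles.

Oracles here are deliberately naive re-derivations from first principles
(pure-Python loops over sequences) so they stay independent of the code
paths they check.
"""

from __future__ import annotations

import pytest

from probespectrum.seq_io import AlignedPanel, Group, SequenceRecord
from probespectrum.simulate import make_paper_like_fixture

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def naive_regions(panel: AlignedPanel, window: int, min_disc: int):
    """Enumerate every window, test the predicate, merge covered columns."""
    targets = [r.residues for r in panel.records if r.group is Group.TARGET]
    offs = [r.residues for r in panel.records
            if r.group in (Group.NON_TARGET, Group.OUTGROUP)]
    length = panel.length
    disc, tgap = [], []
    for i in range(length):
        bases = {s[i] for s in targets}
        gap = "-" in bases
        tgap.append(gap)
        d = False
        if not gap and len(bases) == 1:
            b = next(iter(bases))
            d = any(s[i] != b for s in offs)
        disc.append(d)
    covered: set[int] = set()
    for s in range(length - window + 1):
        win = range(s, s + window)
        if any(tgap[i] for i in win):
            continue
        if sum(1 for i in win if disc[i]) >= min_disc:
            covered.update(win)
    runs: list[list[int]] = []
    for i in sorted(covered):
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [(a + 1, b + 1) for a, b in runs]  # 1-based closed


def naive_screen(pattern: str, subject: str, max_mm: int):
    """(1-based start, mismatches) of every window within the budget."""
    hits = []
    m = len(pattern)
    for s in range(len(subject) - m + 1):
        mm = sum(1 for a, b in zip(pattern, subject[s : s + m]) if a != b)
        if mm <= max_mm:
            hits.append((s + 1, mm))
    return hits


def make_panel(rows, reference_id=None):
    """rows: (id, residues, taxon, group) tuples -> AlignedPanel."""
    records = [
        SequenceRecord(id=i, residues=seq, taxon=taxon, group=Group(group))
        for i, seq, taxon, group in rows
    ]
    return AlignedPanel(records=records, reference_id=reference_id)


@pytest.fixture
def tiny_panel() -> AlignedPanel:
    """Gapless 6-sequence panel: 2 targets, 3 non-targets, 1 outgroup.

    Columns 5 and 11 discriminate the target from everything; column 8
    separates only the outgroup.
    """
    #          123456789012345678901234
    t_seq = "ACGTACGTACGTACGTACGTACGT"
    nt1 = "ACGTGCGTACTTACGTACGTACGT"  # differs at 5, 11
    nt2 = "ACGTGCGTACTTACGTACGTACGT"
    out = "ACGTGCGAACTTACGTACGTACGT"  # differs at 5, 8, 11
    return make_panel([
        ("Tmag1", t_seq, "T_magnatum", "target"),
        ("Tmag2", t_seq, "T_magnatum", "target"),
        ("Taes1", nt1, "T_aestivum", "non_target"),
        ("Tbor1", nt2, "T_borchii", "non_target"),
        ("Tbru1", nt1, "T_brumale", "non_target"),
        ("Meximia1", out, "M_eximia", "outgroup"),
    ])


@pytest.fixture(scope="session")
def bundle():
    """The graded-specificity synthetic bundle at a fixed seed."""
    return make_paper_like_fixture(7)


@pytest.fixture(scope="session")
def bundle_names(bundle):
    return {p.target_start: p.name for p in bundle.probes}
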