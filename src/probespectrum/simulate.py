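"""Synthetic SSU-like panels with planted diagnostic SNPs.

Every other module is testable offline against panels generated here: a
monomorphic target clade, several non-target clades and optional outgroup
clades share one ancestral reference; clade-level substitutions are planted
at chosen positions (the diagnostic SNPs) and, outside those, drawn i.i.d.
per site per clade at a background divergence rate.  Sequences within a
clade are identical — there is no phylogenetic correlation or rate
heterogeneity, which is sufficient for exercising discrimination logic but
does not emulate real rRNA covariation.

Randomness is integer-only (numpy Generator.integers), so panels are
byte-reproducible for a fixed seed across platforms.

The *paper-like* preset builds the reference scenario used throughout the
test-suite: one target taxon, four in-family relatives, two outgroups, and
four planted 18-nt probe windows whose off-target mismatch floors mirror a
graded specificity series — a strictly specific probe with a 1-SNP floor, a
pan-genus probe matching all relatives, a probe matching one relative
exactly and another at a single SNP, and a strictly specific probe with a
3-SNP floor.  All inter-clade variation in the preset is planted (zero
background divergence) so discriminative-region discovery must recover
exactly the four planted windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .probe_design import Probe, probe_from_site
from .seq_io import (
    AlignedPanel,
    Group,
    SequenceRecord,
    write_alignment,
    write_panel_table,
)
from .specificity import CallThresholds

__all__ = ["PlantedSite", "PanelTruth", "PaperLikeBundle",
           "simulate_panel", "make_paper_like_fixture", "write_bundle"]

BASES = "ACGT"
#: deterministic substitution used for planted SNPs (transitions)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class PlantedSite:
    """One diagnostic position: which clades differ from the target base."""

    position: int  # 1-based on the (gapless) reference
    alt_bases: dict[str, str]  # clade taxon -> substituted base

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError("planted position must be >= 1")


@dataclass
class PanelTruth:
    """Generation-time ground truth for a simulated panel."""

    seed: int
    length: int
    reference: str
    groups: dict[str, str]                 # taxon -> group label
    members: dict[str, list[str]]          # taxon -> sequence ids
    planted_sites: list[PlantedSite]
    #: taxon -> {position: base} for every position differing from the target
    diffs: dict[str, dict[int, str]]

    def expected_mismatches(self, taxon: str, start: int, end: int) -> int:
        """Mismatch count of the [start, end] target-site window vs a clade."""
        return sum(1 for p in self.diffs.get(taxon, {}) if start <= p <= end)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "length": self.length,
            "reference": self.reference,
            "groups": self.groups,
            "members": self.members,
            "planted_sites": [
                {"position": s.position, "alt_bases": s.alt_bases}
                for s in self.planted_sites
            ],
            "diffs": {t: {str(p): b for p, b in d.items()}
                      for t, d in self.diffs.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _clade_sequence(
    reference: str,
    taxon: str,
    planted_sites: list[PlantedSite],
    background_divergence: float,
    rng: np.random.Generator,
) -> tuple[str, dict[int, str]]:
    """One clade's (gapless) sequence plus its diffs-vs-target map."""
    seq = list(reference)
    diffs: dict[int, str] = {}
    planted_positions = {s.position for s in planted_sites}
    if background_divergence > 0:
        scale = 1_000_000
        cutoff = int(round(background_divergence * scale))
        draws = rng.integers(0, scale, size=len(reference))
        shifts = rng.integers(1, 4, size=len(reference))
        for i in np.nonzero(draws < cutoff)[0]:
            pos = int(i) + 1
            if pos in planted_positions:
                continue
            new = BASES[(BASES.index(seq[i]) + int(shifts[i])) % 4]
            seq[i] = new
            diffs[pos] = new
    for site in planted_sites:
        alt = site.alt_bases.get(taxon)
        # planting the base the target already carries is a no-op, not a diff
        if alt is not None and alt != seq[site.position - 1]:
            seq[site.position - 1] = alt
            diffs[site.position] = alt
    return "".join(seq), diffs


def simulate_panel(
    seed: int,
    n_target: int = 3,
    n_nontarget_per_clade: int = 2,
    n_clades: int = 4,
    length: int = 1800,
    background_divergence: float = 0.01,
    planted_sites: list[PlantedSite] | None = None,
    n_outgroup_clades: int = 0,
    outgroup_divergence: float = 0.05,
    target_taxon: str = "target",
    clade_taxa: list[str] | None = None,
    outgroup_taxa: list[str] | None = None,
    clade_sizes: dict[str, int] | None = None,
) -> tuple[AlignedPanel, PanelTruth]:
    """Simulate a gapless SSU-like aligned panel with known ground truth.

    Defaults emulate a small design panel: a 1800-nt SSU-length reference,
    four non-target clades at 1%/site background divergence from the target
    (SSU-realistic within a family).  Planted sites override the background:
    the target clade is monomorphic there and exactly the clades named in
    ``alt_bases`` differ.
    """
    if min(n_target, n_clades, length) < 1 or n_nontarget_per_clade < 1:
        raise InputError("panel dimensions must be positive")
    planted_sites = list(planted_sites or [])
    for s in planted_sites:
        if s.position > length:
            raise InputError(f"planted position {s.position} exceeds length {length}")
    if len({s.position for s in planted_sites}) != len(planted_sites):
        raise InputError("planted positions must be distinct")
    rng = np.random.default_rng(seed)
    reference = "".join(BASES[i] for i in rng.integers(0, 4, size=length))

    clade_taxa = clade_taxa or [f"clade{i + 1:02d}" for i in range(n_clades)]
    outgroup_taxa = outgroup_taxa or [
        f"outgroup{i + 1:02d}" for i in range(n_outgroup_clades)
    ]
    clade_sizes = clade_sizes or {}

    records: list[SequenceRecord] = []
    members: dict[str, list[str]] = {}
    groups: dict[str, str] = {target_taxon: Group.TARGET.value}
    diffs: dict[str, dict[int, str]] = {}

    for k in range(clade_sizes.get(target_taxon, n_target)):
        rid = f"{target_taxon}_{k + 1}"
        records.append(SequenceRecord(id=rid, residues=reference,
                                      taxon=target_taxon, group=Group.TARGET))
        members.setdefault(target_taxon, []).append(rid)

    for taxon, group, divergence in (
        [(t, Group.NON_TARGET, background_divergence) for t in clade_taxa]
        + [(t, Group.OUTGROUP, outgroup_divergence) for t in outgroup_taxa]
    ):
        seq, clade_diffs = _clade_sequence(
            reference, taxon, planted_sites, divergence, rng
        )
        groups[taxon] = group.value
        diffs[taxon] = clade_diffs
        for k in range(clade_sizes.get(taxon, n_nontarget_per_clade)):
            rid = f"{taxon}_{k + 1}"
            records.append(SequenceRecord(id=rid, residues=seq,
                                          taxon=taxon, group=group))
            members.setdefault(taxon, []).append(rid)

    panel = AlignedPanel(records=records, reference_id=members[target_taxon][0])
    truth = PanelTruth(
        seed=seed, length=length, reference=reference, groups=groups,
        members=members, planted_sites=planted_sites, diffs=diffs,
    )
    _verify_truth(panel, truth)
    return panel, truth


def _verify_truth(panel: AlignedPanel, truth: PanelTruth) -> None:
    """Generation-time self-check: emitted residues equal truth bookkeeping."""
    for taxon, ids in truth.members.items():
        expected = list(truth.reference)
        for pos, base in truth.diffs.get(taxon, {}).items():
            expected[pos - 1] = base
        expected_seq = "".join(expected)
        for rid in ids:
            assert panel.get(rid).residues == expected_seq, (
                f"truth inconsistent with emitted panel for {rid}"
            )


# --- paper-like preset ----------------------------------------------------

TARGET_ANALOG = "T_magnatum_analog"
RELATIVE_ANALOGS = ["T_borchii_analog", "T_aestivum_analog",
                    "T_brumale_analog", "Choiromyces_analog"]
OUTGROUP_ANALOGS = ["M_eximia_analog", "D_leucomelaena_analog"]

PROBE_LENGTH = 18
PROBE_STARTS = (185, 645, 1313, 1647)

#: per window start: clade taxon -> probe-local 0-based offsets that differ
PLANTED_OFFSETS: dict[int, dict[str, tuple[int, ...]]] = {
    185: {
        "T_borchii_analog": (4,),
        "T_aestivum_analog": (9,),
        "T_brumale_analog": (4, 12),
        "Choiromyces_analog": (7, 14),
        "M_eximia_analog": (2, 6, 10, 15),
        "D_leucomelaena_analog": (3, 8, 13, 16),
    },
    645: {
        "M_eximia_analog": (1, 8, 15),
        "D_leucomelaena_analog": (2, 9, 16),
    },
    1313: {
        "T_aestivum_analog": (8,),
        "T_brumale_analog": (3, 11),
        "Choiromyces_analog": (2, 9, 15),
        "M_eximia_analog": (1, 5, 10, 16),
        "D_leucomelaena_analog": (0, 6, 12, 17),
    },
    1647: {
        "T_borchii_analog": (1, 8, 15),
        "T_aestivum_analog": (2, 9, 16),
        "T_brumale_analog": (3, 10, 17),
        "Choiromyces_analog": (0, 7, 14),
        "M_eximia_analog": (1, 4, 8, 12, 16),
        "D_leucomelaena_analog": (0, 5, 9, 13, 17),
    },
}


@dataclass
class PaperLikeBundle:
    panel: AlignedPanel
    truth: PanelTruth
    probes: list[Probe]
    expected_spectrum: pd.DataFrame
    thresholds: CallThresholds = field(default_factory=CallThresholds)

    @property
    def expected_min_offtarget(self) -> dict[str, int]:
        out = {}
        for probe in self.probes:
            out[probe.name] = min(
                self.truth.expected_mismatches(t, probe.target_start,
                                               probe.target_end)
                for t in RELATIVE_ANALOGS + OUTGROUP_ANALOGS
            )
        return out


def make_paper_like_fixture(
    seed: int, prefix: str = "T.ana", length: int = 1800
) -> PaperLikeBundle:
    """Build the graded-specificity reference bundle (see module docstring)."""
    planted: list[PlantedSite] = []
    for start, clades in PLANTED_OFFSETS.items():
        offsets = sorted({o for offs in clades.values() for o in offs})
        for off in offsets:
            pos = start + off
            alt_bases = {}
            for taxon, offs in clades.items():
                if off in offs:
                    # base is only known after the reference draw; mark with
                    # a placeholder resolved below
                    alt_bases[taxon] = "?"
            planted.append(PlantedSite(position=pos, alt_bases=alt_bases))

    # draw the reference first so planted alt bases can be fixed transitions
    rng = np.random.default_rng(seed)
    reference = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    resolved = [
        PlantedSite(
            position=s.position,
            alt_bases={t: TRANSITION[reference[s.position - 1]]
                       for t in s.alt_bases},
        )
        for s in planted
    ]

    panel, truth = simulate_panel(
        seed=seed,
        length=length,
        background_divergence=0.0,
        outgroup_divergence=0.0,
        planted_sites=resolved,
        target_taxon=TARGET_ANALOG,
        clade_taxa=RELATIVE_ANALOGS,
        outgroup_taxa=OUTGROUP_ANALOGS,
        n_target=3,
        n_nontarget_per_clade=2,
        clade_sizes={"T_brumale_analog": 1, "M_eximia_analog": 1,
                     "D_leucomelaena_analog": 1},
    )
    assert truth.reference == reference  # same seed, same first draw

    probes = [
        probe_from_site(panel, start, PROBE_LENGTH, prefix=prefix)
        for start in PROBE_STARTS
    ]

    thresholds = CallThresholds()
    taxa = sorted(truth.members)
    rows = []
    for probe in probes:
        for taxon in taxa:
            n = truth.expected_mismatches(taxon, probe.target_start,
                                          probe.target_end)
            rows.append({"probe": probe.name, "taxon": taxon,
                         "min_mismatches": n, "call": thresholds.call(n)})
    expected = pd.DataFrame(rows,
                            columns=["probe", "taxon", "min_mismatches", "call"])
    return PaperLikeBundle(panel=panel, truth=truth, probes=probes,
                           expected_spectrum=expected, thresholds=thresholds)


def write_bundle(bundle: PaperLikeBundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit alignment, panel TSV, probes TSV, truth JSON and expected spectrum."""
    from .probe_design import write_probe_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fa",
        "panel": out / "panel.tsv",
        "probes": out / "probes.tsv",
        "truth": out / "truth.json",
        "expected_spectrum": out / "expected_spectrum.tsv",
    }
    write_alignment(bundle.panel, paths["alignment"])
    write_panel_table(bundle.panel, paths["panel"])
    write_probe_table(bundle.probes, paths["probes"])
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    bundle.expected_spectrum.to_csv(paths["expected_spectrum"], sep="\t",
                                    index=False)
    return paths
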