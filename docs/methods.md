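# Methods

## Model and scope

`probespectrum` treats probe specificity as a purely combinatorial
property of a multiple sequence alignment: a probe is a reverse-complement
copy of a target-site sense window, and its affinity for any other
organism is summarized by the Hamming distance between that window and the
organism's aligned residues. This deliberately ignores duplex
thermodynamics beyond an empirical Tm (no nearest-neighbor stacking, no
mismatch-position or mismatch-identity effects, no rRNA secondary
structure). The package therefore predicts *mismatch spectra*, not signal
intensities; the mapping from mismatch counts to hybridization calls is a
threshold convention, documented below.

## Coordinates and alphabet

All probe coordinates are 1-based closed intervals on the **ungapped
designated reference** (by default the first target-group sequence), which
matches the field's probe-naming convention `<prefix><start>` (e.g. a
species probe named after position 1647 of its SSU). A `CoordinateMap`
provides the bijection between alignment columns and ungapped reference
positions; round-trip identity is property-tested. Alignment numbering on
an external standard (e.g. E. coli positions) can be obtained by
designating a different reference record.

RNA input (`U`) is normalized to DNA (`T`) at ingestion — probes are
synthesized as DNA — with a per-record flag preserving the original
alphabet. IUPAC ambiguity codes are legal in panel sequences and are
treated conservatively during mismatch counting: an ambiguous residue
matches only if the expected base is inside its ambiguity set (`R` matches
an expected `A`, not an expected `C`). Gaps never match; a gap inside a
record's target site counts as a mismatch and sets a `has_gap` flag, and a
strict mode can exclude gapped sites from spectrum calls entirely.

## Discriminative columns and candidate regions

A column is *discriminative* when (i) the target group is monomorphic
there — one base, no gap; a `target_tolerance` parameter (default 0) can
allow a fraction of target records to deviate — and (ii) at least one
off-target record (groups `non_target` and `outgroup`; `unassigned`
records are ignored) differs. The *discrimination margin* is the number of
differing off-target records.

Region discovery slides a probe-length window (default 18 nt) across the
alignment; a window qualifies if it contains at least `min_discriminative`
discriminative columns (default 1) and no column where any target record
is gapped (a probe cannot span a target gap). Overlapping or adjacent
qualifying windows merge into maximal regions, reported by ascending start
column. The merge rule — maximal runs of window-covered columns — makes
the output identical to the brute-force "enumerate every window, test the
predicate, union the columns" oracle, which the tests run on 100 random
panels and one 50 × 2000 panel. Lowering `min_discriminative` can only
grow the covered column set (superset monotonicity, tested).

The window-count predicate and its defaults are a declared convention: how
published probe-design studies delimit their "regions exhibiting
polymorphisms" is typically manual and unreported, so the package makes
the rule explicit and configurable rather than pretending to infer one.

## Probe construction and physical properties

`probe_from_site` requires the target group to be monomorphic and ungapped
over the entire site (offending columns are listed in the error), takes
the target consensus as the sense sequence and stores its reverse
complement — the oligonucleotide actually synthesized — as the probe.
Default enumeration constraints: length 18, GC fraction 0.40–0.65,
homopolymer runs ≤ 4. These are standard oligo-design heuristics, not
values with any deeper provenance, and are fully overridable.

Melting temperature uses the empirical salt/formamide-corrected formula
`Tm = 81.5 + 16.6·log10([Na+]) + 0.41·%GC − 675/L − 0.62·%formamide`,
evaluated by default at 0.9 M Na+ and 30% formamide (a standard FISH
hybridization buffer). The formula is linear in its corrections, so the
tests pin one hand-evaluated point (20-mer, 50% GC, 0.9 M Na+, 0%
formamide → 67.49 °C), the exact −0.62 °C/% formamide slope, and
monotonicity in GC and salt. Nearest-neighbor Tm models are out of scope
on purpose: for ranking same-length probes under one buffer the empirical
formula's ordering is what matters.

Anti-sense controls (`AS-<name>`) are the reverse complement of a sense
probe: they carry the target-site *sense* sequence and therefore cannot
base-pair with the rRNA — the standard negative control for non-specific
binding. Controls cannot be chained.

## Specificity, calls and screening

The specificity matrix stores a `MismatchProfile` for every probe × panel
sequence: mismatch count, probe-local substitution positions, and
gap-induced mismatches. The per-probe **off-target floor**
(`min_offtarget`) is the minimum count over all `non_target` and
`outgroup` records.

Per-taxon calls aggregate multiple sequences of one taxon by the
**minimum** mismatch count — the most permissive reading, since any
matching strain can produce signal — and map counts to calls with
thresholds 0 → `positive`, 1 → `weak`, ≥2 → `negative`. The `weak` band at
exactly one mismatch reflects the empirical observation that a single SNP
sometimes still yields faint signal; because mismatch position and
identity are not modeled, a 1-SNP `weak` call is a conservative flag that
may over-predict binding for terminal or destabilizing mismatches, and
reports should treat it as "test in vitro", not "will bind". Raising the
positive threshold can only grow the predicted-positive set (tested).

`screen_collection` is the in-silico specificity screen: every window of
probe length in every subject is compared exhaustively (vectorized
Hamming distance; no indels, no seeding heuristics), so results are
deterministic and provably identical to a naive double loop — the tests
check 50 random probe/subject pairs. The orientation contract follows
hybridization chemistry: a sense-strand (`+`) hit is a window matching the
probe's *site-sense* sequence (its reverse complement); consequently a
probe's own anti-sense control hits nothing in sense-only mode, and a
`both_strands` option additionally reports windows matching the probe
verbatim (`-`, binding the reverse strand of double-stranded subjects).
With budget 0 the screen reduces to exact substring search.

## Accessibility and ranking

Accessibility uses the field's empirical brightness classes I (brightest)
to VI, supplied as a TSV of non-overlapping intervals on the map's own
reference (the packaged `toy_accessibility.tsv` is synthetic and
illustrates the format only — real analyses must supply a published class
map). A probe's score is the multiset of classes over its site positions,
translated through an optional coordinate map; the worst (highest) class
governs, the mean class rank refines, and unmapped positions are
`unknown`, ranked after class VI.

Ranking is lexicographic — descending off-target floor, ascending worst
accessibility class, ascending |Tm − target Tm| (default working
temperature 57 °C), name — because no principled weights exist for
trading specificity against brightness; a weighted scalar mode is
available for exploration. A `specific` badge marks probes with floor ≥ 1.
The order is a total order and permutation-invariant (tested against a
brute-force sort).

## Detection-survey tabulation

`tabulate` turns a long-format (site, species, n_analyzed, n_positive)
table into per-site, per-species and overall totals. Percentages are
integer **round-half-up** (via `decimal`, so 12.5 → 13, 16.7 → 17,
42.9 → 43 — the convention that reproduces published survey tables;
banker's rounding would not), with configurable precision; 0/0 renders as
`NA`, never 0. The packaged fixture table encodes a 100-sample,
three-site truffle detection survey; its per-site positive-species counts
are exact, and per-species analyzed counts were reconstructed to be
jointly consistent with the published site totals and species
percentages (species never found positive are aggregated per site as
"other species", since their full breakdown is supplementary-only).

## Synthetic panels and what they do (not) show

`simulate_panel` builds gapless SSU-like alignments: a random reference
(uniform base composition), a monomorphic target clade, and per-clade
i.i.d. substitutions — clade members are identical; there is no
phylogenetic correlation, rate heterogeneity, indel realism or base-
composition skew. Background divergence defaults to 0.01/site for
non-target clades and 0.05/site for outgroups, realistic orders for SSU
within a family vs. across orders. Planted sites override the background:
exactly the named clades differ there, by a fixed transition base, and
planting the base the target already carries is recorded as a no-op. All
randomness flows through one integer-only numpy generator, so panels are
byte-reproducible across platforms for a fixed seed, and a generation-time
self-check asserts the emitted residues equal the truth bookkeeping.

The `paper-like` preset instantiates the reference scenario used by the
test-suite and acceptance script: a 1800-nt reference, one target taxon
(3 sequences), four in-family relatives, two outgroups (12 sequences
total), and four planted 18-nt probe windows starting at positions 185,
645, 1313 and 1647 whose planted mismatch patterns give a graded
specificity series — floors 1 (strictly specific at one SNP), 0
(pan-genus: all relatives exact, outgroups at ≥3), 0/1 (one relative
exact, another at a single SNP) and 3 (strictly specific at three SNPs),
with outgroups never within two mismatches of any probe. The preset plants
*all* inter-clade variation (zero background divergence) so that region
discovery must recover exactly the four planted windows and every reported
number is a deterministic function of the construction; the cost is that
the preset exercises discrimination logic, not robustness to background
noise, which the generic simulator covers separately. Passing these tests
shows the pipeline's bookkeeping is exact on known truth; it does not show
that real probes with these floors will behave in fixed tissue, where
accessibility, mismatch position and cell physiology intervene.

## Numerical and degenerate-input choices

- Ties in region merging: adjacent covered runs merge; regions report by
  ascending start. Probe enumeration orders by (target_start, length).
- `min_offtarget` on a panel without off-target records is a configuration
  error, not 0 or infinity.
- Empty accessibility maps are legal; every score becomes `unknown`.
- An all-gap record yields an empty coordinate map plus a warning; ragged
  alignments and duplicate ids fail fast with the offending id named.
- Screening requires `max_mismatches < probe length`; subjects shorter
  than the probe are skipped with a warning.
- CLI outputs carry `#` metadata headers; the timestamp line is
  suppressible (`--no-timestamp`) so identical runs are byte-identical.

## Problem sizes

The shipped tests and the acceptance script run at the scale the methods
target in practice: panels of 12–50 sequences and 1.8–2 kb alignments,
100-panel oracle sweeps at 40–400 columns, and 50 random screening pairs
against ≤ 500-nt subjects — seconds of wall time in total, chosen because
the planted-truth checks are exact at any size and larger inputs add no
discriminating power.
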