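"""Mismatch profiles, specificity matrices, spectra and exhaustive screening."""

import numpy as np
import pytest

from probespectrum.errors import ConfigurationError, CoordinateError, InputError
from probespectrum.probe_design import Probe, probe_from_site
from probespectrum.seq_io import build_coordinate_map
from probespectrum.specificity import (
    CallThresholds,
    min_offtarget_distance,
    mismatch_profile,
    predict_spectrum,
    screen_collection,
    specificity_matrix,
)

from conftest import make_panel, naive_revcomp, naive_screen


def two_seq_panel(target_seq, other_seq, other_group="non_target"):
    return make_panel([("t", target_seq, "target_taxon", "target"),
                       ("n", other_seq, "other_taxon", other_group)])


class TestMismatchProfile:
    def test_identity_gives_zero(self, bundle):
        cmap = build_coordinate_map(bundle.panel, bundle.panel.reference_id)
        for probe in bundle.probes:
            profile = mismatch_profile(probe, bundle.panel.reference, cmap)
            assert profile.n_mismatches == 0 and not profile.has_gap

    def test_substitutions_counted_with_positions(self):
        panel = two_seq_panel("ACGTACGTAC", "ACCTACGAAC")  # diffs at 3 and 8
        probe = probe_from_site(panel, start=1, length=10)
        cmap = build_coordinate_map(panel, "t")
        profile = mismatch_profile(probe, panel.get("n"), cmap)
        assert profile.n_mismatches == 2
        assert profile.mismatch_positions == (3, 8)

    def test_gap_counts_as_mismatch_and_flags(self):
        panel = two_seq_panel("ACGTACGTAC", "ACGT-CGTAC")
        probe = probe_from_site(panel, start=1, length=10)
        cmap = build_coordinate_map(panel, "t")
        profile = mismatch_profile(probe, panel.get("n"), cmap)
        assert profile.n_mismatches == 1
        assert profile.has_gap and profile.mismatch_positions == ()

    def test_ambiguity_containment(self):
        # R = A/G matches expected A; Y = C/T does not
        panel = two_seq_panel("AAAAAAAAAA", "RAAAAYAAAA")
        probe = probe_from_site(panel, start=1, length=10)
        cmap = build_coordinate_map(panel, "t")
        profile = mismatch_profile(probe, panel.get("n"), cmap)
        assert profile.mismatch_positions == (6,)

    def test_site_outside_alignment_errors(self):
        panel = two_seq_panel("ACGTACGTAC", "ACGTACGTAC")
        cmap = build_coordinate_map(panel, "t")
        probe = Probe(name="far", sequence="ACGTACGTAC",
                      target_start=5, target_end=14)
        with pytest.raises(CoordinateError):
            mismatch_profile(probe, panel.get("n"), cmap)

    def test_bundle_counts_equal_truth(self, bundle):
        """Pipeline mismatch counts equal the generator's planted bookkeeping."""
        matrix = specificity_matrix(bundle.probes, bundle.panel)
        for probe in bundle.probes:
            for rec in bundle.panel:
                expected = bundle.truth.expected_mismatches(
                    rec.taxon, probe.target_start, probe.target_end
                )
                assert matrix.profile(probe.name, rec.id).n_mismatches == expected


class TestSpecificityMatrix:
    def test_complete_and_consistent(self, bundle):
        matrix = specificity_matrix(bundle.probes, bundle.panel)
        assert len(matrix.profiles) == len(bundle.probes) * len(bundle.panel)
        for probe in bundle.probes:
            offs = bundle.panel.offtarget_records
            brute = min(matrix.profile(probe.name, r.id).n_mismatches
                        for r in offs)
            assert matrix.min_offtarget(probe.name) == brute

    def test_min_offtarget_distance_examples(self, bundle):
        by_start = {p.target_start: p for p in bundle.probes}
        assert min_offtarget_distance(by_start[185], bundle.panel) == 1
        assert min_offtarget_distance(by_start[1647], bundle.panel) == 3

    def test_probe_equal_to_offtarget_window_gives_zero(self):
        panel = two_seq_panel("ACGTACGTAC", "ACGTACGTAC")
        probe = probe_from_site(panel, start=1, length=10)
        assert min_offtarget_distance(probe, panel) == 0

    def test_no_offtargets_is_configuration_error(self):
        panel = make_panel([("t", "ACGTACGTAC", "t", "target")])
        probe = probe_from_site(panel, start=1, length=10)
        with pytest.raises(ConfigurationError):
            min_offtarget_distance(probe, panel)

    def test_random_panels_match_brute_force(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        for _ in range(20):
            length = int(rng.integers(25, 60))
            t = "".join(bases[i] for i in rng.integers(0, 4, length))
            rows = [("t", t, "t", "target")]
            seqs = []
            for j in range(int(rng.integers(1, 5))):
                s = list(t)
                for i in np.nonzero(rng.integers(0, 10, length) == 0)[0]:
                    s[i] = bases[(bases.index(s[i]) + 1) % 4]
                seqs.append("".join(s))
                rows.append((f"n{j}", seqs[-1], f"n{j}", "non_target"))
            panel = make_panel(rows)
            start = int(rng.integers(1, length - 17))
            probe = probe_from_site(panel, start=start, length=18)
            brute = min(
                sum(1 for a, b in zip(t[start - 1 : start + 17],
                                      s[start - 1 : start + 17]) if a != b)
                for s in seqs
            )
            assert min_offtarget_distance(probe, panel) == brute


class TestPredictSpectrum:
    def test_threshold_calls(self, bundle):
        matrix = specificity_matrix(bundle.probes, bundle.panel)
        calls = {(p.probe_name, p.taxon): p.call
                 for p in predict_spectrum(matrix)}
        # pan-genus probe: positive across relatives, negative on outgroups
        for taxon in ("T_borchii_analog", "T_aestivum_analog",
                      "T_brumale_analog", "Choiromyces_analog"):
            assert calls[("T.ana645", taxon)] == "positive"
        for taxon in ("M_eximia_analog", "D_leucomelaena_analog"):
            assert calls[("T.ana645", taxon)] == "negative"
        # narrow probe: one relative exact, one at a single SNP
        assert calls[("T.ana1313", "T_borchii_analog")] == "positive"
        assert calls[("T.ana1313", "T_aestivum_analog")] == "weak"
        assert calls[("T.ana1313", "T_brumale_analog")] == "negative"

    def test_two_mismatches_everywhere_is_all_negative(self, bundle):
        matrix = specificity_matrix([p for p in bundle.probes
                                     if p.name == "T.ana1647"], bundle.panel)
        for pred in predict_spectrum(matrix):
            if pred.taxon != "T_magnatum_analog":
                assert pred.call == "negative"

    def test_target_taxa_always_positive(self, bundle):
        matrix = specificity_matrix(bundle.probes, bundle.panel)
        for pred in predict_spectrum(matrix):
            if pred.taxon == "T_magnatum_analog":
                assert pred.call == "positive" and pred.min_mismatches == 0

    def test_taxon_aggregation_uses_minimum(self):
        panel = make_panel([
            ("t", "ACGTACGTAC", "t", "target"),
            ("n1", "ACGTACGTAC", "same_taxon", "non_target"),
            ("n2", "AGGTAGGTAC", "same_taxon", "non_target"),
        ])
        probe = probe_from_site(panel, start=1, length=10)
        matrix = specificity_matrix([probe], panel)
        (pred,) = [p for p in predict_spectrum(matrix) if p.taxon == "same_taxon"]
        assert pred.min_mismatches == 0 and pred.call == "positive"

    @pytest.mark.parametrize("relaxed_max", [1, 2, 3])
    def test_positive_set_grows_under_threshold_relaxation(self, bundle,
                                                           relaxed_max):
        matrix = specificity_matrix(bundle.probes, bundle.panel)
        strict = {(p.probe_name, p.taxon)
                  for p in predict_spectrum(matrix, CallThresholds(0, 1))
                  if p.call == "positive"}
        relaxed = {(p.probe_name, p.taxon)
                   for p in predict_spectrum(
                       matrix, CallThresholds(relaxed_max, relaxed_max + 1))
                   if p.call == "positive"}
        assert strict <= relaxed


class TestScreenCollection:
    def make_probe(self, sequence):
        return Probe(name="q", sequence=sequence, target_start=1,
                     target_end=len(sequence))

    def test_planted_reverse_complement_found_once(self):
        rng = np.random.default_rng(42)
        bases = "ACGT"
        subject = list(bases[i] for i in rng.integers(0, 4, 1000))
        probe_seq = "TGCAATCGTTAGCCGATA"
        subject[100:118] = naive_revcomp(probe_seq)  # window starts at 101
        subject = "".join(subject)
        hits = screen_collection(self.make_probe(probe_seq),
                                 [("s", subject)], max_mismatches=0)
        assert [(h.subject_start, h.n_mismatches) for h in hits] == [(101, 0)]
        assert hits[0].strand == "+"

    def test_zero_budget_equals_exact_substring_search(self):
        rng = np.random.default_rng(9)
        bases = "ACGT"
        subject = "".join(bases[i] for i in rng.integers(0, 4, 500))
        probe = self.make_probe("ACGTACGTACGTACGTAC")
        pattern = naive_revcomp(probe.sequence)
        expected = sorted(
            i + 1 for i in range(len(subject) - len(pattern) + 1)
            if subject[i : i + len(pattern)] == pattern
        )
        hits = screen_collection(probe, [("s", subject)], 0)
        assert [h.subject_start for h in hits] == expected

    def test_short_subject_skipped_with_warning(self, caplog):
        probe = self.make_probe("ACGTACGTACGTACGTAC")
        with caplog.at_level("WARNING", logger="probespectrum"):
            hits = screen_collection(probe, [("tiny", "ACGT")], 2)
        assert hits == []
        assert any("tiny" in rec.message for rec in caplog.records)

    def test_budget_must_be_below_probe_length(self):
        probe = self.make_probe("ACGT")
        with pytest.raises(InputError):
            screen_collection(probe, [("s", "ACGTACGT")], 4)

    def test_both_strands_mode_reports_minus_hits(self):
        probe = self.make_probe("TGCAATCGTTAGCCGATA")
        subject = "CCCC" + probe.sequence + "CCCC"  # probe verbatim: '-' hit
        assert screen_collection(probe, [("s", subject)], 0) == []
        hits = screen_collection(probe, [("s", subject)], 0, both_strands=True)
        assert [(h.subject_start, h.strand) for h in hits] == [(5, "-")]

    def test_fifty_random_pairs_match_naive_oracle(self):
        rng = np.random.default_rng(123)
        bases = "ACGT"
        for _ in range(50):
            m = int(rng.integers(12, 25))
            probe_seq = "".join(bases[i] for i in rng.integers(0, 4, m))
            subject = "".join(bases[i] for i in rng.integers(0, 4,
                                                             rng.integers(m, 400)))
            max_mm = int(rng.integers(0, min(m, 7)))
            probe = self.make_probe(probe_seq)
            got = [(h.subject_start, h.n_mismatches)
                   for h in screen_collection(probe, [("s", subject)], max_mm)]
            assert got == naive_screen(naive_revcomp(probe_seq), subject, max_mm)
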