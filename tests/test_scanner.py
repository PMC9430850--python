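import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ntcascan.genome import AnnotatedGenome, GeneFeature, reverse_complement
from ntcascan.scanner import (
    DEFAULT_ARCHITECTURE,
    MotifArchitecture,
    attach_minus10,
    build_consensus,
    find_dyads,
    mismatch_descriptor,
    scan_upstream,
)
from ntcascan.sites import REPORTED_SITES

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


def naive_dyad_windows(seq: str, arch: MotifArchitecture):
    """Brute-force oracle: enumerate every window on both strands and
    count arm mismatches position by position."""
    w = arch.dyad_length
    out = set()
    for i in range(len(seq) - w + 1):
        for strand in "+-":
            window = seq[i : i + w]
            if strand == "-":
                window = reverse_complement(window)
            mm5 = sum(
                1 for a, b in zip(window[:3], arch.arm5) if a != b
            )
            mm3 = sum(
                1 for a, b in zip(window[-3:], arch.arm3) if a != b
            )
            if mm5 <= arch.max_mismatch_per_arm and mm3 <= arch.max_mismatch_per_arm:
                out.add((i + 1, strand, mm5, mm3))
    return out


def as_tuples(hits):
    return {(h.start, h.strand, h.arm5_mismatches, h.arm3_mismatches) for h in hits}


class TestFindDyads:
    def test_reported_canonical_dyad_has_plus_hit_without_arm_changes(self):
        hits = [h for h in find_dyads("GTAACAACGGCTAC") if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].arm_mismatches == ()

    def test_reported_single_arm_deviation_annotated(self):
        hits = [h for h in find_dyads("GTAGCGATTGCAAC") if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].arm_mismatches == ("TAC changed to AAC",)

    def test_poly_a_has_no_hits(self):
        assert find_dyads("A" * 20) == []

    def test_perfect_site_is_detected_on_both_strands(self):
        # GTA-N8-TAC is its own reverse complement
        hits = find_dyads("GTAACAACGGCTAC")
        assert {h.strand for h in hits} == {"+", "-"}
        assert len({h.start for h in hits}) == 1

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            find_dyads("GTAACAACGGCTAX")

    def test_n_bases_never_match(self):
        assert all(
            h.strand == "-" or h.arm5_mismatches == 1
            for h in find_dyads("NTAACAACGGCTAC")
        )

    @given(dna)
    def test_matches_bruteforce_oracle(self, seq):
        assert as_tuples(find_dyads(seq)) == naive_dyad_windows(
            seq, DEFAULT_ARCHITECTURE
        )

    @given(dna)
    def test_strand_symmetry(self, seq):
        fwd = as_tuples(find_dyads(seq))
        rev = as_tuples(find_dyads(reverse_complement(seq)))
        n = len(seq)
        w = DEFAULT_ARCHITECTURE.dyad_length
        mirrored = {
            (n - w + 2 - s, "+" if strand == "-" else "-", m5, m3)
            for s, strand, m5, m3 in rev
        }
        assert fwd == mirrored

    @given(dna)
    def test_enlarging_budgets_never_removes_hits(self, seq):
        tight = MotifArchitecture(max_mismatch_per_arm=0)
        loose = MotifArchitecture(max_mismatch_per_arm=2)
        assert {(h.start, h.strand) for h in find_dyads(seq, tight)} <= {
            (h.start, h.strand) for h in find_dyads(seq, loose)
        }


class TestMismatchDescriptor:
    def test_both_arms_changed_uses_respectively_form(self):
        assert (
            mismatch_descriptor("GTGACCTACCTCAC", "dyad")
            == "GTA and TAC changed to GTG and CAC, respectively"
        )

    def test_minus10_keeps_unconstrained_positions_as_n(self):
        assert (
            mismatch_descriptor("AAAACT", "minus10")
            == "TAN_3_T changed to AAN_3_T"
        )

    def test_exact_elements_have_empty_descriptor(self):
        assert mismatch_descriptor("GTAACAACGGCTAC", "dyad") == ""
        assert mismatch_descriptor("TACGGT", "minus10") == ""

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_descriptor("GTA", "dyad")


class TestAttachMinus10:
    def _dyad_hit(self, seq):
        return [h for h in find_dyads(seq) if h.strand == "+" and h.start == 1][0]

    def test_reported_site_attaches_at_printed_linker(self):
        seq = "GTAGCGATTGCAAC" + "A" * 22 + "TGCAAT"
        hit = attach_minus10(self._dyad_hit(seq), seq)
        assert hit.minus10 is not None
        assert hit.minus10.linker_length == 22
        assert hit.minus10.descriptor == "TAN_3_T changed to TGN_3_T"

    def test_out_of_range_linker_is_not_attached(self):
        seq = "GTAACAACGGCTAC" + "G" * 30 + "TAAAAT"
        assert attach_minus10(self._dyad_hit(seq), seq).minus10 is None

    def test_perfect_box_in_range_attaches_with_zero_mismatches(self):
        seq = "GTAACAACGGCTAC" + "G" * 22 + "TAAAAT"
        hit = attach_minus10(self._dyad_hit(seq), seq)
        assert hit.minus10.mismatches == 0 and hit.minus10.linker_length == 22

    def test_fewest_mismatches_wins_over_shorter_linker(self):
        # 1-mismatch candidate at linker 21, perfect box at linker 24
        seq = "GTAACAACGGCTAC" + "G" * 21 + "TAG" + "TAAAAT"
        hit = attach_minus10(self._dyad_hit(seq), seq)
        assert hit.minus10.mismatches == 0 and hit.minus10.linker_length == 24

    def test_minus_strand_box_read_on_hit_strand(self):
        fwd = "GTAGCGATTGCAAC" + "A" * 22 + "TGCAAT"
        seq = reverse_complement(fwd)
        hit = [
            h
            for h in find_dyads(seq)
            if h.strand == "-" and h.dyad_sequence == "GTAGCGATTGCAAC"
        ][0]
        hit = attach_minus10(hit, seq)
        assert hit.minus10 is not None and hit.minus10.sequence == "TGCAAT"


class TestScanUpstream:
    def _planted_genome(self, distance=125):
        element = "GTAACAACGGCTAC" + "G" * 22 + "TAAAAT"
        upstream = "A" * (300 - distance - len(element)) + element + "C" * distance
        seq = upstream + "ATG" + "CAGTTT" * 50
        return AnnotatedGenome(
            "p", seq, [GeneFeature("target", 301, 601, "+")]
        )

    def test_planted_element_end_distance(self):
        hits = scan_upstream(self._planted_genome(125), "target")
        ours = [h for h in hits if h.minus10 is not None and h.strand == "+"]
        assert any(h.gene.distance_upstream_end == 125 for h in ours)

    def test_background_without_sites_yields_nothing_under_strict_budgets(self):
        # A/T-skewed background cannot contain the G/C-bearing arms;
        # brute-force enumeration of all windows agrees
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("AT"), size=400))
        g = AnnotatedGenome("bg", seq + "ATGAAATTTTAG", [GeneFeature("x", 401, 412, "+")])
        strict = MotifArchitecture(max_mismatch_per_arm=0, minus10_required=True)
        assert scan_upstream(g, "x", strict, window=300) == []
        assert naive_dyad_windows(seq, MotifArchitecture(max_mismatch_per_arm=0)) == set()

    def test_coordinates_mapped_to_contig_for_minus_strand_gene(self):
        g_plus = self._planted_genome(80)
        seq_rc = reverse_complement(g_plus.sequence)
        n = len(seq_rc)
        feat = g_plus.features[0]
        g_minus = AnnotatedGenome(
            "m", seq_rc, [GeneFeature("target", n - feat.end + 1, n - feat.start + 1, "-")]
        )
        d_plus = {
            (h.gene.distance_upstream_end, h.dyad_sequence)
            for h in scan_upstream(g_plus, "target")
        }
        d_minus = {
            (h.gene.distance_upstream_end, h.dyad_sequence)
            for h in scan_upstream(g_minus, "target")
        }
        assert d_plus == d_minus

    def test_window_shorter_than_dyad_rejected(self):
        with pytest.raises(ValueError):
            scan_upstream(self._planted_genome(), "target", window=10)


class TestConsensus:
    def test_reported_dyads_tally(self):
        # hand tally over the printed 14-mers: all start G,T and end A,C
        hits = [
            h
            for site in REPORTED_SITES
            for h in find_dyads(site.dyad)
            if h.strand == "+" and h.start == 1
        ]
        summary = build_consensus(hits)
        assert summary.n_sites == len(REPORTED_SITES) == 8
        cons = summary.dyad_consensus
        assert cons[:2] == "GT" and cons[12:] == "AC"
        assert summary.dyad_counts[0] == {"G": 8}
        assert summary.dyad_counts[2] == {"A": 3, "G": 2, "T": 2, "C": 1}

    def test_single_site_consensus_is_itself(self):
        hits = [h for h in find_dyads("GTAGCGATTGCAAC") if h.strand == "+"]
        assert build_consensus(hits).dyad_consensus == "GTAGCGATTGCAAC"

    def test_two_site_tie_yields_iupac_code(self):
        hits = [
            h
            for s in ("GTAACAACGGCTAC", "GTGACAACGGCTAC")
            for h in find_dyads(s)
            if h.strand == "+"
        ]
        # position 3 is A in one site, G in the other -> R
        assert build_consensus(hits).dyad_consensus[2] == "R"

    def test_counts_sum_to_n_sites(self):
        hits = find_dyads("GTAACAACGGCTACGTAGCGATTGCAAC")
        summary = build_consensus(hits)
        for counts in summary.dyad_counts:
            assert sum(counts.values()) == summary.n_sites

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestReportedSiteFidelity:
    """Every printed site must pass the default budgets and reproduce its
    printed deviation annotation exactly."""

    @pytest.mark.parametrize(
        "site", REPORTED_SITES, ids=[f"{s.gene}_{s.distance}" for s in REPORTED_SITES]
    )
    def test_dyad_within_budgets_and_notation_exact(self, site):
        hits = [h for h in find_dyads(site.dyad) if h.strand == "+" and h.start == 1]
        assert hits, "printed dyad rejected by default budgets"
        assert mismatch_descriptor(site.dyad, "dyad") == site.dyad_note

    @pytest.mark.parametrize(
        "site",
        [s for s in REPORTED_SITES if s.minus10 is not None],
        ids=[f"{s.gene}_{s.distance}" for s in REPORTED_SITES if s.minus10 is not None],
    )
    def test_minus10_within_budget_and_notation_exact(self, site):
        seq = site.dyad + "A" * site.linker + site.minus10
        hit = [h for h in find_dyads(seq) if h.strand == "+" and h.start == 1][0]
        hit = attach_minus10(hit, seq)
        assert hit.minus10 is not None
        assert hit.minus10.linker_length == site.linker
        assert hit.minus10.descriptor == site.minus10_note

    def test_combined_descriptor_matches_printed_phrasing(self):
        site = REPORTED_SITES[2]  # both arms + box deviate
        seq = site.dyad + "A" * site.linker + site.minus10
        hit = [h for h in find_dyads(seq) if h.strand == "+" and h.start == 1][0]
        hit = attach_minus10(hit, seq)
        assert hit.descriptor == (
            "GTA and TAC changed to GTG and CAC, respectively, "
            "and TAN_3_T changed to TTN_3_T"
        )
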