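"""Control-region domains, motif search and tandem repeats."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitokit.annotation_io import extract_feature_sequence
from mitokit.control_region import (
    REPORTABLE_SPAN,
    DomainPartition,
    find_motif,
    find_tandem_repeats,
    load_motif_config,
    partition_cr,
    scan_motifs,
    variable_site_proportion,
)

POLY_C = "CCCCCCCCCCTTCCCCCCCC"


class TestVariableSiteProportion:
    def test_identical_sequences_zero(self):
        assert variable_site_proportion(["ACGT", "ACGT"]) == 0.0

    def test_one_of_four_columns(self):
        assert variable_site_proportion(["ACGT", "ACGA"]) == 25.0

    def test_gap_only_columns_excluded_from_denominator(self):
        # column 2 is all gaps; of the 3 comparable columns 1 varies
        aln = ["AC-T", "AC-A"]
        assert variable_site_proportion(aln) == pytest.approx(100 / 3)

    def test_all_columns_denominator_option(self):
        aln = ["AC-T", "AC-A"]
        assert variable_site_proportion(aln, denominator="all") == 25.0

    def test_single_residue_column_not_comparable(self):
        aln = ["A-", "AC"]
        assert variable_site_proportion(aln) == 0.0

    def test_permutation_invariance_and_monotonicity(self):
        aln = ["ACGTACGT", "ACGTACGA", "ACCTACGA"]
        for perm in itertools.permutations(aln):
            assert variable_site_proportion(list(perm)) == \
                variable_site_proportion(aln)
        divergent = "TTTTTTTT"
        assert variable_site_proportion(aln + [divergent]) >= \
            variable_site_proportion(aln)

    def test_interval_restriction(self):
        aln = ["AAAA", "AAAT"]
        assert variable_site_proportion(aln, interval=(0, 2)) == 0.0
        assert variable_site_proportion(aln, interval=(2, 4)) == 50.0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            variable_site_proportion(["ACG", "AC"])


class TestFindMotif:
    def test_poly_c_exact(self):
        seq = "AT" * 10 + POLY_C + "GG" * 10
        hits = find_motif(seq, POLY_C, 0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].mismatches) == (20, 0)

    def test_overlapping_hits(self):
        hits = find_motif("ACAC", "AC", 0)
        assert [h.start for h in hits] == [0, 2]

    def test_iupac_codes(self):
        assert find_motif("ACGT", "AYGT", 0)  # Y matches C
        assert find_motif("ATGT", "AYGT", 0)  # and T
        assert not find_motif("AGGT", "AYGT", 0)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=40),
           st.text(alphabet="ACGT", min_size=2, max_size=5))
    def test_mismatch_monotonicity_and_naive_scan(self, seq, pattern):
        h0 = {h.start for h in find_motif(seq, pattern, 0)}
        h1 = {h.start for h in find_motif(seq, pattern, 1)}
        assert h0 <= h1
        naive = {i for i in range(len(seq) - len(pattern) + 1)
                 if seq[i:i + len(pattern)] == pattern}
        assert h0 == naive

    def test_pattern_longer_than_sequence(self):
        assert find_motif("AC", "ACGT", 2) == []

    def test_empty_pattern_is_error(self):
        with pytest.raises(ValueError):
            find_motif("ACGT", "", 0)


class TestPartitionCR:
    def test_explicit_boundaries_verbatim(self):
        part = partition_cr("A" * 1250, boundaries=(0, 400, 900, 1250))
        assert part.as_dict() == {"I": (0, 400), "II": (400, 900),
                                  "III": (900, 1250)}

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(ValueError):
            DomainPartition((0, 500), (400, 900), (900, 1250))

    def test_anchor_mode_recovers_implant_positions(self, genome, truth):
        cr = extract_feature_sequence(genome, genome.get("CR"))
        part = partition_cr(cr, anchors=True)
        b = truth["genes"]["CR"]["domain_boundaries"]
        assert part.as_dict() == {"I": (b[0], b[1]), "II": (b[1], b[2]),
                                  "III": (b[2], b[3])}

    def test_missing_anchor_is_error(self):
        with pytest.raises(ValueError, match="not found"):
            partition_cr("AT" * 300, anchors=True)

    def test_poly_c_found_in_domain_i_near_5_prime(self, genome, truth):
        cr = extract_feature_sequence(genome, genome.get("CR"))
        scan = scan_motifs(cr).set_index("motif")
        hit = scan.loc["poly_C"]
        assert hit["found"] and hit["mismatches"] == 0
        assert hit["start"] == truth["genes"]["CR"]["motifs"]["poly_C"]["start"]
        assert hit["start"] < truth["genes"]["CR"]["domain_boundaries"][1]

    def test_all_boxes_and_csb1_recovered(self, genome, truth):
        cr = extract_feature_sequence(genome, genome.get("CR"))
        scan = scan_motifs(cr).set_index("motif")
        for name, info in truth["genes"]["CR"]["motifs"].items():
            assert scan.loc[name, "found"]
            assert scan.loc[name, "start"] == info["start"]

    def test_config_round_trip(self, tmp_path):
        default = load_motif_config()
        p = tmp_path / "m.tsv"
        p.write_text("\n".join(f"{n}\t{pat}\t{mm}" for n, pat, mm in default))
        assert load_motif_config(p) == default


def oracle_tandem_repeats(seq, min_unit=1, max_unit=None, min_copies=2.0):
    """Exhaustive pure-repeat oracle: test every (start, end, unit) triple
    for periodicity and maximality, then collapse covered larger units."""
    n = len(seq)
    max_unit = max_unit if max_unit is not None else n // 2
    found = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        for s in range(n):
            for e in range(s + u + 1, n + 1):
                if seq[s:e - u] != seq[s + u:e]:
                    continue
                left_max = s == 0 or seq[s - 1] != seq[s - 1 + u]
                right_max = e == n or seq[e] != seq[e - u]
                if left_max and right_max and (e - s) / u >= min_copies:
                    found.append((s, e, u))
    found = sorted(set(found), key=lambda t: (t[2], t[0]))
    kept = []
    for s, e, u in found:
        if not any(s2 <= s and e <= e2 and u2 < u for s2, e2, u2 in kept):
            kept.append((s, e, u))
    return sorted((s, e, u) for s, e, u in kept)


class TestTandemRepeats:
    def test_triple_acg(self):
        (rep,) = find_tandem_repeats("ACGACGACG", min_unit=3, min_copies=2,
                                     min_purity=1.0)
        assert (rep.unit, rep.copies) == ("ACG", 3.0)

    def test_homopolymer(self):
        (rep,) = find_tandem_repeats("CCCCCC", min_unit=1, min_purity=1.0)
        assert (rep.unit, rep.copies) == ("C", 6.0)

    def test_fractional_copies(self):
        (rep,) = find_tandem_repeats("ACGTACGTAC", min_unit=4, min_copies=2,
                                     min_purity=1.0)
        assert (rep.unit, rep.copies, rep.start, rep.end) == \
            ("ACGT", 2.5, 0, 10)

    def test_random_sequence_has_no_reportable_repeats(self):
        rng = random.Random(42)
        seq = "".join(rng.choice("ACGT") for _ in range(1000))
        assert find_tandem_repeats(seq, min_unit=5, min_copies=3,
                                   min_purity=1.0,
                                   min_length=REPORTABLE_SPAN) == []

    def test_planted_repeat_recovered_exactly(self, genome_with_repeat):
        rec, truth = genome_with_repeat
        cr = extract_feature_sequence(rec, rec.get("CR"))
        planted = truth["genes"]["CR"]["tandem_repeat"]
        hits = find_tandem_repeats(cr, min_purity=1.0,
                                   min_length=REPORTABLE_SPAN)
        assert len(hits) == 1
        rep = hits[0]
        assert (rep.unit, rep.copies, rep.start, rep.end) == (
            planted["unit"], planted["copies"], planted["start"],
            planted["end"])

    def test_clean_cr_has_no_reportable_repeats(self, genome):
        cr = extract_feature_sequence(genome, genome.get("CR"))
        assert find_tandem_repeats(cr, min_length=REPORTABLE_SPAN) == []

    def test_span_consistency_invariant(self, genome_with_repeat):
        rec, _ = genome_with_repeat
        cr = extract_feature_sequence(rec, rec.get("CR"))
        for rep in find_tandem_repeats(cr):
            assert rep.end - rep.start == pytest.approx(
                rep.unit_length * rep.copies)

    @pytest.mark.parametrize("length", range(1, 11))
    def test_matches_exhaustive_oracle_on_short_ac_strings(self, length):
        for bits in itertools.product("AC", repeat=length):
            seq = "".join(bits)
            got = sorted((r.start, r.end, r.unit_length)
                         for r in find_tandem_repeats(
                             seq, min_unit=1, min_copies=2, min_purity=1.0))
            assert got == oracle_tandem_repeats(seq), seq
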