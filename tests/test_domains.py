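"""Domain fragment assembly, length filters, multi-HMM resolution."""

from __future__ import annotations

import io

import pytest

from ssnclose import (
    DomainHit,
    assemble_all,
    assemble_fragments,
    extract_sequences,
    filter_hits,
    length_filter,
    parse_domtblout,
    resolve_multi_hmm,
)


def hit(seq_from, seq_to, hmm_from, hmm_to, seq_id="P1", hmm="GHX",
        hmm_length=200, i_evalue=1e-10):
    return DomainHit(seq_id, hmm, hmm_length, seq_from, seq_to, hmm_from, hmm_to, i_evalue)


class TestFilterHits:
    @pytest.mark.parametrize(
        "i_evalue, kept",
        [(1e-5, True), (1e-3, False), (1e-4, False), (0.0, True)],
    )
    def test_strict_cutoff(self, i_evalue, kept):
        hits = filter_hits([hit(1, 100, 1, 100, i_evalue=i_evalue)])
        assert bool(hits) is kept


class TestAssembleFragments:
    def test_merge_when_all_rules_pass(self):
        """Starts 149 apart, ends 150 apart, gap 50, profile overlap 6:
        one assembled domain spanning 1-250."""
        out = assemble_fragments([hit(1, 100, 1, 100), hit(150, 250, 95, 200)])
        assert len(out) == 1
        assert (out[0].seq_from, out[0].seq_to) == (1, 250)
        assert len(out[0].fragments) == 2

    def test_gap_over_200_splits(self):
        out = assemble_fragments([hit(1, 100, 1, 100), hit(360, 450, 95, 200)])
        assert len(out) == 2

    def test_hmm_overlap_over_30_splits(self):
        out = assemble_fragments([hit(1, 100, 1, 100), hit(150, 250, 55, 200)])
        assert len(out) == 2

    def test_near_duplicate_starts_split(self):
        # starts 15 apart: a re-alignment of the same region, not a new piece
        out = assemble_fragments([hit(1, 100, 1, 100), hit(16, 250, 95, 200)])
        assert len(out) == 2

    def test_near_duplicate_ends_split(self):
        # starts 104 apart but ends only 18 apart: rule i (ends) fails
        out = assemble_fragments([hit(1, 100, 1, 100), hit(105, 118, 95, 108)])
        assert len(out) == 2

    def test_overlapping_sequence_intervals_never_merge(self):
        out = assemble_fragments([hit(1, 100, 1, 100), hit(90, 250, 95, 200)])
        assert len(out) == 2

    def test_three_fragment_chain(self):
        out = assemble_fragments(
            [hit(1, 100, 1, 100), hit(150, 250, 95, 200), hit(300, 380, 195, 280, hmm_length=300)]
        )
        assert len(out) == 1
        assert out[0].seq_to == 380
        assert [f.seq_from for f in out[0].fragments] == [1, 150, 300]

    def test_unsorted_input_is_sorted_first(self):
        out = assemble_fragments([hit(150, 250, 95, 200), hit(1, 100, 1, 100)])
        assert len(out) == 1 and out[0].seq_from == 1

    def test_idempotent_on_single_fragments(self):
        once = assemble_fragments([hit(1, 100, 1, 100)])
        again = assemble_fragments(once[0].fragments)
        assert [(d.seq_from, d.seq_to) for d in once] == [
            (d.seq_from, d.seq_to) for d in again
        ]

    def test_rejects_mixed_groups(self):
        with pytest.raises(ValueError, match="one sequence and one HMM"):
            assemble_fragments([hit(1, 50, 1, 50), hit(60, 90, 40, 80, seq_id="P2")])

    def test_assemble_all_groups_by_seq_and_hmm(self):
        hits = [
            hit(1, 100, 1, 100, seq_id="A"),
            hit(150, 250, 95, 200, seq_id="A"),
            hit(1, 80, 1, 80, seq_id="B"),
            hit(1, 90, 1, 90, seq_id="A", hmm="GHY"),
        ]
        out = assemble_all(hits)
        keys = {(d.seq_id, d.hmm_name) for d in out}
        assert keys == {("A", "GHX"), ("B", "GHX"), ("A", "GHY")}
        assert len(out) == 3

    def test_coordinate_invariants(self):
        out = assemble_all(
            [hit(1, 100, 1, 100), hit(150, 250, 95, 200), hit(900, 950, 1, 60)]
        )
        for d in out:
            assert d.seq_from == d.fragments[0].seq_from
            assert d.seq_to == d.fragments[-1].seq_to
            froms = [f.seq_from for f in d.fragments]
            hmm_froms = [f.hmm_from for f in d.fragments]
            assert froms == sorted(froms)
            assert hmm_froms == sorted(hmm_froms)

    def test_coordinate_validation(self):
        with pytest.raises(ValueError):
            hit(100, 50, 1, 60)
        with pytest.raises(ValueError):
            hit(1, 50, 0, 60)


class TestLengthFilter:
    def test_half_length_discard_is_strict(self):
        domains = [
            assemble_fragments([hit(1, 99, 1, 99)])[0],   # length 99 < 100
            assemble_fragments([hit(1, 100, 1, 100)])[0],  # length 100: kept
        ]
        out = length_filter(domains, {"GHX": 200})
        assert out[0].length_flag == "short_discarded"
        assert out[1].length_flag != "short_discarded"

    def test_outliers_flagged_against_retained_population(self):
        lengths = [195 + i for i in range(11)]  # 195..205, mean 200, sd ~3.3
        domains = [assemble_fragments([hit(1, L, 1, 150)])[0] for L in lengths]
        domains.append(assemble_fragments([hit(1, 600, 1, 150)])[0])
        out = length_filter(domains, {"GHX": 200})
        flags = [d.length_flag for d in out]
        assert flags[:-1] == ["ok"] * 11
        assert flags[-1] == "outlier_flagged"

    def test_outlier_is_kept_not_discarded(self):
        domains = [assemble_fragments([hit(1, L, 1, 150)])[0] for L in (200,) * 10 + (201, 600)]
        out = length_filter(domains, {"GHX": 200})
        assert sum(d.length_flag == "outlier_flagged" for d in out) == 1
        assert all(d.length_flag != "short_discarded" for d in out)


class TestResolveMultiHmm:
    def test_longer_domain_wins(self):
        a = assemble_fragments([hit(1, 210, 1, 200, hmm="H1")])[0]
        b = assemble_fragments([hit(1, 180, 1, 170, hmm="H2")])[0]
        best = resolve_multi_hmm([a, b], ["H1", "H2"])
        assert best["P1"].hmm_name == "H1"
        best2 = resolve_multi_hmm([b, a], ["H2", "H1"])
        assert best2["P1"].hmm_name == "H1"

    def test_single_hmm_passthrough(self):
        a = assemble_fragments([hit(1, 210, 1, 200, hmm="H1")])[0]
        assert resolve_multi_hmm([a], ["H1", "H2"])["P1"] is a

    def test_tie_goes_to_first_configured_hmm_and_is_logged(self):
        a = assemble_fragments([hit(1, 200, 1, 190, hmm="H1")])[0]
        b = assemble_fragments([hit(11, 210, 1, 190, hmm="H2")])[0]
        log: list[str] = []
        best = resolve_multi_hmm([b, a], ["H2", "H1"], log=log)
        assert best["P1"].hmm_name == "H2"
        assert any("tie" in line for line in log)

    def test_unconfigured_hmm_rejected(self):
        a = assemble_fragments([hit(1, 200, 1, 190, hmm="H9")])[0]
        with pytest.raises(ValueError, match="H9"):
            resolve_multi_hmm([a], ["H1"])


FASTA = ">P1 some description\n" + "M" + "KVLA" * 74 + "RYZ\n>sp|P12345|X desc\nMKVLAMKVLAMKVLA\n"
# P1 has length 300; sp|P12345|X has length 15


class TestExtractSequences:
    def test_full_and_partial_slices(self):
        doms = [
            assemble_fragments([hit(1, 300, 1, 200)])[0],
            assemble_fragments([hit(2, 5, 1, 4)])[0],
        ]
        out = extract_sequences(doms, io.StringIO(FASTA))
        assert out[0][0] == "P1/1-300"
        assert len(out[0][1]) == 300
        assert out[1] == ("P1/2-5", "KVLA")

    def test_first_token_id_policy(self):
        dom = assemble_fragments([hit(10, 15, 1, 6, seq_id="sp|P12345|X")])[0]
        out = extract_sequences([dom], io.StringIO(FASTA))
        assert out[0][0] == "sp|P12345|X/10-15"

    def test_out_of_range_coordinates_error_names_record(self):
        dom = assemble_fragments([hit(10, 20, 1, 11, seq_id="sp|P12345|X")])[0]
        with pytest.raises(ValueError, match="sp\\|P12345\\|X"):
            extract_sequences([dom], io.StringIO(FASTA))

    def test_missing_id_error(self):
        dom = assemble_fragments([hit(1, 10, 1, 10, seq_id="NOPE")])[0]
        with pytest.raises(KeyError, match="NOPE"):
            extract_sequences([dom], io.StringIO(FASTA))


DOMTBL = """\
#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
GHX                  -            200 P1                   -            300   1.2e-50  170.0   0.1   1   2   3.1e-30   6.2e-28  95.0   0.0     1   100     1   100     1   105 0.98 -
GHX                  -            200 P1                   -            300   1.2e-50  170.0   0.1   2   2   1.0e-22   2.0e-20  60.0   0.0    95   200   150   250   145   255 0.95 -
GHX                  -            200 P2                   -            250   5.0e-03    9.0   0.0   1   1   2.2e-03   4.4e-02   8.0   0.0     1    80    10    90     5    95 0.80 -
"""


class TestParseDomtblout:
    def test_parse_and_filter_pipeline(self):
        hits = parse_domtblout(io.StringIO(DOMTBL))
        assert len(hits) == 3
        h = hits[0]
        assert (h.seq_id, h.hmm_name, h.hmm_length) == ("P1", "GHX", 200)
        assert (h.seq_from, h.seq_to, h.hmm_from, h.hmm_to) == (1, 100, 1, 100)
        assert h.i_evalue == pytest.approx(6.2e-28)
        kept = filter_hits(hits)
        assert {h.seq_id for h in kept} == {"P1"}  # P2's 4.4e-02 fails
        assembled = assemble_all(kept)
        assert len(assembled) == 1
        assert (assembled[0].seq_from, assembled[0].seq_to) == (1, 250)

    def test_malformed_line_raises_with_number(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_domtblout(io.StringIO("GHX - 200 P1\n"))
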