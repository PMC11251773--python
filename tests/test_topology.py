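"""Bridging predictor, topology-code algebra, and their brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanthimine import topology as T

PEPTIDE = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


def brute_crossings(bridges):
    arcs = bridges.arcs()
    return sum(
        1
        for (a, b), (c, d) in itertools.combinations(sorted(arcs), 2)
        if a < c < b < d
    )


# ---------------------------------------------------------------------------
# predict_bridges
# ---------------------------------------------------------------------------

class TestPredict:
    def test_labionin_motif_forms_a_unit(self):
        bs = T.predict_bridges("SAASAAC")
        assert bs.labionin_units == [(1, 4, 7)]
        assert bs.lan_bridges == [] and bs.free_cys == []

    def test_blocked_labionin_falls_back_to_crossed_lan_arcs(self):
        # C10 cannot take the labionin (C7 sits inside the span) so it binds
        # S4; C7 then finds S4 bonded and reaches back to S1.
        bs = T.predict_bridges("SAASAACAAC")
        assert bs.lan_bridges == [(1, 7), (4, 10)]
        assert bs.labionin_units == []
        assert T.count_crossings(bs) == 1

    def test_partner_closer_than_min_gap_leaves_cys_free(self):
        bs = T.predict_bridges("SAC")
        assert bs.free_cys == [3] and not bs.lan_bridges

    def test_first_cys_only_mode_limits_labionin_to_terminal_cys(self):
        # the C-terminal-most Cys takes a Lan partner, so under
        # first_cys_only no labionin can form at the earlier Cys
        pep = "SAASAACAAATAAC"
        all_cys = T.predict_bridges(pep, labionin_mode="all_cys")
        first_only = T.predict_bridges(pep, labionin_mode="first_cys_only")
        assert all_cys.labionin_units == [(1, 4, 7)]
        assert first_only.labionin_units == []

    def test_labionin_off_mode(self):
        bs = T.predict_bridges("SAASAAC", labionin_mode="off")
        assert bs.labionin_units == [] and bs.lan_bridges == [(4, 7)]

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            T.predict_bridges("SAXC")

    def test_thr_cannot_anchor_default_labionin(self):
        bs = T.predict_bridges("TAASAAC")
        assert bs.labionin_units == []
        assert bs.lan_bridges == [(4, 7)]

    def test_variant_pattern_allows_thr_first_serine(self):
        pat = T.LabioninPattern(
            first_residues=frozenset("T"),
            second_residues=frozenset("S"),
            spacer=3,
            cys_gap_min=2,
            cys_gap_max=3,
        )
        bs = T.predict_bridges("TAASAC", labionin_pattern=pat)
        assert bs.labionin_units == [(1, 4, 6)]

    @given(pep=PEPTIDE)
    @settings(max_examples=300, deadline=None)
    def test_every_cys_and_bridged_st_used_exactly_once(self, pep):
        bs = T.predict_bridges(pep)
        used = bs.positions_used()
        assert len(used) == len(set(used))
        cys_positions = {i + 1 for i, ch in enumerate(pep) if ch == "C"}
        covered_cys = {j for _, j in bs.lan_bridges}
        covered_cys |= {j for _, _, j in bs.labionin_units}
        covered_cys |= set(bs.free_cys)
        assert covered_cys == cys_positions

    @given(pep=PEPTIDE)
    @settings(max_examples=300, deadline=None)
    def test_prediction_never_nests(self, pep):
        assert T.check_nesting(T.predict_bridges(pep)) == []


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------

class TestCodes:
    @pytest.mark.parametrize(
        "pep, expected",
        [
            ("SAAACSAAAC", "SCSC"),  # tandem, uncrossed
            ("SAASAACAAC", "SSCC"),  # overlapping
            ("SAASAAC", "LLC"),  # labionin
        ],
    )
    def test_encode_worked_examples(self, pep, expected):
        bs = T.predict_bridges(pep)
        assert str(T.encode_topology(bs, pep)) == expected

    def test_geobacillin_decode_reproduces_printed_pairing(self):
        bs = T.decode_topology("SCSCSCSSCSCSCC")
        assert sorted(bs.lan_bridges) == [
            (1, 2), (3, 4), (5, 6), (7, 9), (8, 11), (10, 13), (12, 14),
        ]
        assert bs.free_cys == [] and bs.labionin_units == []

    def test_ssccc_decode_is_crossed(self):
        bs = T.decode_topology("SSCC")
        assert sorted(bs.lan_bridges) == [(1, 3), (2, 4)]
        assert T.count_crossings(bs) == 1

    def test_llc_decode(self):
        bs = T.decode_topology("LLC")
        assert bs.labionin_units == [(1, 2, 3)]

    def test_decoded_arbitrary_code_can_nest(self):
        bs = T.decode_topology("LLSCC")
        assert T.check_nesting(bs)  # nested pair never produced by predict

    @pytest.mark.parametrize("bad", ["LC", "LLCL", "CLL"])
    def test_unbalanced_l_errors(self, bad):
        with pytest.raises(ValueError):
            T.decode_topology(bad)

    def test_alphabet_validated(self):
        with pytest.raises(ValueError):
            T.decode_topology("SCX")

    @given(pep=PEPTIDE)
    @settings(max_examples=300, deadline=None)
    def test_round_trip_exact_for_labionin_free_predictions(self, pep):
        """decode(encode(predict)) reproduces the arc pattern when no
        labionin fires (positions re-indexed to code order)."""
        bs = T.predict_bridges(pep)
        if bs.labionin_units:
            return
        code = T.encode_topology(bs, pep)
        if not code.code:
            return
        bs2 = T.decode_topology(code)
        rank = {p: i + 1 for i, p in enumerate(sorted(bs.positions_used()))}
        assert sorted((rank[a], rank[b]) for a, b in bs.lan_bridges) == sorted(
            bs2.lan_bridges
        )
        assert len(bs2.free_cys) == len(bs.free_cys)
        assert T.count_crossings(bs2) == T.count_crossings(bs)


# ---------------------------------------------------------------------------
# counting and combinatorics
# ---------------------------------------------------------------------------

class TestCounts:
    def test_bridge_counts_worked_examples(self):
        assert T.count_bridges(T.decode_topology("SCSCSCSSCSCSCC")) == 7
        assert T.count_bridges(T.decode_topology("SCSSCCSCSCSSCCSC")) == 8
        assert T.count_bridges(T.BridgeSet(peptide_length=5)) == 0

    def test_labionin_counts_once(self):
        bs = T.predict_bridges("SAASAACAAATAAAAC")
        assert len(bs.labionin_units) == 1 and len(bs.lan_bridges) == 1
        assert T.count_bridges(bs) == 2

    def test_crossings_worked_examples(self):
        assert T.count_crossings(T.decode_topology("SCSCSCSSCSCSCC")) == 3
        assert T.count_crossings(T.decode_topology("SCSC")) == 0
        assert T.count_crossings(T.decode_topology("SSCC")) == 1

    @given(pep=PEPTIDE)
    @settings(max_examples=300, deadline=None)
    def test_crossings_match_brute_force_on_predictions(self, pep):
        bs = T.predict_bridges(pep)
        assert T.count_crossings(bs) == brute_crossings(bs)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_crossings_match_brute_force_on_random_arc_sets(self, data):
        n = data.draw(st.integers(4, 30))
        k = data.draw(st.integers(0, n // 2))
        positions = data.draw(
            st.permutations(range(1, n + 1)).map(lambda p: list(p)[: 2 * k])
        )
        arcs = [
            tuple(sorted(positions[2 * i : 2 * i + 2])) for i in range(k)
        ]
        bs = T.BridgeSet(peptide_length=n, lan_bridges=arcs)
        assert T.count_crossings(bs) == brute_crossings(bs)

    def test_bridge_space_printed_value(self):
        assert T.bridge_space_size(15, 8) == 259_459_200
        assert T.bridge_space_size(15, 8) > 250_000_000
        assert T.bridge_space_size(1, 1) == 1
        assert T.bridge_space_size(3, 2) == 6

    @pytest.mark.parametrize("n", range(0, 8))
    def test_bridge_space_matches_enumeration(self, n):
        for k in range(n + 1):
            enumerated = sum(1 for _ in itertools.permutations(range(n), k))
            assert T.bridge_space_size(n, k) == enumerated
            assert T.bridge_space_size(n, k) == math.perm(n, k)

    def test_bridge_space_rejects_bad_args(self):
        with pytest.raises(ValueError):
            T.bridge_space_size(3, 4)


# ---------------------------------------------------------------------------
# tallies and motifs
# ---------------------------------------------------------------------------

class TestTalliesAndMotifs:
    def test_tally_respects_known_codes_and_support(self):
        df = T.tally_topologies(
            ["SCSC", "SCSC", "SSCC"], known_codes={"SCSC"}, min_support=2
        )
        by_code = df.set_index("code")
        assert not by_code.loc["SCSC", "is_novel"]
        assert by_code.loc["SSCC", "is_novel"]
        assert not by_code.loc["SSCC", "novel_supported"]  # support 1 < 2
        assert by_code.loc["SSCC", "count"] == 1

    def test_tally_novel_with_support(self):
        df = T.tally_topologies(["LLC", "LLC"], known_codes=set())
        assert df.iloc[0].to_dict() == {
            "code": "LLC", "count": 2, "is_novel": True, "novel_supported": True,
        }

    def test_tally_empty(self):
        assert len(T.tally_topologies([], set())) == 0

    @pytest.mark.parametrize(
        "pep, pattern, expected",
        [
            ("SAASAAC", "SxxSx{2,5}C", [1]),
            ("CASAAS", "CxSxxS", [1]),
            ("AAAA", "SxxSx{2,5}C", []),
            ("TAASAC", "TxxSx{1,2}C", [1]),
            ("SAASAACSAASAAC", "S[^C]{2}S[^C]{2,5}C", [1, 8]),
        ],
    )
    def test_motif_search(self, pep, pattern, expected):
        assert T.find_motif(pep, pattern) == expected

    def test_overlapping_matches_found(self):
        assert T.find_motif("CGCGCG", "CxC") == [1, 3]
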