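"""The XYLP membership rule against brute-force oracles and planted truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylpscan.core_io import ProteinRecord
from xylpscan.synthetic_data import gen_xylp_proteome
from xylpscan.xylp_classify import (
    MotifBounds, PastRegion, classify_xylp, find_glycomodules,
    find_past_regions, match_nsltp_motif, name_candidates, past_fraction,
)

from oracles import brute_force_past_regions, exhaustive_nsltp_assignment


class TestPastFraction:
    def test_all_past(self):
        assert past_fraction("APSTAPSTAP", 1, 10) == 1.0

    def test_no_past(self):
        assert past_fraction("GGGGGGGGGG", 1, 10) == 0.0

    def test_sub_window(self):
        assert past_fraction("GAPSTG", 2, 5) == 1.0
        assert past_fraction("GAPSTG", 1, 6) == pytest.approx(4 / 6)

    def test_invalid_window_error(self):
        with pytest.raises(ValueError):
            past_fraction("GAPSTG", 4, 2)


class TestFindPastRegions:
    def test_no_qualifying_window(self):
        assert find_past_regions("G" * 100) == []

    def test_planted_block_single_region(self):
        seq = "G" * 30 + "APAPSPSTTP" * 4 + "G" * 30
        regions = find_past_regions(seq)
        assert len(regions) == 1
        (r,) = regions
        # exactly one region, containing the planted block (31-70); under
        # the union-of-qualifying-windows definition flanks join whenever a
        # longer diluted window still clears the threshold
        assert r.start <= 31 and r.end >= 70
        assert [(r.start, r.end)] == brute_force_past_regions(seq)

    def test_threshold_is_inclusive_at_35_percent(self):
        # exactly 7 PAST residues in a 20-mer: fraction 0.35 qualifies
        seq = "P" * 7 + "G" * 13
        regions = find_past_regions(seq, theta=0.35, l_min=20)
        assert regions and regions[0].past_fraction == pytest.approx(0.35)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_past_regions("APST" * 10, theta=0.0)
        with pytest.raises(ValueError):
            find_past_regions("APST" * 10, l_min=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_window_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 301))
        p_past = float(rng.uniform(0.1, 0.6))
        seq = "".join(
            rng.choice(list("PAST")) if rng.random() < p_past
            else rng.choice(list("GLVKDERF"))
            for _ in range(n)
        )
        got = [(r.start, r.end) for r in find_past_regions(seq)]
        assert got == brute_force_past_regions(seq)


class TestGlycomodules:
    def test_single_hit(self):
        hits = find_glycomodules("GAPG")
        assert [(h.position, h.dipeptide) for h in hits] == [(2, "AP")]

    def test_overlapping_hits_all_counted(self):
        hits = find_glycomodules("APA")
        assert [(h.position, h.dipeptide) for h in hits] == [(1, "AP"), (2, "PA")]

    def test_pp_not_a_glycomodule(self):
        assert find_glycomodules("PPPP") == []

    def test_region_restricts_start_positions(self):
        seq = "APGGGGAP"
        region = PastRegion(1, 3, 1.0)
        hits = find_glycomodules(seq, region)
        assert [h.position for h in hits] == [1]

    @given(st.text(alphabet="GLVKDERF", min_size=0, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_appending_non_past_outside_region_keeps_hits(self, suffix):
        seq = "GAPAPSPSTG"
        region = PastRegion(2, 9, 1.0)
        base = find_glycomodules(seq, region)
        assert find_glycomodules(seq + suffix, region) == base


TOY = ("A" * 5 + "C" + "A" * 9 + "C" + "A" * 5 + "P" + "A" * 8 + "CC"
       + "A" * 12 + "C" + "L" + "C" + "A" * 20 + "C" + "A" * 8 + "C")


class TestNsltpMotif:
    def test_constructed_scaffold(self):
        m = match_nsltp_motif(TOY)
        assert m is not None
        assert m.cys_positions == exhaustive_nsltp_assignment(TOY)
        assert m.spacer_lengths == (9, 14, 0, 12, 1, 20, 8)
        assert m.inter56_residue == "L" and m.inter56_hydrophobic

    def test_two_residues_between_c5_c6_rejected(self):
        toy2 = TOY.replace("C" + "L" + "C", "C" + "LL" + "C")
        assert match_nsltp_motif(toy2) is None

    def test_seven_cysteines_no_match(self):
        assert match_nsltp_motif(TOY[: TOY.rfind("C")]) is None

    def test_malformed_bounds_error(self):
        with pytest.raises(ValueError):
            MotifBounds(c1_c2=(10, 5))

    def test_hydrophobic_annotation_not_a_filter(self):
        toy_q = TOY.replace("C" + "L" + "C", "C" + "Q" + "C")
        m = match_nsltp_motif(toy_q)
        assert m is not None and not m.inter56_hydrophobic

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(60, 150))
        seq = "".join(
            "C" if rng.random() < 0.08
            else ("P" if rng.random() < 0.1 else rng.choice(list("AGLVKDER")))
            for _ in range(n)
        )
        if seq.count("C") > 12:
            seq = seq.replace("C", "A", seq.count("C") - 12)
        m = match_nsltp_motif(seq)
        expected = exhaustive_nsltp_assignment(seq)
        if expected is None:
            assert m is None
        else:
            assert m is not None and m.cys_positions == expected


class TestClassifier:
    def test_decoy_without_motif(self):
        recs, truth = gen_xylp_proteome(1)
        by_id = {r.id: r for r in recs}
        for pid in truth.decoy_past_ids:
            call = classify_xylp(by_id[pid])
            assert call.verdict == "not_XYLP"
            assert "no_nsltp_motif" in call.reasons

    def test_decoy_without_past_region(self):
        recs, truth = gen_xylp_proteome(1)
        by_id = {r.id: r for r in recs}
        for pid in truth.decoy_motif_ids:
            call = classify_xylp(by_id[pid])
            assert call.verdict == "not_XYLP"
            assert "no_past_region" in call.reasons

    def test_planted_xylps_accepted_with_truth_coordinates(self):
        recs, truth = gen_xylp_proteome(2)
        by_id = {r.id: r for r in recs}
        for pid in truth.xylp_ids:
            call = classify_xylp(by_id[pid])
            assert call.verdict == "XYLP"
            start, end = truth.regions[pid]
            assert any(r.start <= start and r.end >= end
                       for r in call.past_regions)
            assert call.motif.cys_positions == truth.cys_positions[pid]


class TestNaming:
    def test_input_order(self):
        def call(pid, verdict):
            return type("C", (), {"protein_id": pid, "verdict": verdict})()

        calls = [call("p9", "XYLP"), call("p2", "XYLP"), call("p4", "not_XYLP"),
                 call("p5", "XYLP")]
        assert name_candidates(calls) == {"p9": "XYLP1", "p2": "XYLP2",
                                          "p5": "XYLP3"}

    def test_prefix_and_28_members(self):
        def call(i):
            return type("C", (), {"protein_id": f"p{i}", "verdict": "XYLP"})()

        names = name_candidates([call(i) for i in range(28)], prefix="AcXYLP")
        assert names["p0"] == "AcXYLP1" and names["p27"] == "AcXYLP28"

    def test_empty_accepted_set_warns(self):
        def call(i):
            return type("C", (), {"protein_id": f"p{i}",
                                  "verdict": "not_XYLP"})()

        with pytest.warns(UserWarning):
            assert name_candidates([call(0)]) == {}
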