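import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import necklace_count, ssr_oracle
from denovotx.fixtures import load_table1
from denovotx.ssr import (
    canonical_motif,
    detect_ssrs,
    enumerate_motif_classes,
    is_primitive,
    select_marker_loci,
    summarize_ssrs,
    summarize_table1,
)


class TestCanonicalMotif:
    def test_minimal_rotation(self):
        assert canonical_motif("TC") == "CT"
        assert canonical_motif("GAT") == "ATG"

    def test_rejects_non_primitive(self):
        with pytest.raises(ValueError, match="primitive"):
            canonical_motif("ATAT")

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            canonical_motif("AX")

    def test_twelve_primitive_dimers_form_six_classes(self):
        units = ["".join(u) for u in itertools.product("ACGT", repeat=2)]
        primitive = [u for u in units if is_primitive(u)]
        assert len(primitive) == 12
        assert len({canonical_motif(u) for u in primitive}) == 6

    @settings(derandomize=True, max_examples=80)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=6), st.integers(0, 5))
    def test_rotation_invariance(self, unit, shift):
        if not is_primitive(unit):
            return
        rotated = unit[shift % len(unit) :] + unit[: shift % len(unit)]
        assert canonical_motif(unit) == canonical_motif(rotated)


class TestEnumerateMotifClasses:
    def test_matches_necklace_formula(self):
        for k in range(1, 7):
            assert enumerate_motif_classes(k) == necklace_count(k)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_motif_classes(7)


class TestDetectSsrs:
    def test_constructed_dinucleotide_locus(self):
        loci = detect_ssrs("GGACACACACACTT")
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.start, locus.end, locus.unit, locus.n_repeats) == (2, 12, "AC", 5)

    def test_four_repeats_below_threshold(self):
        assert detect_ssrs("ACACACAC") == []

    def test_ambiguous_base_breaks_repeat(self):
        # 4 clean repeats on each side of the N: below threshold
        assert detect_ssrs("ACACACAC" + "N" + "ACACACAC") == []
        # 5 clean repeats on each side: two separate loci
        assert len(detect_ssrs("ACACACACAC" + "N" + "ACACACACAC")) == 2

    def test_mononucleotide_runs_excluded(self):
        assert detect_ssrs("A" * 40) == []

    def test_composite_period_reported_at_primitive_unit(self):
        loci = detect_ssrs("T" + "AC" * 12 + "G")
        assert len(loci) == 1
        assert loci[0].unit == "AC"
        assert loci[0].n_repeats == 12

    def test_overlap_resolution_prefers_longer_then_leftmost(self):
        # (CA)x5 then (AT)x5 sharing one bp: equal spans, leftmost wins
        loci = detect_ssrs("CACACACACATATATATATA")
        assert len(loci) == 1
        assert (loci[0].start, loci[0].unit) == (0, "CA")

    def test_matches_oracle_on_random_sequences(self, rng):
        for _ in range(60):
            # biased alphabet so repeats actually occur
            seq = "".join(rng.choice(list("ACGT"), size=400, p=[0.4, 0.4, 0.1, 0.1]))
            if rng.random() < 0.5:  # plant one clean repeat
                unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
                pos = int(rng.integers(0, 300))
                seq = seq[:pos] + unit * 6 + seq[pos + 6 * len(unit) :]
            got = [(l.start, l.end, l.unit, l.n_repeats) for l in detect_ssrs(seq)]
            assert sorted(got) == ssr_oracle(seq)

    def test_reported_loci_revalidate(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=600, p=[0.35, 0.35, 0.15, 0.15]))
            loci = detect_ssrs(seq)
            for locus in loci:
                assert seq[locus.start : locus.end] == locus.unit * locus.n_repeats
                assert is_primitive(locus.unit)
            spans = sorted((l.start, l.end) for l in loci)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestSummaries:
    def test_empty_is_all_zero(self):
        summary = summarize_ssrs([], 1000)
        assert (summary[["n_loci", "bp", "percent"]] == 0).all().all()

    def test_planted_loci_counted_exactly(self):
        seqs = {
            "u1": "G" * 30 + "AC" * 7 + "G" * 30,
            "u2": "T" * 25 + "GAT" * 5 + "T" * 25,
        }
        loci = [l for uid, s in seqs.items() for l in detect_ssrs(s, unigene_id=uid)]
        total = sum(len(s) for s in seqs.values())
        summary = summarize_ssrs(loci, total)
        assert summary.loc[2, "n_loci"] == 1 and summary.loc[2, "bp"] == 14
        assert summary.loc[3, "n_loci"] == 1 and summary.loc[3, "bp"] == 15
        assert summary.loc["total", "n_loci"] == 2
        assert summary.loc["total", "bp"] == 29

    def test_distinct_classes_never_exceed_analytic_maximum(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.4, 0.4, 0.1, 0.1]))
        summary = summarize_ssrs(detect_ssrs(seq), 2000)
        for k in range(2, 7):
            assert summary.loc[k, "n_classes"] <= enumerate_motif_classes(k)


class TestSelectMarkerLoci:
    def _host(self, flank="random", rng=None):
        rng = rng or np.random.default_rng(5)
        left = "".join(rng.choice(list("ACGT"), size=100))
        right = "".join(rng.choice(list("ACGT"), size=100))
        return left + "TCA" * 6 + right

    def test_clean_planted_locus_is_eligible(self):
        seq = self._host()
        unigenes = {"u1": seq}
        loci = detect_ssrs(seq, unigene_id="u1")
        cands = select_marker_loci(loci, unigenes)
        assert len(cands) == 1 and cands[0].eligible

    def test_duplicate_unigenes_fail_uniqueness(self):
        seq = self._host()
        unigenes = {"u1": seq, "u2": seq}
        loci = [l for uid in unigenes for l in detect_ssrs(seq, unigene_id=uid)]
        cands = select_marker_loci(loci, unigenes)
        assert all(not c.unique and not c.eligible for c in cands)

    def test_short_flank_fails(self):
        rng = np.random.default_rng(9)
        seq = "TCA" * 6 + "".join(rng.choice(list("ACGT"), size=200))
        cands = select_marker_loci(detect_ssrs(seq, unigene_id="u"), {"u": seq})
        assert len(cands) == 1
        assert cands[0].left_flank_bp == 0 and not cands[0].eligible

    def test_repeat_in_flank_fails(self):
        rng = np.random.default_rng(13)
        left = "".join(rng.choice(list("ACGT"), size=80)) + "GT" * 4  # 4 reps: short repeat
        right = "".join(rng.choice(list("ACGT"), size=100))
        seq = left + "TCA" * 6 + right
        loci = [l for l in detect_ssrs(seq, unigene_id="u") if l.unit == "TCA"]
        cands = select_marker_loci(loci, {"u": seq})
        assert len(cands) == 1 and not cands[0].flank_repeat_free and not cands[0].eligible

    def test_dangling_unigene_reference(self):
        loci = detect_ssrs("G" * 60 + "AC" * 7 + "G" * 60, unigene_id="ghost")
        with pytest.raises(KeyError):
            select_marker_loci(loci, {"u": "ACGT" * 50})


class TestSummarizeTable1:
    def test_packaged_marker_table_breakdown(self):
        result = summarize_table1(load_table1())
        assert result["polymorphic"] == 14
        assert result["monomorphic"] == 4
        assert result["null_alleles"] == 5
        assert result["n_loci"] == 23
        assert result["by_motif_length"] == {2: 8, 3: 14, 4: 1}

    def test_empty_fixture_all_zero(self):
        import pandas as pd

        result = summarize_table1(pd.DataFrame(columns=["motif", "status"]))
        assert result["polymorphic"] == result["monomorphic"] == result["null_alleles"] == 0

    def test_malformed_status_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="status"):
            summarize_table1(pd.DataFrame({"motif": ["AC"], "status": ["MAYBE"]}))
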