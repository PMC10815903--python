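"""Alignment redundancy filtering, reference mapping, column profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tdtkinetics.conservation import (
    POCKET_POSITIONS,
    AlignedSet,
    column_frequencies,
    filter_redundancy,
    map_reference_position,
    pocket_profile,
)
from tdtkinetics.synthdata import gen_alignment


def small_alignment(**rows):
    records = {"ref": rows.pop("ref")}
    records.update(rows)
    return AlignedSet(records=records, reference_id="ref")


class TestFilterRedundancy:
    def test_exact_duplicates_collapse_to_one(self):
        a = small_alignment(ref="ACDEF", s1="ACDEF", s2="ACDEF")
        out = filter_redundancy(a)
        assert len(out.records) == 1

    def test_fragment_below_coverage_removed(self):
        a = small_alignment(ref="ACDEFGHIKL", s1="ACDEF-----", s2="ACDEFGHIKM")
        out = filter_redundancy(a, min_coverage=0.8)
        assert "s1" not in out.records
        assert "s2" in out.records

    def test_counting_on_injected_redundancy(self):
        aln, book = gen_alignment(
            n_sequences=10, length=60, compositions={}, n_duplicates=3,
            n_fragments=1, seed=4,
        )
        out = filter_redundancy(aln)
        assert len(out.records) == 10
        for rid in book["duplicates"] + book["fragments"]:
            assert rid not in out.records

    def test_idempotent(self):
        aln, _ = gen_alignment(
            n_sequences=30, length=80, compositions={}, n_duplicates=4,
            n_fragments=3, seed=5,
        )
        once = filter_redundancy(aln)
        twice = filter_redundancy(once)
        assert once.records == twice.records

    def test_reference_always_retained(self):
        a = small_alignment(ref="AC---", s1="ACDEF")  # ref is itself a fragment
        out = filter_redundancy(a, min_coverage=0.9)
        assert "ref" in out.records


class TestMapReferencePosition:
    def test_gap_skipping(self):
        a = small_alignment(ref="AC-DE")
        assert map_reference_position(a, 3) == 4

    def test_first_residue_maps_to_first_nongap_column(self):
        a = small_alignment(ref="--A-C")
        assert map_reference_position(a, 1) == 3

    def test_out_of_range_rejected(self):
        a = small_alignment(ref="AC-DE")
        with pytest.raises(ValueError, match="exceeds"):
            map_reference_position(a, 5)

    @given(st.lists(st.sampled_from("ACDEFG-"), min_size=5, max_size=40))
    def test_agrees_with_ungapping_oracle(self, chars):
        ref = "".join(chars)
        ungapped = ref.replace("-", "")
        if not ungapped:
            return
        a = AlignedSet(records={"ref": ref}, reference_id="ref")
        for pos in range(1, len(ungapped) + 1):
            col = map_reference_position(a, pos)
            # oracle: brute-force scan of the gapped string
            assert ref[col - 1] != "-"
            assert ref[: col].replace("-", "")[-1] == ungapped[pos - 1]
            assert len(ref[:col].replace("-", "")) == pos


class TestColumnFrequencies:
    def test_simple_split(self):
        rows = {f"s{i}": ("D" if i < 7 else "E") * 5 for i in range(10)}
        a = AlignedSet(records={"ref": "DDDDD", **rows}, reference_id="ref")
        prof = column_frequencies(a, 3)
        # 8 D (7 + reference) and 3 E among 11 records
        assert prof.percents["D"] == pytest.approx(100 * 8 / 11)
        assert prof.percents["E"] == pytest.approx(100 * 3 / 11)
        assert sum(prof.percents.values()) == pytest.approx(100.0, abs=0.01)

    def test_strictly_conserved_column(self):
        a = small_alignment(ref="AFA", s1="CFD", s2="DFE")
        prof = column_frequencies(a, 2)
        assert prof.percents == {"F": 100.0}

    def test_gaps_excluded_from_denominator(self):
        a = small_alignment(ref="ADA", s1="C-D", s2="DDE")
        prof = column_frequencies(a, 2)
        assert prof.n_gap == 1
        assert prof.percents["D"] == pytest.approx(100.0)

    def test_generated_composition_recovered_exactly(self):
        comp = {395: {"D": 0.723, "E": 0.273, "other": 0.004}}
        aln, _ = gen_alignment(n_sequences=469, compositions=comp, seed=6)
        prof = column_frequencies(aln, 395)
        assert prof.counts["D"] == 339
        assert prof.counts["E"] == 128
        assert prof.percents["D"] == pytest.approx(100 * 339 / 469)
        assert prof.percents["E"] == pytest.approx(100 * 128 / 469)


class TestPocketProfile:
    def test_default_positions_give_seven_profiles(self):
        aln, _ = gen_alignment(n_sequences=50, seed=7)
        profiles = pocket_profile(aln)
        assert [p.ref_position for p in profiles] == list(POCKET_POSITIONS)

    def test_permutation_invariance(self):
        aln, _ = gen_alignment(n_sequences=40, seed=8)
        ids = list(aln.records)
        rng = np.random.default_rng(0)
        shuffled_ids = [ids[i] for i in rng.permutation(len(ids))]
        shuffled = AlignedSet(
            records={rid: aln.records[rid] for rid in shuffled_ids},
            reference_id=aln.reference_id,
        )
        p1 = pocket_profile(aln)
        p2 = pocket_profile(shuffled)
        for a, b in zip(p1, p2):
            assert a.percents == b.percents
            assert a.n_gap == b.n_gap

    def test_all_gap_column_insertion_does_not_change_profiles(self):
        aln, _ = gen_alignment(n_sequences=20, length=60, compositions={}, seed=9)
        padded = AlignedSet(
            records={rid: seq[:10] + "-" + seq[10:] for rid, seq in aln.records.items()},
            reference_id=aln.reference_id,
        )
        for pos in (5, 15, 40):
            assert (
                column_frequencies(aln, pos).percents
                == column_frequencies(padded, pos).percents
            )
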