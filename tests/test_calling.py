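"""Indel calling: demultiplexing, alignment, classification, subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paircut as pc
from paircut.calling import (
    BACKGROUND_FILTERED, CallingConfig, EDITED, INVALID, IndelEvent,
    LibraryIndex, PairEditingProfile, RepairType, TARGET_START, UNASSIGNED,
    UNEDITED, align_target, apply_events, call_reads, classify_read,
    demultiplex, left_normalize, subtract_background,
)
from paircut.design import reverse_complement

from oracles import oracle_canonical


def _to_plain(events, subs):
    return (tuple((ev.kind, ev.start, ev.length, ev.inserted_seq) for ev in events),
            tuple(subs))


class TestDemultiplex:
    @pytest.fixture()
    def index(self, small_library):
        return LibraryIndex(small_library)

    def _amplicon(self, index, pair_id):
        return index.reference_amplicon(pair_id)

    def test_exact_match_assigns(self, index, small_library):
        pid = small_library[0].pair_id
        assert demultiplex(self._amplicon(index, pid), index) == ("assigned", pid)

    def test_spacer_mismatch_is_invalid(self, index, small_library):
        pid = small_library[0].pair_id
        read = self._amplicon(index, pid)
        i = 30  # inside the crRNA-encoding region
        read = read[:i] + ("A" if read[i] != "A" else "C") + read[i + 1:]
        assert demultiplex(read, index) == (INVALID, pid)

    def test_unknown_barcode_unassigned(self, index, small_library):
        read = self._amplicon(index, small_library[0].pair_id)
        bc = "A" * 12 if small_library[0].barcode != "A" * 12 else "C" * 12
        read = read[:68] + bc + read[80:]
        assert demultiplex(read, index)[0] == UNASSIGNED

    def test_short_read_unassigned(self, index):
        assert demultiplex("ACGT", index)[0] == UNASSIGNED

    def test_reverse_complement_rescue(self, index, small_library):
        pid = small_library[0].pair_id
        rc = reverse_complement(self._amplicon(index, pid))
        profiles, stats = call_reads([rc], index)
        assert stats.rc_rescued == 1 and profiles[pid].unedited_count == 1


class TestAlignTarget:
    def test_identity(self):
        ref = "TTTA" + "ACGT" * 9 + "CG"
        assert align_target(ref, ref) == ([], [])

    def test_worked_deletion_20_to_25(self, small_library):
        """Removing positions 20-25 yields the single event (20, 6)."""
        ref = small_library[0].target
        read = ref[:20] + ref[26:]
        events, subs = align_target(read, ref)
        assert subs == []
        assert [(e.kind, e.start, e.length) for e in events] == [("deletion", 20, 6)]

    def test_homopolymer_deletion_left_aligned(self):
        ref = "TTTAGC" + "AAAAA" + "GCGTACGTACGTACGTACGTACGTACGTACG"
        ref = ref[:42]
        read = ref[:8] + ref[9:]  # delete one A from the middle of the run
        events, _ = align_target(read, ref)
        assert [(e.kind, e.start, e.length) for e in events] == [("deletion", 6, 1)]

    def test_insertion_reported_with_sequence(self):
        ref = "TTTACGATCGGCTAGCTAGGACTGACTGATCGATCGATCGAT"
        read = ref[:10] + "GGC" + ref[10:]
        events, _ = align_target(read, ref)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "insertion" and ev.length == 3

    def test_substitution_shortcut_matches_dp(self):
        ref = "TTTACGATCGGCTAGCTAGGACTGACTGATCGATCGATCGAT"
        read = ref[:5] + "A" + ref[6:]
        assert read != ref
        events, subs = align_target(read, ref)
        assert events == [] and subs == [5]

    @pytest.mark.parametrize("n_events", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, n_events):
        rng = np.random.default_rng(100 + n_events)
        cfg = CallingConfig()
        for _ in range(40):
            n = int(rng.integers(25, 61))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            read = _plant_events(ref, n_events, rng)
            got = _to_plain(*align_target(read, ref, cfg))
            (exp_events, exp_subs), _score = oracle_canonical(read, ref)
            assert got == (exp_events, exp_subs)


def _plant_events(ref, n_events, rng):
    read = ref
    for _ in range(n_events):
        if rng.random() < 0.5 and len(read) > 8:
            L = int(rng.integers(1, 7))
            pos = int(rng.integers(0, len(read) - L))
            read = read[:pos] + read[pos + L:]
        else:
            L = int(rng.integers(1, 5))
            pos = int(rng.integers(0, len(read) + 1))
            ins = "".join(rng.choice(list("ACGT"), size=L))
            read = read[:pos] + ins + read[pos:]
    return read


class TestClassifyRead:
    def test_cut_site_deletion_is_edited(self):
        assert classify_read([IndelEvent("deletion", 20, 6)], []) == EDITED

    def test_small_peripheral_indel_is_background(self):
        assert classify_read([IndelEvent("deletion", 2, 1)], []) == BACKGROUND_FILTERED

    def test_large_peripheral_deletion_stays_edited(self):
        assert classify_read([IndelEvent("deletion", 0, 10)], []) == EDITED

    def test_no_events_is_unedited(self):
        assert classify_read([], []) == UNEDITED

    def test_out_of_frame_indel_is_background(self):
        # event in the trailing constant region, outside the 42-bp frame
        assert classify_read([IndelEvent("deletion", 50, 2)], []) == BACKGROUND_FILTERED

    def test_substitution_policies(self):
        cfg_count = CallingConfig(substitution_policy="count_in_frame")
        assert classify_read([], [21], cfg_count) == EDITED
        assert classify_read([], [21]) == UNEDITED  # default tolerates


class TestSerialization:
    def test_catalogue_format_deletion(self):
        rt = RepairType((IndelEvent("deletion", 20, 6),), 111)
        assert pc.serialize_repair_type(rt) == "[(20, 6)]:111"

    def test_parse_count_and_events(self):
        rt = pc.parse_repair_type("[(20, 6)]:111")
        assert rt.count == 111
        assert rt.events == (IndelEvent("deletion", 20, 6),)

    @pytest.mark.parametrize("s", [
        "[(20, 6)]:111",
        "[(3, 2), (20, 6)]:7",
        "[(22, 3I:ACG)]:5",
        "[(10, 1S:G)]:2",
        "[(5, 2), (22, 2I:AT)]:1",
    ])
    def test_roundtrip_from_string(self, s):
        assert pc.serialize_repair_type(pc.parse_repair_type(s)) == s

    @given(st.lists(
        st.tuples(st.integers(0, 41), st.integers(1, 8)), min_size=1, max_size=3))
    @settings(derandomize=True, max_examples=30)
    def test_roundtrip_from_events(self, raw):
        events, last = [], -10
        for start, length in sorted(raw):
            if start <= last:
                continue
            events.append(IndelEvent("deletion", start, min(length, 42 - start)))
            last = start + events[-1].length
        rt = RepairType(tuple(events), 9)
        assert pc.parse_repair_type(pc.serialize_repair_type(rt)) == rt

    @pytest.mark.parametrize("bad", ["nonsense", "[(20, 6)]", "[(x, 2)]:3",
                                     "[(1, 2) (3, 4)]:5"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            pc.parse_repair_type(bad)


class TestEventApplication:
    def test_deletion_span_inclusive(self):
        ref = "".join(chr(ord("A") + (i % 26)) for i in range(42))
        out = apply_events(ref, [IndelEvent("deletion", 20, 6)])
        assert out == ref[:20] + ref[26:]
        assert len(ref) - len(out) == 6

    def test_left_normalize_shifts_through_homopolymer(self):
        ref = "CCAAAAGG"
        ev = left_normalize([IndelEvent("deletion", 5, 1)], ref)
        assert ev[0].start == 2
        assert apply_events(ref, ev) == apply_events(
            ref, [IndelEvent("deletion", 5, 1)])


class TestProfilesAndSubtraction:
    def _profile(self, pid, types, unedited=100):
        prof = PairEditingProfile(pid, unedited_count=unedited)
        for (start, length), n in types.items():
            prof.edited_types[(IndelEvent("deletion", start, length),)] = n
        return prof

    def test_repair_type_grouping(self, small_library):
        """Reads with the same event list collapse into one catalogue entry."""
        index = LibraryIndex(small_library)
        pair = small_library[0]
        ref = index.reference_amplicon(pair.pair_id)
        edited = ref[:TARGET_START + 20] + ref[TARGET_START + 26:]
        reads = [edited] * 111 + [ref] * 189
        profiles, _ = call_reads(reads, index)
        prof = profiles[pair.pair_id]
        rts = prof.repair_types()
        assert len(rts) == 1
        assert pc.serialize_repair_type(rts[0]) == "[(20, 6)]:111"
        assert prof.unedited_count == 189

    def test_shared_type_removed_unique_kept(self):
        exp = {"p": self._profile("p", {(20, 6): 50, (22, 2): 10})}
        ctrl = {"p": self._profile("p", {(22, 2): 4})}
        out = subtract_background(exp, ctrl)["p"]
        assert list(out.edited_types.values()) == [50]
        assert out.unedited_count == 110  # background reads become unedited

    def test_empty_control_changes_nothing(self):
        exp = {"p": self._profile("p", {(20, 6): 50})}
        out = subtract_background(exp, {"p": self._profile("p", {})})["p"]
        assert out.edited_types == exp["p"].edited_types

    def test_missing_control_pair_logged(self, caplog):
        exp = {"p": self._profile("p", {(20, 6): 5})}
        with caplog.at_level("WARNING"):
            out = subtract_background(exp, {})
        assert "missing from control" in caplog.text
        assert out["p"].edited_total == 5

    def test_frequency_formula(self):
        cfg = CallingConfig(min_reads=100)
        prof = self._profile("p", {(20, 6): 111}, unedited=189)
        assert pc.indel_frequency(prof, cfg) == pytest.approx(0.37)

    def test_zero_edited_frequency(self):
        prof = self._profile("p", {}, unedited=400)
        assert pc.indel_frequency(prof) == 0.0

    def test_low_coverage_excluded(self):
        prof = self._profile("p", {(20, 6): 99}, unedited=200)  # total 299
        assert pc.indel_frequency(prof) is None
        prof2 = self._profile("p", {(20, 6): 101}, unedited=200)  # total 301
        assert pc.indel_frequency(prof2) is not None
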