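"""Indel calling on paired guide-target amplicons.

The core computation: demultiplex full-length integrated amplicons by the
42-nt crRNA-encoding sequence (19-nt handle + 23-nt spacer) plus the 12-nt
barcode, globally align the target region of each read to its 42-nt
reference, call indel events with left-aligned gap placement, run a
two-round frame analysis (a 42-bp primary frame around the cleavage site,
then an 8-bp secondary frame that reclassifies small peripheral indels as
background), catalogue repair types in the ``[(start, len)]:count`` format,
subtract repair types that also occur in the no-effector control, and
compute per-pair indel frequencies.

Coordinates are 0-based with the 5' end of the PAM at position 0; a deletion
``(20, 6)`` removes positions 20-25 inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .design import (
    BARCODE_LEN, DEFAULT_FWD_CONST, DEFAULT_HANDLE, DEFAULT_REV_CONST,
    FWD_CONST_LEN, HANDLE_LEN, POLYT_LEN, SPACER_LEN, TARGET_LEN,
    GuideTargetPair, reverse_complement,
)

logger = logging.getLogger("paircut.calling")

NEG_INF = float("-inf")

# Fixed offsets of the amplicon layout.
CRRNA_START = FWD_CONST_LEN                      # 20
CRRNA_END = CRRNA_START + HANDLE_LEN + SPACER_LEN  # 62; handle+spacer = 42 nt
BARCODE_START = CRRNA_END + POLYT_LEN            # 68
BARCODE_END = BARCODE_START + BARCODE_LEN        # 80
TARGET_START = BARCODE_END                       # 80


# ---------------------------------------------------------------------------
# Events and repair types
# ---------------------------------------------------------------------------

DELETION = "deletion"
INSERTION = "insertion"
SUBSTITUTION = "substitution"

_KIND_ORDER = {DELETION: 0, INSERTION: 1, SUBSTITUTION: 2}


@dataclass(frozen=True, order=False)
class IndelEvent:
    """One editing event in target coordinates (PAM 5' end = position 0).

    A deletion of length L starting at s removes positions s..s+L-1.  An
    insertion of ``inserted_seq`` at s places the new bases immediately
    before position s.  Substitution events (length 1, ``inserted_seq`` =
    observed base) are produced only under the ``count_in_frame`` policy.
    """

    kind: str
    start: int
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be positive")
        if self.start < 0:
            raise ValueError("event start must be >= 0")
        if self.kind == INSERTION and len(self.inserted_seq) != self.length:
            raise ValueError("insertion length must match inserted_seq")

    @property
    def end(self) -> int:
        """Half-open end on the reference (insertions occupy zero width)."""
        return self.start + (self.length if self.kind == DELETION else 0)

    def sort_key(self) -> tuple:
        return (self.start, _KIND_ORDER[self.kind], self.length, self.inserted_seq)


@dataclass(frozen=True)
class RepairType:
    """A distinct edited outcome: an ordered event list with its read count."""

    events: Tuple[IndelEvent, ...]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("repair-type count must be >= 1")
        if tuple(sorted(self.events, key=IndelEvent.sort_key)) != self.events:
            object.__setattr__(self, "events",
                               tuple(sorted(self.events, key=IndelEvent.sort_key)))


def serialize_events(events: Sequence[IndelEvent]) -> str:
    parts = []
    for ev in events:
        if ev.kind == DELETION:
            parts.append(f"({ev.start}, {ev.length})")
        elif ev.kind == INSERTION:
            payload = f":{ev.inserted_seq}" if ev.inserted_seq else ""
            parts.append(f"({ev.start}, {ev.length}I{payload})")
        else:
            parts.append(f"({ev.start}, 1S:{ev.inserted_seq})")
    return "[" + ", ".join(parts) + "]"


def serialize_repair_type(rt: RepairType) -> str:
    """Render as the catalogue format, e.g. ``[(20, 6)]:111``."""
    return f"{serialize_events(rt.events)}:{rt.count}"


_EVENT_RE = re.compile(
    r"\((\d+),\s*(\d+)(I|S)?(?::([ACGTN]*))?\)")


def parse_repair_type(s: str) -> RepairType:
    """Inverse of :func:`serialize_repair_type`; errors carry the position."""
    m = re.fullmatch(r"\[(.*)\]:(\d+)", s.strip())
    if not m:
        raise ValueError(f"malformed repair type {s!r}: expected '[...]:count'")
    body, count = m.group(1), int(m.group(2))
    events: List[IndelEvent] = []
    pos = 0
    body = body.strip()
    while pos < len(body):
        em = _EVENT_RE.match(body, pos)
        if not em:
            raise ValueError(f"malformed event in {s!r} at offset {pos}")
        start, length, tag, payload = (int(em.group(1)), int(em.group(2)),
                                       em.group(3), em.group(4) or "")
        if tag == "I":
            if payload and len(payload) != length:
                raise ValueError(f"insertion payload length mismatch at offset {pos}")
            events.append(IndelEvent(INSERTION, start, length,
                                     payload or "N" * length))
        elif tag == "S":
            events.append(IndelEvent(SUBSTITUTION, start, 1, payload))
        else:
            events.append(IndelEvent(DELETION, start, length))
        pos = em.end()
        if pos < len(body):
            if not body.startswith(", ", pos):
                raise ValueError(f"malformed separator in {s!r} at offset {pos}")
            pos += 2
    return RepairType(tuple(events), count)


def apply_events(reference: str, events: Sequence[IndelEvent]) -> str:
    """Reconstruct the edited sequence from reference + event list.

    Events apply right-to-left; at an equal start coordinate the deletion
    applies first, so an insertion at a deletion's start lands at the
    junction of the collapsed sequence.
    """
    seq = reference
    order = sorted(events, key=lambda e: (e.start, -_KIND_ORDER[e.kind]),
                   reverse=True)
    for ev in order:
        if ev.kind == DELETION:
            seq = seq[:ev.start] + seq[ev.start + ev.length:]
        elif ev.kind == INSERTION:
            seq = seq[:ev.start] + ev.inserted_seq + seq[ev.start:]
        else:
            seq = seq[:ev.start] + ev.inserted_seq + seq[ev.start + 1:]
    return seq


def left_normalize(events: Sequence[IndelEvent], reference: str) -> Tuple[IndelEvent, ...]:
    """Shift indels to the lowest sequence-equivalent coordinate.

    Standard left-alignment: a deletion slides left while the base entering
    the deleted window from the left equals the one leaving on the right; an
    insertion rotates left while its last base equals the reference base just
    before the insertion point.  Events must be supplied in alignment order
    (the order they occur along the read) and never slide past the previous
    event; the returned tuple is coordinate-sorted.
    """
    out: List[IndelEvent] = []
    prev_end = 0
    for ev in events:
        if ev.kind == DELETION:
            s, L = ev.start, ev.length
            while s > prev_end and reference[s - 1] == reference[s + L - 1]:
                s -= 1
            out.append(replace(ev, start=s))
            prev_end = s + L
        elif ev.kind == INSERTION:
            s, ins = ev.start, ev.inserted_seq
            while s > prev_end and ins and reference[s - 1] == ins[-1]:
                ins = reference[s - 1] + ins[:-1]
                s -= 1
            out.append(replace(ev, start=s, inserted_seq=ins))
            prev_end = s
        else:
            out.append(ev)
            prev_end = ev.start + 1
    return tuple(sorted(out, key=IndelEvent.sort_key))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallingConfig:
    """Tunable parameters of the two-round calling analysis.

    ``primary_frame`` is the window in which indels are recognized at all
    (the whole 42-nt target by default).  ``secondary_frame`` is the 8-bp
    window centred between the two staggered nicks (22 and 27 -> [21, 29));
    reads whose recognized indels are all short (<= ``small_indel_max``) and
    disjoint from it are reclassified as background.  ``substitution_policy``
    controls whether substitution-only reads count as edited
    (``count_in_frame``) or are tolerated (``ignore``, the default).
    """

    primary_frame: Tuple[int, int] = (0, TARGET_LEN)
    secondary_frame: Tuple[int, int] = (21, 29)
    small_indel_max: int = 3
    substitution_policy: str = "ignore"  # or "count_in_frame"
    min_reads: int = 300
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    count_filtered_as_unedited: bool = True
    rc_rescue: bool = True

    def __post_init__(self) -> None:
        p0, p1 = self.primary_frame
        s0, s1 = self.secondary_frame
        if not (p0 <= s0 and s1 <= p1):
            raise ValueError("secondary_frame must lie inside primary_frame")
        if self.small_indel_max < 1:
            raise ValueError("small_indel_max must be >= 1")
        if self.substitution_policy not in ("ignore", "count_in_frame"):
            raise ValueError(f"unknown substitution_policy {self.substitution_policy!r}")


# ---------------------------------------------------------------------------
# Global affine alignment with exhaustive optimal-path canonicalization
# ---------------------------------------------------------------------------

def _affine_dp(read: str, ref: str, cfg: CallingConfig):
    """Forward pass of global Needleman-Wunsch with affine gaps.

    Returns the three score matrices (M diagonal, D gap-in-read consuming
    reference, I gap-in-reference consuming read).  A gap of length L costs
    ``gap_open + L * gap_extend``.
    """
    m, n = len(read), len(ref)
    go, ge = cfg.gap_open, cfg.gap_extend
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    D = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    I = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for j in range(1, n + 1):
        D[0][j] = go + ge * j
    for i in range(1, m + 1):
        I[i][0] = go + ge * i
    for i in range(1, m + 1):
        ri = read[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        for j in range(1, n + 1):
            s = cfg.match if ri == ref[j - 1] else cfg.mismatch
            best_prev = Mp[j - 1]
            if Dp[j - 1] > best_prev:
                best_prev = Dp[j - 1]
            if Ip[j - 1] > best_prev:
                best_prev = Ip[j - 1]
            Mi[j] = best_prev + s
            # D: consume ref[j-1] with a gap in the read
            open_d = (Mi[j - 1] if Mi[j - 1] >= Ii[j - 1] else Ii[j - 1]) + go + ge
            ext_d = Di[j - 1] + ge
            Di[j] = open_d if open_d >= ext_d else ext_d
            # I: consume read[i-1] with a gap in the reference
            open_i = (Mp[j] if Mp[j] >= Dp[j] else Dp[j]) + go + ge
            ext_i = Ip[j] + ge
            Ii[j] = open_i if open_i >= ext_i else ext_i
    return M, D, I


def _enumerate_optimal_events(read: str, ref: str, cfg: CallingConfig,
                              max_paths: int = 1000):
    """All distinct left-normalized event lists among optimal alignments.

    Traceback enumerates every co-optimal path (capped at *max_paths*),
    converts each to an event list, left-normalizes, and deduplicates.
    """
    M, D, I = _affine_dp(read, ref, cfg)
    m, n = len(read), len(ref)
    go, ge = cfg.gap_open, cfg.gap_extend
    best = max(M[m][n], D[m][n], I[m][n])

    results = set()
    # stack entries: (i, j, state, moves-so-far); moves recorded in reverse.
    start_states = [st for st, v in (("M", M[m][n]), ("D", D[m][n]), ("I", I[m][n]))
                    if v == best]
    stack = [(m, n, st, []) for st in start_states]
    paths = 0
    while stack and paths < max_paths:
        i, j, st, moves = stack.pop()
        if i == 0 and j == 0:
            paths += 1
            results.add(_moves_to_events(read, ref, moves[::-1]))
            continue
        if st == "M":
            s = cfg.match if read[i - 1] == ref[j - 1] else cfg.mismatch
            target = M[i][j] - s
            for prev_st, val in (("M", M[i - 1][j - 1]), ("D", D[i - 1][j - 1]),
                                 ("I", I[i - 1][j - 1])):
                if val == target:
                    stack.append((i - 1, j - 1, prev_st, moves + ["M"]))
        elif st == "D":
            if D[i][j] == D[i][j - 1] + ge:
                stack.append((i, j - 1, "D", moves + ["D"]))
            if D[i][j] == M[i][j - 1] + go + ge:
                stack.append((i, j - 1, "M", moves + ["D"]))
            if D[i][j] == I[i][j - 1] + go + ge:
                stack.append((i, j - 1, "I", moves + ["D"]))
        else:  # I
            if I[i][j] == I[i - 1][j] + ge:
                stack.append((i - 1, j, "I", moves + ["I"]))
            if I[i][j] == M[i - 1][j] + go + ge:
                stack.append((i - 1, j, "M", moves + ["I"]))
            if I[i][j] == D[i - 1][j] + go + ge:
                stack.append((i - 1, j, "D", moves + ["I"]))
    return results, best


def _moves_to_events(read: str, ref: str, moves: Sequence[str]):
    """Convert an alignment path into (indel events, substitution positions)."""
    events: List[IndelEvent] = []
    subs: List[int] = []
    i = j = 0
    k = 0
    while k < len(moves):
        mv = moves[k]
        if mv == "M":
            if read[i] != ref[j]:
                subs.append(j)
            i += 1
            j += 1
            k += 1
        elif mv == "D":
            start = j
            while k < len(moves) and moves[k] == "D":
                j += 1
                k += 1
            events.append(IndelEvent(DELETION, start, j - start))
        else:  # I
            start = j
            ins_start = i
            while k < len(moves) and moves[k] == "I":
                i += 1
                k += 1
            events.append(IndelEvent(INSERTION, start, i - ins_start,
                                     read[ins_start:i]))
    norm = left_normalize(events, ref)
    return (norm, tuple(subs))


def _events_order_key(item):
    events, subs = item
    return (tuple(ev.sort_key() for ev in events), subs)


@lru_cache(maxsize=200_000)
def _align_cached(read: str, ref: str, cfg: CallingConfig):
    results, _ = _enumerate_optimal_events(read, ref, cfg)
    return min(results, key=_events_order_key)


def align_target(read_region: str, reference: str,
                 config: CallingConfig = CallingConfig()
                 ) -> Tuple[List[IndelEvent], List[int]]:
    """Globally align a read's target region to its reference.

    Returns the canonical (left-aligned, lexicographically least among
    co-optimal alignments) indel event list in reference coordinates plus
    the substituted reference positions.
    """
    if not read_region or not reference:
        raise ValueError("empty sequence passed to align_target")
    if read_region == reference:
        return [], []
    # Cheap exact shortcut: at equal length, <=2 substitutions always beat
    # any gapped explanation (penalty 2*|mismatch-match| = 12 < 14, the
    # minimal cost of a compensating deletion+insertion pair). At 3
    # mismatches a 1-nt shift can win, so fall through to the full DP.
    if len(read_region) == len(reference):
        mism = [j for j, (a, b) in enumerate(zip(read_region, reference)) if a != b]
        if len(mism) <= 2:
            return [], mism
    events, subs = _align_cached(read_region, reference, config)
    return list(events), list(subs)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

EDITED = "edited"
UNEDITED = "unedited"
BACKGROUND_FILTERED = "background_filtered"
INVALID = "invalid"
UNASSIGNED = "unassigned"


class LibraryIndex:
    """Exact-match lookup from (crRNA-encoding sequence, barcode) to pair."""

    def __init__(self, pairs: Sequence[GuideTargetPair],
                 handle: str = DEFAULT_HANDLE,
                 fwd_const: str = DEFAULT_FWD_CONST,
                 rev_const: str = DEFAULT_REV_CONST):
        self.handle = handle
        self.fwd_const = fwd_const
        self.rev_const = rev_const
        self.pairs: Dict[str, GuideTargetPair] = {}
        self.barcode_to_pair: Dict[str, str] = {}
        self.crrna: Dict[str, str] = {}
        self.reference_region: Dict[str, str] = {}
        for p in pairs:
            if p.barcode in self.barcode_to_pair:
                raise ValueError(f"duplicate barcode {p.barcode} in library")
            self.pairs[p.pair_id] = p
            self.barcode_to_pair[p.barcode] = p.pair_id
            self.crrna[p.pair_id] = handle + p.spacer
            self.reference_region[p.pair_id] = p.target + rev_const

    def reference_amplicon(self, pair_id: str) -> str:
        p = self.pairs[pair_id]
        return (self.fwd_const + self.handle + p.spacer + "T" * POLYT_LEN
                + p.barcode + p.target + self.rev_const)


def demultiplex(read: str, index: LibraryIndex) -> Tuple[str, Optional[str]]:
    """Assign a read to a pair by exact crRNA-region + barcode match.

    Returns (status, pair_id): an exact match on both keys assigns the read;
    a recognized barcode with a mismatched crRNA-encoding region is
    ``invalid`` (an imperfect guide cannot report on editing); an unknown
    barcode is ``unassigned``.
    """
    if len(read) < BARCODE_END:
        return UNASSIGNED, None
    pair_id = index.barcode_to_pair.get(read[BARCODE_START:BARCODE_END])
    if pair_id is None:
        return UNASSIGNED, None
    if read[CRRNA_START:CRRNA_END] != index.crrna[pair_id]:
        return INVALID, pair_id
    return "assigned", pair_id


# ---------------------------------------------------------------------------
# Classification and profiles
# ---------------------------------------------------------------------------

def _overlaps(ev: IndelEvent, frame: Tuple[int, int]) -> bool:
    lo, hi = frame
    if ev.kind == INSERTION:
        return lo <= ev.start <= hi  # zero-width: inside or on the boundary
    return ev.start < hi and ev.end > lo


def classify_read(events: Sequence[IndelEvent], substitutions: Sequence[int],
                  config: CallingConfig = CallingConfig()) -> str:
    """Two-round frame classification of one aligned read.

    Round 1 recognizes indels overlapping the primary frame.  Round 2
    reclassifies reads whose recognized indels are all small and disjoint
    from the secondary frame as background.  Substitution handling follows
    ``config.substitution_policy``.
    """
    recognized = [ev for ev in events if _overlaps(ev, config.primary_frame)]
    if recognized:
        if all(ev.length <= config.small_indel_max
               and not _overlaps(ev, config.secondary_frame)
               for ev in recognized):
            return BACKGROUND_FILTERED
        return EDITED
    if events:
        # indels only outside the primary frame (e.g. in the trailing
        # constant region): not Cas12a editing, kept out of the catalogue.
        return BACKGROUND_FILTERED
    if config.substitution_policy == "count_in_frame":
        lo, hi = config.primary_frame
        if any(lo <= s < hi for s in substitutions):
            return EDITED
    return UNEDITED


@dataclass
class PairEditingProfile:
    """Per-pair bookkeeping after classification (and subtraction)."""

    pair_id: str
    unedited_count: int = 0
    edited_types: Dict[Tuple[IndelEvent, ...], int] = field(default_factory=dict)
    invalid_count: int = 0
    filtered_count: int = 0

    @property
    def edited_total(self) -> int:
        return sum(self.edited_types.values())

    @property
    def assigned_total(self) -> int:
        return self.unedited_count + self.filtered_count + self.edited_total

    def repair_types(self) -> List[RepairType]:
        out = [RepairType(ev, n) for ev, n in self.edited_types.items()]
        out.sort(key=lambda rt: (-rt.count, tuple(e.sort_key() for e in rt.events)))
        return out


@dataclass
class CallingStats:
    """Library-wide demultiplexing tallies."""

    total_reads: int = 0
    assigned: int = 0
    invalid: int = 0
    unassigned: int = 0
    rc_rescued: int = 0


def _event_key(events: Sequence[IndelEvent], substitutions: Sequence[int],
               read_region: str, reference: str,
               config: CallingConfig) -> Tuple[IndelEvent, ...]:
    """Catalogue key for an edited read.

    Under ``count_in_frame``, in-frame substitutions join the key as
    substitution pseudo-events so that recurring sequencing-error types can
    be removed by control subtraction; under ``ignore`` the key holds the
    indel events only.
    """
    evs = list(events)
    if config.substitution_policy == "count_in_frame":
        lo, hi = config.primary_frame
        # reconstruct observed bases at substituted reference positions
        obs = _observed_bases(read_region, reference, events, substitutions)
        for pos, base in zip(substitutions, obs):
            if lo <= pos < hi:
                evs.append(IndelEvent(SUBSTITUTION, pos, 1, base))
    return tuple(sorted(evs, key=IndelEvent.sort_key))


def _observed_bases(read_region: str, reference: str,
                    events: Sequence[IndelEvent],
                    substitutions: Sequence[int]) -> List[str]:
    """Map substituted reference positions to the base observed in the read."""
    shift = 0
    out = []
    evs = sorted(events, key=IndelEvent.sort_key)
    for pos in substitutions:
        s = shift
        for ev in evs:
            if ev.kind == DELETION and ev.start + ev.length <= pos:
                s -= ev.length
            elif ev.kind == INSERTION and ev.start <= pos:
                s += ev.length
        idx = pos + s
        out.append(read_region[idx] if 0 <= idx < len(read_region) else "N")
    return out


def call_reads(reads: Iterable[str], index: LibraryIndex,
               config: CallingConfig = CallingConfig()
               ) -> Tuple[Dict[str, PairEditingProfile], CallingStats]:
    """Demultiplex, align and classify a read stream into per-pair profiles."""
    profiles = {pid: PairEditingProfile(pid) for pid in index.pairs}
    stats = CallingStats()
    for read in reads:
        stats.total_reads += 1
        status, pair_id = demultiplex(read, index)
        if status == UNASSIGNED and config.rc_rescue:
            status, pair_id = demultiplex(reverse_complement(read), index)
            if status != UNASSIGNED:
                read = reverse_complement(read)
                stats.rc_rescued += 1
        if status == UNASSIGNED:
            stats.unassigned += 1
            continue
        if status == INVALID:
            stats.invalid += 1
            profiles[pair_id].invalid_count += 1
            continue
        stats.assigned += 1
        prof = profiles[pair_id]
        reference = index.reference_region[pair_id]
        region = read[TARGET_START:]
        if not region:  # truncated read: no target to interrogate
            stats.assigned -= 1
            stats.invalid += 1
            prof.invalid_count += 1
            continue
        events, subs = align_target(region, reference, config)
        cls = classify_read(events, subs, config)
        if cls == EDITED:
            key = _event_key(events, subs, region, reference, config)
            prof.edited_types[key] = prof.edited_types.get(key, 0) + 1
        elif cls == BACKGROUND_FILTERED:
            prof.filtered_count += 1
        else:
            prof.unedited_count += 1
    return profiles, stats


# ---------------------------------------------------------------------------
# Background subtraction and frequency
# ---------------------------------------------------------------------------

def subtract_background(experimental: Dict[str, PairEditingProfile],
                        control: Dict[str, PairEditingProfile]
                        ) -> Dict[str, PairEditingProfile]:
    """Remove repair types that also occur in the matched control.

    Only event lists unique to the experimental sample are retained as
    effector-induced; types also seen in the same pair's control are moved
    to the unedited tally (they existed before editing).
    """
    out: Dict[str, PairEditingProfile] = {}
    for pid, prof in experimental.items():
        ctrl = control.get(pid)
        if ctrl is None:
            logger.warning("pair %s missing from control; no subtraction applied", pid)
            ctrl_types = frozenset()
        else:
            ctrl_types = frozenset(ctrl.edited_types)
        kept: Dict[Tuple[IndelEvent, ...], int] = {}
        moved = 0
        for key, n in prof.edited_types.items():
            if key in ctrl_types:
                moved += n
            else:
                kept[key] = n
        out[pid] = PairEditingProfile(
            pair_id=pid, unedited_count=prof.unedited_count + moved,
            edited_types=kept, invalid_count=prof.invalid_count,
            filtered_count=prof.filtered_count)
    return out


def indel_frequency(profile: PairEditingProfile,
                    config: CallingConfig = CallingConfig()) -> Optional[float]:
    """edited / (edited + unedited), or None when the pair is excluded.

    Background-filtered reads count as unedited in the denominator by
    default.  Pairs with (edited + unedited) <= ``min_reads`` are excluded
    (the screen required read counts over 300).
    """
    unedited = profile.unedited_count
    if config.count_filtered_as_unedited:
        unedited += profile.filtered_count
    edited = profile.edited_total
    total = edited + unedited
    if total <= config.min_reads or total == 0:
        return None
    return edited / total


def profiles_to_frame(profiles: Dict[str, PairEditingProfile],
                      config: CallingConfig = CallingConfig()):
    """Per-pair summary table (one row per pair, TSV interchange columns)."""
    import pandas as pd

    rows = []
    for pid in sorted(profiles):
        prof = profiles[pid]
        freq = indel_frequency(prof, config)
        rows.append({
            "pair_id": pid, "unedited": prof.unedited_count,
            "edited_total": prof.edited_total, "filtered": prof.filtered_count,
            "invalid": prof.invalid_count,
            "indel_frequency": float("nan") if freq is None else freq,
            "excluded": freq is None})
    return pd.DataFrame(rows)


def catalogue_to_frame(profiles: Dict[str, PairEditingProfile]):
    """Repair-type catalogue (one row per pair x type, serialized format)."""
    import pandas as pd

    rows = []
    for pid in sorted(profiles):
        for rt in profiles[pid].repair_types():
            rows.append({"pair_id": pid, "repair_type": serialize_repair_type(rt),
                         "count": rt.count})
    return pd.DataFrame(rows, columns=["pair_id", "repair_type", "count"])
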