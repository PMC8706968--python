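"""Design of paired guide-target Cas12a libraries.

A library unit couples a crRNA spacer with its own target site on the same
construct, so that after lentiviral integration every cell carries both the
guide and the sequence it cuts.  Each synthesized oligo is 142 nt::

    fwd_const(20) | handle(19) | spacer(23) | polyT(6) | barcode(12) | target(42) | rev_const(20)

The target is the 4-nt PAM followed by the 23-nt protospacer and 15 nt of
downstream genomic context.  This module scans source sequences for
PAM-adjacent protospacers on both strands, filters guides on GC content and
poly-T runs, picks the top candidates per gene, assigns error-robust
barcodes, and assembles/parses the oligo layout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

# IUPAC degeneracy sets for nucleotide symbols.
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

# Element lengths of the synthesized oligo, in layout order.
FWD_CONST_LEN = 20
HANDLE_LEN = 19
SPACER_LEN = 23
POLYT_LEN = 6
BARCODE_LEN = 12
TARGET_LEN = 42
REV_CONST_LEN = 20
OLIGO_LEN = 142

PAM_LEN = 4
CONTEXT_LEN = TARGET_LEN - PAM_LEN - SPACER_LEN  # 15 nt downstream context

# Default constant primer-binding ends (any fixed 20-mers work; these are the
# package defaults used by the simulator and the caller unless overridden).
DEFAULT_FWD_CONST = "TTGTGGAAAGGACGAAACAC"
DEFAULT_REV_CONST = "TCTAGAGCCATTTGTCTGCA"

# Default 19-nt crRNA scaffold handle (AsCas12a-style direct repeat) and the
# non-conserved loop positions where orthologue-specific substitutions live.
DEFAULT_HANDLE = "TAATTTCTACTCTTGTAGA"
DEFAULT_LOOP_POSITIONS = frozenset({8, 9, 10, 11})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


# ---------------------------------------------------------------------------
# PAM patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PamPattern:
    """IUPAC-degenerate PAM, e.g. ``TTTV`` (V = A/C/G) or ``KKYV``."""

    symbols: str

    def __post_init__(self) -> None:
        for ch in self.symbols:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern {self.symbols!r}")
        if not self.symbols:
            raise ValueError("empty PAM pattern")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def size(self) -> int:
        """Number of concrete sequences the pattern expands to."""
        n = 1
        for ch in self.symbols:
            n *= len(IUPAC[ch])
        return n


def expand_pattern(pattern: PamPattern | str) -> List[str]:
    """All concrete sequences matching *pattern*, lexicographically sorted."""
    pat = pattern if isinstance(pattern, PamPattern) else PamPattern(pattern)
    sets = [sorted(IUPAC[ch]) for ch in pat.symbols]
    return ["".join(tup) for tup in itertools.product(*sets)]


def matches_pam(sequence: str, pattern: PamPattern | str) -> bool:
    """True iff each base of *sequence* is in its position's degeneracy set."""
    pat = pattern if isinstance(pattern, PamPattern) else PamPattern(pattern)
    if len(sequence) != len(pat):
        raise ValueError(
            f"length mismatch: sequence {len(sequence)} nt vs pattern {len(pat)} nt"
        )
    return all(b in IUPAC[s] for b, s in zip(sequence.upper(), pat.symbols))


# Library presets from the screen: Lib-A canonical, Lib-B C-rich, Lib-C others.
LIBRARY_PRESETS: Dict[str, List[str]] = {
    "lib-a": ["TTTV"],
    "lib-b": ["TTCV", "VTCV", "VCTV", "VCCV", "VTTV"],
    "lib-c": ["TRTN", "NTTT"],
}


@dataclass(frozen=True)
class LibraryPreset:
    name: str
    pam_patterns: List[PamPattern] = field(default_factory=list)

    @classmethod
    def named(cls, name: str) -> "LibraryPreset":
        key = name.lower()
        if key not in LIBRARY_PRESETS:
            raise KeyError(f"unknown preset {name!r}; known: {sorted(LIBRARY_PRESETS)}")
        return cls(key, [PamPattern(p) for p in LIBRARY_PRESETS[key]])


# ---------------------------------------------------------------------------
# Protospacer scanning and guide filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideCandidate:
    """One PAM-adjacent protospacer found in a source sequence.

    Minus-strand hits are reported in the orientation read 5'->3' off the
    reverse complement; ``pam_start`` is the 0-based offset of the PAM's first
    base in that same orientation.
    """

    gene_id: str
    spacer: str
    pam: str
    strand: str  # '+' or '-'
    pam_start: int
    gc_percent: float

    @property
    def target_region_start(self) -> int:
        return self.pam_start


def _scan_one_strand(seq: str, pat: PamPattern, spacer_len: int, strand: str,
                     gene_id: str) -> List[GuideCandidate]:
    out = []
    plen = len(pat)
    for i in range(len(seq) - plen - spacer_len + 1):
        window = seq[i:i + plen]
        if matches_pam(window, pat):
            spacer = seq[i + plen:i + plen + spacer_len]
            out.append(GuideCandidate(
                gene_id=gene_id, spacer=spacer, pam=window, strand=strand,
                pam_start=i, gc_percent=gc_percent(spacer)))
    return out


def scan_protospacers(sequence: str, pattern: PamPattern | str,
                      spacer_len: int = SPACER_LEN,
                      gene_id: str = "") -> List[GuideCandidate]:
    """Find every PAM match with >= *spacer_len* bases 3' of it, both strands.

    Candidates are sorted by (strand, pam_start), '+' before '-'.
    """
    pat = pattern if isinstance(pattern, PamPattern) else PamPattern(pattern)
    seq = sequence.upper()
    if not seq:
        return []
    hits = _scan_one_strand(seq, pat, spacer_len, "+", gene_id)
    hits += _scan_one_strand(reverse_complement(seq), pat, spacer_len, "-", gene_id)
    hits.sort(key=lambda c: (c.strand, c.pam_start))
    return hits


def filter_guides(candidates: Iterable[GuideCandidate],
                  gc_min: float = 20.0, gc_max: float = 80.0,
                  forbidden_run: str = "TTTT") -> List[GuideCandidate]:
    """Keep guides with GC in [gc_min, gc_max] % and no forbidden run (TTTT).

    Order-preserving and idempotent.
    """
    if gc_min > gc_max:
        raise ValueError(f"gc_min ({gc_min}) > gc_max ({gc_max})")
    return [c for c in candidates
            if gc_min <= c.gc_percent <= gc_max and forbidden_run not in c.spacer]


def take_top_k_per_gene(candidates: Sequence[GuideCandidate], k: int = 10
                        ) -> List[GuideCandidate]:
    """At most *k* guides per gene, ranked deterministically.

    Rank: |GC - 50| ascending (mid-GC guides first), then pam_start ascending,
    then '+' strand before '-'.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    by_gene: Dict[str, List[GuideCandidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)
    out: List[GuideCandidate] = []
    for gene in by_gene:  # insertion order = first-appearance order
        ranked = sorted(by_gene[gene],
                        key=lambda c: (abs(c.gc_percent - 50.0), c.pam_start, c.strand))
        out.extend(ranked[:k])
    return out


def filter_offtargets(candidates: Sequence[GuideCandidate],
                      genome_index=None) -> List[GuideCandidate]:
    """Hook for genome-wide off-target filtering; no-op without an index."""
    return list(candidates)


# ---------------------------------------------------------------------------
# Guide-target pairs and barcodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideTargetPair:
    """One library unit: spacer, barcode and the 42-nt target it cuts."""

    pair_id: str
    spacer: str
    barcode: str
    target: str
    pam: str
    gene_id: str = ""
    strand: str = "+"
    pam_start: int = -1

    def __post_init__(self) -> None:
        if len(self.target) != TARGET_LEN:
            raise ValueError(
                f"target must be {TARGET_LEN} nt, got {len(self.target)} for {self.pair_id}")
        if not self.target.startswith(self.pam):
            raise ValueError(f"target of {self.pair_id} does not start with its PAM")
        if self.barcode and len(self.barcode) != BARCODE_LEN:
            raise ValueError(
                f"barcode must be {BARCODE_LEN} nt, got {len(self.barcode)}")


def _has_homopolymer(seq: str, run: int = 4) -> bool:
    return any(b * run in seq for b in "ACGT")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_barcodes(pairs: Sequence[GuideTargetPair], length: int = BARCODE_LEN,
                    min_distance: int = 3, seed: int = 0) -> List[GuideTargetPair]:
    """Give every pair a unique random barcode.

    Constraints: pairwise Hamming distance >= *min_distance* and no
    homopolymer run of 4, so single-error reads cannot be mis-demultiplexed.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: List[str] = []
    max_attempts = 500 * max(len(pairs), 1) + 1000
    attempts = 0
    while len(accepted) < len(pairs):
        if attempts >= max_attempts:
            raise RuntimeError(
                f"barcode search exhausted: found {len(accepted)} of {len(pairs)} "
                f"barcodes (length {length}, min distance {min_distance})")
        attempts += 1
        bc = "".join(rng.choice(bases, size=length))
        if _has_homopolymer(bc):
            continue
        if all(_hamming(bc, other) >= min_distance for other in accepted):
            accepted.append(bc)
    return [replace(p, barcode=bc) for p, bc in zip(pairs, accepted)]


# ---------------------------------------------------------------------------
# Scaffold variants and oligo assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldVariant:
    """A crRNA handle with base substitutions restricted to its loop region.

    Orthologue-specific handles differ only in the non-conserved loop; the
    stem duplex must stay intact, so substitutions outside ``loop_positions``
    are rejected.
    """

    base_handle: str = DEFAULT_HANDLE
    loop_positions: frozenset = DEFAULT_LOOP_POSITIONS
    substitutions: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.base_handle) != HANDLE_LEN:
            raise ValueError(f"handle must be {HANDLE_LEN} nt")
        bad = set(self.substitutions) - set(self.loop_positions)
        if bad:
            raise ValueError(
                f"substitution at non-loop position(s) {sorted(bad)}; "
                f"loop is {sorted(self.loop_positions)}")
        for pos, base in self.substitutions.items():
            if base not in "ACGT":
                raise ValueError(f"substitution base {base!r} at {pos} not in ACGT")

    def apply(self) -> str:
        handle = list(self.base_handle)
        for pos, base in self.substitutions.items():
            handle[pos] = base
        return "".join(handle)


def apply_scaffold_variant(variant: ScaffoldVariant) -> str:
    return variant.apply()


@dataclass(frozen=True)
class OligoRecord:
    """The 142-nt synthesized oligo, field by field."""

    fwd_const: str
    handle: str
    spacer: str
    polyT: str
    barcode: str
    target: str
    rev_const: str

    _LENGTHS = {
        "fwd_const": FWD_CONST_LEN, "handle": HANDLE_LEN, "spacer": SPACER_LEN,
        "polyT": POLYT_LEN, "barcode": BARCODE_LEN, "target": TARGET_LEN,
        "rev_const": REV_CONST_LEN,
    }

    def __post_init__(self) -> None:
        for name, want in self._LENGTHS.items():
            got = len(getattr(self, name))
            if got != want:
                raise ValueError(f"field {name!r} must be {want} nt, got {got}")
        if self.polyT != "T" * POLYT_LEN:
            raise ValueError("polyT field must be six thymidines")

    @property
    def sequence(self) -> str:
        return (self.fwd_const + self.handle + self.spacer + self.polyT
                + self.barcode + self.target + self.rev_const)


def assemble_oligo(pair: GuideTargetPair,
                   handle: ScaffoldVariant | str = DEFAULT_HANDLE,
                   fwd_const: str = DEFAULT_FWD_CONST,
                   rev_const: str = DEFAULT_REV_CONST) -> OligoRecord:
    """Concatenate the seven layout elements into a 142-nt oligo record."""
    handle_seq = handle.apply() if isinstance(handle, ScaffoldVariant) else handle
    return OligoRecord(fwd_const=fwd_const, handle=handle_seq, spacer=pair.spacer,
                       polyT="T" * POLYT_LEN, barcode=pair.barcode,
                       target=pair.target, rev_const=rev_const)


def parse_oligo(sequence: str) -> OligoRecord:
    """Slice a 142-nt oligo back into its layout fields (inverse of assemble)."""
    if len(sequence) != OLIGO_LEN:
        raise ValueError(f"oligo must be {OLIGO_LEN} nt, got {len(sequence)}")
    offsets = [0, FWD_CONST_LEN, FWD_CONST_LEN + HANDLE_LEN,
               FWD_CONST_LEN + HANDLE_LEN + SPACER_LEN,
               FWD_CONST_LEN + HANDLE_LEN + SPACER_LEN + POLYT_LEN,
               FWD_CONST_LEN + HANDLE_LEN + SPACER_LEN + POLYT_LEN + BARCODE_LEN,
               OLIGO_LEN - REV_CONST_LEN, OLIGO_LEN]
    parts = [sequence[a:b] for a, b in zip(offsets, offsets[1:])]
    return OligoRecord(*parts)


# ---------------------------------------------------------------------------
# End-to-end library design
# ---------------------------------------------------------------------------

def design_library(sequences: Mapping[str, str],
                   patterns: Sequence[PamPattern | str] | LibraryPreset,
                   spacer_len: int = SPACER_LEN,
                   gc_min: float = 20.0, gc_max: float = 80.0,
                   top_k: int = 10, seed: int = 0,
                   max_pairs: Optional[int] = None) -> List[GuideTargetPair]:
    """Scan, filter, rank, extract targets and barcode a full library.

    ``sequences`` maps gene id to its (spliced transcript or genomic)
    sequence.  Candidates lacking the 15-nt downstream context needed for the
    42-nt target are dropped at pair construction.
    """
    if isinstance(patterns, LibraryPreset):
        patterns = patterns.pam_patterns
    pats = [p if isinstance(p, PamPattern) else PamPattern(p) for p in patterns]

    drafts: List[GuideTargetPair] = []
    for gene_id, raw in sequences.items():
        seq = raw.upper()
        cands: List[GuideCandidate] = []
        for pat in pats:
            cands.extend(scan_protospacers(seq, pat, spacer_len, gene_id=gene_id))
        cands.sort(key=lambda c: (c.strand, c.pam_start))
        cands = filter_guides(cands, gc_min=gc_min, gc_max=gc_max)
        cands = filter_offtargets(cands)
        cands = take_top_k_per_gene(cands, k=top_k)
        seen_spacers = set()
        for i, c in enumerate(cands):
            oriented = seq if c.strand == "+" else reverse_complement(seq)
            end = c.pam_start + PAM_LEN + spacer_len + CONTEXT_LEN
            if end > len(oriented):
                continue
            target = oriented[c.pam_start:end]
            if c.spacer in seen_spacers:
                continue
            seen_spacers.add(c.spacer)
            drafts.append(GuideTargetPair(
                pair_id=f"{gene_id}_{i:02d}", spacer=c.spacer, barcode="",
                target=target, pam=c.pam, gene_id=gene_id, strand=c.strand,
                pam_start=c.pam_start))
    if max_pairs is not None:
        drafts = drafts[:max_pairs]
    return assign_barcodes(drafts, seed=seed)


def library_to_frame(pairs: Sequence[GuideTargetPair]):
    """Library as a DataFrame with the interchange TSV column order."""
    import pandas as pd

    return pd.DataFrame(
        [{"pair_id": p.pair_id, "gene_id": p.gene_id, "spacer": p.spacer,
          "barcode": p.barcode, "pam": p.pam, "target": p.target,
          "strand": p.strand, "pam_start": p.pam_start} for p in pairs])


def library_from_frame(df) -> List[GuideTargetPair]:
    return [GuideTargetPair(
        pair_id=str(r.pair_id), spacer=str(r.spacer), barcode=str(r.barcode),
        target=str(r.target), pam=str(r.pam),
        gene_id=str(getattr(r, "gene_id", "")),
        strand=str(getattr(r, "strand", "+")),
        pam_start=int(getattr(r, "pam_start", -1)))
        for r in df.itertuples(index=False)]
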