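"""Synthetic amplicon sequencing data with known ground truth.

Emulates the deep-sequenced, genome-integrated self-cleavage constructs:
each read is a full 142-nt amplicon whose target region may carry a
Cas12a-style repair outcome.  Double-strand breaks from the staggered cut
(nicks ~18 and ~23 nt distal to the PAM, target coordinates 22 and 27) are
repaired either by microhomology-mediated end joining (MMEJ; a deletion
collapsing two identical flanking k-mers around the cut) or by NHEJ
(deletions/short insertions with endpoints near the nicks).

Noise has two components mirroring real screens: clonal synthesis/cloning
artifacts — per-pair indel types present in the oligo pool itself and hence
shared between the experimental and the no-effector control sample, which
is what makes presence-based control subtraction effective — and i.i.d.
sequencing noise (per-base substitutions plus rare per-read indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import (
    DELETION, INSERTION, IndelEvent, apply_events, left_normalize,
    serialize_events,
)
from .design import (
    DEFAULT_FWD_CONST, DEFAULT_HANDLE, DEFAULT_REV_CONST, OLIGO_LEN,
    POLYT_LEN, TARGET_LEN, GuideTargetPair,
)
from .io import FastqRead

PAM_LEN = 4
DEFAULT_CUT_POSITIONS = (22, 27)  # nicks after protospacer nt 18 and 23

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectorModel:
    """A Cas12a effector: per-PAM activity, repair balance, cut geometry."""

    name: str
    pam_activity: Dict[str, float]
    mmej_weight: float = 0.5
    cut_positions: Tuple[int, int] = DEFAULT_CUT_POSITIONS

    def __post_init__(self) -> None:
        for pam, p in self.pam_activity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activity for {pam} out of [0,1]: {p}")
        if not 0.0 <= self.mmej_weight <= 1.0:
            raise ValueError("mmej_weight must be in [0,1]")
        for c in self.cut_positions:
            if not 0 <= c < TARGET_LEN:
                raise ValueError(f"cut position {c} outside [0,{TARGET_LEN})")


@dataclass(frozen=True)
class NoiseModel:
    """Background error model.

    substitution_rate: i.i.d. per-base sequencing substitution probability.
    background_indel_rate: per-read probability of carrying a clonal
        synthesis/cloning artifact indel (the artifact *types* are fixed per
        pair and shared between experimental and control samples).
    artifact_len_max: maximal artifact indel length.
    sequencing_indel_rate: per-read probability of an i.i.d. sequencing indel.
    """

    substitution_rate: float = 0.001
    background_indel_rate: float = 0.02
    artifact_len_max: int = 3
    sequencing_indel_rate: float = 1e-5
    n_artifact_types: int = 2

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "background_indel_rate",
                     "sequencing_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


NO_NOISE = NoiseModel(substitution_rate=0.0, background_indel_rate=0.0,
                      sequencing_indel_rate=0.0)


@dataclass
class TruthRecord:
    """Ground truth for one pair: nominal rate and emitted outcome counts."""

    pair_id: str
    true_edit_rate: float
    emitted_repair_types: Dict[Tuple[IndelEvent, ...], int] = field(default_factory=dict)
    unedited_count: int = 0

    @property
    def total_reads(self) -> int:
        return self.unedited_count + sum(self.emitted_repair_types.values())


# ---------------------------------------------------------------------------
# Microhomology search
# ---------------------------------------------------------------------------

def find_microhomologies(target: str, min_len: int = 2,
                         max_span: Optional[int] = None
                         ) -> List[Tuple[int, int, int]]:
    """All deletions producible by collapsing two identical flanking k-mers.

    Returns (deletion_start, deletion_len, mh_len) tuples, left-normalized
    and deduplicated; ``mh_len`` is the maximal matching flank length (>=
    ``min_len``).  ``max_span`` bounds the deletion length (default: whole
    sequence).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(target)
    span = n if max_span is None else max_span
    best: Dict[Tuple[int, int], int] = {}
    for d in range(1, span + 1):            # deletion length
        for i in range(0, n - d):           # first k-mer start
            if target[i] != target[i + d]:
                continue
            k = 1
            while (i + k < n - d and target[i + k] == target[i + d + k]):
                k += 1
            if k < min_len:
                continue
            # left-normalize the deletion [s, s+d)
            s = i
            while s > 0 and target[s - 1] == target[s + d - 1]:
                s -= 1
            # maximal flank at the normalized coordinate
            kk = 0
            while s + kk < n - d and target[s + kk] == target[s + d + kk]:
                kk += 1
            key = (s, d)
            if kk >= min_len and kk > best.get(key, 0):
                best[key] = kk
    return sorted((s, d, k) for (s, d), k in best.items())


# ---------------------------------------------------------------------------
# Repair simulation
# ---------------------------------------------------------------------------

def _nhej_events(target: str, effector: EffectorModel, rng: np.random.Generator,
                 max_ins: int = 3) -> List[IndelEvent]:
    cuts = effector.cut_positions
    if rng.random() < 0.7:  # deletions dominate Cas12a NHEJ outcomes
        L = int(min(rng.geometric(0.3), 20))
        anchor = int(rng.choice(cuts))
        start = anchor - int(rng.integers(0, L + 1))
        start = max(0, min(start, TARGET_LEN - L))
        return [IndelEvent(DELETION, start, L)]
    L = int(rng.integers(1, max_ins + 1))
    pos = int(rng.choice(cuts))
    ins = "".join(rng.choice(_BASES, size=L))
    return [IndelEvent(INSERTION, pos, L, ins)]


def simulate_repair(pair: GuideTargetPair, effector: EffectorModel,
                    rng_seed, edit_prob: Optional[float] = None
                    ) -> Optional[Tuple[IndelEvent, ...]]:
    """One molecule's repair outcome, or None if unedited.

    With probability ``pam_activity[pam]`` (or ``edit_prob`` if given) the
    molecule is cut and repaired: the MMEJ branch picks a
    microhomology-collapsing deletion overlapping the cut interval,
    weighted by flank length; the NHEJ branch emits a deletion or a 1-3-nt
    insertion anchored at the nicks.  Deterministic for a fixed seed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if edit_prob is None:
        if pair.pam not in effector.pam_activity:
            raise KeyError(
                f"PAM {pair.pam} of {pair.pair_id} absent from pam_activity of "
                f"{effector.name}")
        edit_prob = effector.pam_activity[pair.pam]
    if rng.random() >= edit_prob:
        return None
    events: List[IndelEvent]
    if rng.random() < effector.mmej_weight:
        lo = min(effector.cut_positions)
        hi = max(effector.cut_positions)
        mhs = [(s, d, k) for s, d, k in find_microhomologies(pair.target, min_len=2)
               if s < hi and s + d > lo]
        if mhs:
            w = np.array([k for _, _, k in mhs], dtype=float)
            s, d, _ = mhs[int(rng.choice(len(mhs), p=w / w.sum()))]
            events = [IndelEvent(DELETION, s, d)]
        else:
            events = _nhej_events(pair.target, effector, rng)
    else:
        events = _nhej_events(pair.target, effector, rng)
    return left_normalize(events, pair.target)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Artifact:
    """A clonal synthesis indel in amplicon (not target) coordinates."""

    kind: str
    pos: int
    length: int
    ins: str = ""

    def apply(self, seq: str) -> str:
        if self.kind == DELETION:
            return seq[:self.pos] + seq[self.pos + self.length:]
        return seq[:self.pos] + self.ins + seq[self.pos:]


def _draw_artifacts(noise: NoiseModel, rng: np.random.Generator) -> List[_Artifact]:
    arts = []
    for _ in range(noise.n_artifact_types):
        L = int(rng.integers(1, noise.artifact_len_max + 1))
        if rng.random() < 0.7:
            pos = int(rng.integers(0, OLIGO_LEN - L))
            arts.append(_Artifact(DELETION, pos, L))
        else:
            pos = int(rng.integers(0, OLIGO_LEN))
            arts.append(_Artifact(INSERTION, pos, L, "".join(rng.choice(_BASES, size=L))))
    return arts


def _sequencing_noise(seq: str, noise: NoiseModel, rng: np.random.Generator) -> str:
    n_sub = rng.binomial(len(seq), noise.substitution_rate)
    if n_sub:
        chars = list(seq)
        for pos in rng.choice(len(chars), size=n_sub, replace=False):
            old = chars[pos]
            alts = [b for b in "ACGT" if b != old]
            chars[pos] = alts[int(rng.integers(0, 3))]
        seq = "".join(chars)
    if noise.sequencing_indel_rate and rng.random() < noise.sequencing_indel_rate:
        L = int(rng.integers(1, noise.artifact_len_max + 1))
        if rng.random() < 0.5 and len(seq) > L:
            pos = int(rng.integers(0, len(seq) - L))
            seq = seq[:pos] + seq[pos + L:]
        else:
            pos = int(rng.integers(0, len(seq) + 1))
            seq = seq[:pos] + "".join(rng.choice(_BASES, size=L)) + seq[pos:]
    return seq


@dataclass
class SimulatedDataset:
    """In-memory experimental + control reads with their ground truth."""

    experimental: List[FastqRead]
    control: List[FastqRead]
    truth: pd.DataFrame
    truth_records: Dict[str, TruthRecord]


def _amplicon(pair: GuideTargetPair, target: str, handle: str,
              fwd_const: str, rev_const: str) -> str:
    return (fwd_const + handle + pair.spacer + "T" * POLYT_LEN + pair.barcode
            + target + rev_const)


def generate_dataset(library: Sequence[GuideTargetPair],
                     effector: EffectorModel,
                     noise: NoiseModel = NoiseModel(),
                     depth_per_pair: int = 1000,
                     seed: int = 0,
                     per_pair_rates: Optional[Dict[str, float]] = None,
                     handle: str = DEFAULT_HANDLE,
                     fwd_const: str = DEFAULT_FWD_CONST,
                     rev_const: str = DEFAULT_REV_CONST) -> SimulatedDataset:
    """Emit experimental and control FASTQ reads for a whole library.

    The control sample runs the identical pipeline with editing probability
    forced to 0 (noise only).  Clonal artifact types are drawn once per pair
    and shared between both samples, as the two cell libraries derive from
    the same oligo pool.  ``per_pair_rates`` overrides the effector's
    per-PAM activity with explicit per-pair editing probabilities.
    """
    if depth_per_pair < 1:
        raise ValueError("depth_per_pair must be >= 1")
    barcodes = [p.barcode for p in library]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in library")

    exp_reads: List[FastqRead] = []
    ctrl_reads: List[FastqRead] = []
    truth_records: Dict[str, TruthRecord] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(library))

    for pair, child in zip(library, children):
        rng = np.random.default_rng(child)
        if per_pair_rates is not None:
            rate = per_pair_rates[pair.pair_id]
        else:
            if pair.pam not in effector.pam_activity:
                raise KeyError(f"PAM {pair.pam} absent from pam_activity")
            rate = effector.pam_activity[pair.pam]
        artifacts = _draw_artifacts(noise, rng)
        art_prob = (noise.background_indel_rate / max(len(artifacts), 1)
                    if artifacts else 0.0)
        record = TruthRecord(pair.pair_id, rate)
        ref_amplicon = _amplicon(pair, pair.target, handle, fwd_const, rev_const)

        for sample, sink, p_edit in (("exp", exp_reads, rate),
                                     ("ctrl", ctrl_reads, 0.0)):
            for i in range(depth_per_pair):
                events = simulate_repair(pair, effector, rng, edit_prob=p_edit)
                if events is not None:
                    target = apply_events(pair.target, events)
                    seq = _amplicon(pair, target, handle, fwd_const, rev_const)
                    if sample == "exp":
                        record.emitted_repair_types[events] = (
                            record.emitted_repair_types.get(events, 0) + 1)
                else:
                    seq = ref_amplicon
                    # synthesis artifacts are modeled on unedited templates
                    for art in artifacts:
                        if rng.random() < art_prob:
                            seq = art.apply(seq)
                            break
                    if sample == "exp":
                        record.unedited_count += 1
                seq = _sequencing_noise(seq, noise, rng)
                sink.append(FastqRead(f"{sample}:r{len(sink):07d}", seq,
                                      "I" * len(seq)))
        truth_records[pair.pair_id] = record

    rows = []
    for pid, rec in truth_records.items():
        rows.append({"pair_id": pid, "true_edit_rate": rec.true_edit_rate,
                     "repair_type": ".", "count": rec.unedited_count})
        for events, n in sorted(rec.emitted_repair_types.items(),
                                key=lambda kv: -kv[1]):
            rows.append({"pair_id": pid, "true_edit_rate": rec.true_edit_rate,
                         "repair_type": f"{serialize_events(events)}:{n}",
                         "count": n})
    truth = pd.DataFrame(rows, columns=["pair_id", "true_edit_rate",
                                        "repair_type", "count"])
    return SimulatedDataset(exp_reads, ctrl_reads, truth, truth_records)


def synthesize_gene_sequences(n_genes: int, length: int = 1500,
                              seed: int = 0) -> Dict[str, str]:
    """Random gene-like sequences to feed the library designer.

    Uniform base composition; at 1.5 kb a TTTV PAM occurs dozens of times
    per strand, so no site planting is needed.
    """
    rng = np.random.default_rng(seed)
    return {f"gene{i:04d}": "".join(rng.choice(_BASES, size=length))
            for i in range(n_genes)}
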