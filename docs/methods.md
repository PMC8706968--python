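# Methods

`paircut` models a high-throughput Cas12a activity screen built on
genome-integrated, self-cleaving paired guide–target constructs, and
implements the computation that turns the screen's amplicon sequencing into
per-target indel frequencies and effector-level activity profiles.

## The construct and its coordinate system

Each synthesized oligo is 142 nt:

```
fwd_const(20) | handle(19) | spacer(23) | polyT(6) | barcode(12) | target(42) | rev_const(20)
```

The 42-nt target is the 4-nt PAM, the 23-nt protospacer matching the
spacer, and 15 nt of downstream context. All editing coordinates are
0-based with the 5′ end of the PAM at position 0, so the repair type
`(20, 6)` is a deletion of positions 20–25 inclusive. Cas12a cuts with a
staggered geometry ~18 and ~23 nt distal to the PAM; in target coordinates
the two nicks default to 22 and 27 (PAM occupies 0–3). These values come
from canonical Cas12a biochemistry; they are configurable on
`EffectorModel.cut_positions`.

## Library design

Protospacers are found by scanning both strands for 4-nt windows matching
an IUPAC-degenerate PAM pattern (presets: Lib-A = TTTV; Lib-B = TTCV, VTCV,
VCTV, VCCV, VTTV; Lib-C = TRTN, NTTT) with at least a spacer length of
sequence 3′ of the PAM. Guides are filtered to 20–80% GC and no TTTT run
(a poly-T would terminate the U6 transcript early), and the top 10 per gene
are kept. The ranking statistic of the original web-based designer is not
public, so the package ranks by |GC − 50| ascending with position and
strand tie-breaks: deterministic, and favouring mid-GC guides, which is the
dominant well-understood covariate of guide activity. Off-target counting
requires a genome index and is exposed only as a no-op hook.

Barcodes are random 12-mers constrained to pairwise Hamming distance ≥ 3
and no 4-mer homopolymer. The screen itself only required uniqueness; the
distance constraint is this package's choice so that a single sequencing
error cannot convert one barcode into another.

## Synthetic reads

The generator emits full-length amplicons for an experimental sample and a
no-effector control (identical pipeline, editing probability forced to 0).
Per molecule, editing occurs with the pair's activity probability; an
edited molecule is repaired by:

- **MMEJ** (probability `mmej_weight`, default 0.5 — the literature gives
  no universal MMEJ:NHEJ ratio, so this free parameter defaults to an even
  split): a deletion collapsing two identical flanking k-mers (k ≥ 2) that
  spans the cut interval, sampled with weight proportional to
  microhomology length.
- **NHEJ** otherwise: 70% deletions with geometric(p = 0.3) length
  truncated at 20 and an endpoint anchored at one of the two nicks, 30%
  insertions of 1–3 uniform bases at a nick.

Noise has two deliberately distinct components:

- **Clonal synthesis/cloning artifacts** (`background_indel_rate`, default
  0.02/read): a small set of per-pair indel types drawn once and shared
  between the experimental and control samples, because both cell libraries
  derive from the same oligo pool. This clonality is what makes
  presence-based control subtraction effective, in the simulation exactly
  as in a real screen. Array synthesis has per-base indel error on the
  order of 10⁻³, so ~2% of 142-mers carrying an artifact is realistic.
  Artifacts are drawn only for unedited molecules — an approximation
  (artifact-bearing templates often carry damaged guides and edit poorly)
  that also keeps the realized edit rate equal to the nominal one.
- **i.i.d. sequencing noise**: per-base substitutions at 10⁻³ (≈Q30) and
  rare per-read indels at 10⁻⁵.

Not modeled: quality-score profiles, paired-end structure, PCR duplication,
chromatin-accessibility effects. Passing recovery tests therefore shows
that the calling logic is correct under a faithful error structure, not
that every real-data failure mode is handled.

## Indel calling

Demultiplexing uses the 42-nt crRNA-encoding sequence (19-nt handle +
23-nt spacer) plus the 12-nt barcode at their fixed offsets, both matched
exactly. A recognized barcode with a mismatched crRNA region makes the read
*invalid* (an imperfect guide cannot report on editing); an unknown barcode
leaves it *unassigned*, with one reverse-complement rescue attempt.
Error-correcting barcode matching (possible given the distance-3 design) is
off by default, mirroring strict exact identification.

The read's target region (target + trailing constant, so that artifacts in
the constant tail are visible but fall outside the frame) is globally
aligned to its reference with affine gap scores match +2, mismatch −4, gap
open −6, gap extend −1 (a length-L gap costs 6 + L). Tie-breaking is fully
deterministic: all co-optimal alignments are enumerated (capped at 1000),
converted to event lists, left-normalized (indels shifted to the lowest
sequence-equivalent coordinate, the VCF convention), and the
coordinate-least list is taken. An equal-length read with ≤ 2 mismatches is
short-circuited to substitutions only, which is provably optimal under
these scores (2 × 6 < 14, the minimal cost of a compensating indel pair);
at 3 mismatches a shift alignment can win, so the full DP runs.

Classification is two-round:

1. indels overlapping the 42-bp primary frame (the whole target window,
   `[0, 42)`) are recognized;
2. a read whose recognized indels are all ≤ 3 bp and disjoint from the
   8-bp secondary frame are reclassified *background-filtered*. The screen
   never published the frame's exact placement; the package centres it
   between the staggered nicks (22 and 27 → midpoint 24.5), giving
   `[21, 29)`. Both frames and the small-indel threshold are configurable.

Filtered reads count as unedited in the frequency denominator by default
(they were sequenced, just not effector-edited); a flag drops them instead.

Substitution handling is a genuinely open design point: the upstream
method's description can be read either as counting substitution-only reads
as edits or as merely tolerating them. The package implements both; the
default is `ignore` (tolerate). The deciding argument is quantitative: the
reported quantity is an *indel* frequency, and counting substitution-only
reads as edits makes the zero-background property unattainable at any
realistic sequencing error rate, because a specific substitution type is
too rare for its exact event list to recur in a depth-1000 control (≈126
type classes per pair at ~10⁻⁵ each), so presence-based subtraction cannot
remove it. Under `count_in_frame`, in-frame substitutions join the repair-
type key as pseudo-events so subtraction still removes recurring ones.

Edited reads are grouped into repair types keyed by their exact sorted
event list and serialized as `[(start, len)]:count`; insertions carry an
`I` suffix plus the inserted bases (`(22, 3I:ACG)`) so that serialization
round-trips losslessly.

Background subtraction is per pair and presence-based: any repair type
whose event list also occurs in the same pair's control catalogue is moved
to the unedited tally; types unique to the experimental sample are kept.
Per-pair (rather than library-wide) matching is the stricter reading of a
"corresponding control group". The final frequency is the plain ratio
edited / (edited + unedited) — no further normalization — and pairs with
edited + unedited ≤ 300 reads are excluded from all downstream summaries,
never imputed.

## Profiling and statistics

PAM preference tables average included pairs' frequencies per (possibly
degenerate) PAM group — the heatmap view. Pathway classification calls a
repair type MMEJ iff it is a single deletion whose junction is flanked by
identical sequences of length ≥ 2 in the reference; everything else
(insertions, multi-event types, repeat-free deletions) is NHEJ. This is a
deliberate operational narrowing: mixed-event MMEJ is not distinguishable
from NHEJ without outcome-level repair modelling.

Mann–Whitney U is two-tailed; for n_A + n_B ≤ 16 the p value is computed
by exact enumeration of all group assignments of the pooled values (valid
under ties; C(16, 8) = 12 870 keeps it instant), otherwise by the
tie-corrected normal approximation. Kruskal–Wallis uses the tie-corrected H
(via scipy) and Dunn's post hoc z tests are computed from pooled midranks
with the tie correction and Bonferroni adjustment by default (the upstream
analysis did not name its adjustment). Effector ranking splits at a mean
frequency of 0.20 — a descriptive reporting convention, not inference; both
mean and median are available since published category splits have used
each.

## MOI planning

MOI = −ln(1 − P(+)) under the Poisson model; MOI 0.5 and 0.7 correspond to
39% and 50% FACS-positive. The titration standard curve is fit through the
origin on the MOI scale (MOI is additive in virus dose; the positive
fraction saturates), and the recommended volume scales with the cell count
relative to the titration plating (default 2 × 10⁵ cells), keeping dose per
cell conserved.

## Problem sizes and determinism

The package's reference experiment — used by the test suite and
`scripts/acceptance.py` — is a 200-pair TTTV library at depth 1000 per pair
per sample, the scale at which per-pair binomial noise (σ ≈ 0.015) sits
comfortably inside the recovery tolerances while a full run stays under a
minute. All randomness flows through numpy `SeedSequence` children of a
single seed; identical seeds give byte-identical FASTQ/TSV outputs.

## Known limitations

- Exact-match demultiplexing discards ~5% of reads as invalid at Q30-level
  noise; this is faithful to the strict-identification design but wastes
  depth.
- The aligner is exhaustive-enumeration-exact but pure Python; throughput
  (~10⁴ distinct alignments/min) is adequate for amplicon screens because
  identical target regions are cached, not for genome-scale data.
- The MMEJ/NHEJ boundary at single deletions with ≥ 2-nt flanks is a
  convention; 1-nt microhomologies are indistinguishable from blunt NHEJ.
- The generator's truth is per-molecule; it does not model editing-rate
  heterogeneity across cells, integration-site effects, or PCR bias.
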