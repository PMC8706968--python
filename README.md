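# paircut

Design, simulation and analysis of **paired guide–target Cas12a screens** —
the high-throughput assay in which every lentiviral construct carries both a
crRNA expression cassette and its own 42-nt synthetic target, so that each
transduced cell edits its integrated target in cis and deep sequencing of
the integrated amplicons reads out per-guide editing activity.

The package is aimed at people building or analysing such screens: it
designs the 142-nt oligo libraries (PAM scanning over IUPAC-degenerate
patterns, guide filtering, barcode assignment), simulates realistic amplicon
sequencing data with known ground truth, and implements the screen's core
computation — demultiplexing, indel calling, repair-type cataloguing,
control-background subtraction and indel frequencies — plus downstream PAM
preference, MMEJ/NHEJ classification, replicate correlation and the usual
nonparametric comparisons.

## The model

Each amplicon is

```
fwd_const(20) | handle(19) | spacer(23) | polyT(6) | barcode(12) | target(42) | rev_const(20)   = 142 nt
```

with the target = 4-nt PAM + 23-nt protospacer + 15-nt context, coordinates
0-based from the PAM's 5′ end. Reads are assigned by exact match of the
42-nt crRNA-encoding sequence (handle + spacer) *and* the 12-nt barcode;
reads with a recognized barcode but a mutated crRNA region are invalid.
The target region is globally aligned (affine gaps, left-aligned indels)
and classified in two rounds: indels inside the 42-bp primary frame are
recognized, then reads whose indels are all ≤ 3 bp and outside the 8-bp
frame centred between the staggered nicks (positions 22/27) are refiled as
background. Edited reads form repair types `[(start, len)]:count`; any type
that also occurs in the matched no-effector control is subtracted, and

```
indel frequency = edited / (edited + unedited),   pairs with ≤ 300 reads excluded.
```

MOI planning uses the Poisson model MOI = −ln(1 − P(+)): transducing at
MOI 0.5–0.7 means sorting 39–50% fluorescence-positive cells.

## Worked example

```python
import numpy as np
import paircut as pc
from paircut.calling import (CallingConfig, LibraryIndex, call_reads,
                             indel_frequency, subtract_background,
                             serialize_repair_type)

genes = pc.synthesize_gene_sequences(4, 1500, seed=7)
lib = pc.design_library(genes, ["TTTV"], seed=7, max_pairs=12)
rng = np.random.default_rng(8)
rates = {p.pair_id: float(rng.uniform(0.1, 0.5)) for p in lib}

ds = pc.generate_dataset(lib, pc.EffectorModel("demo", {}), pc.NoiseModel(),
                         depth_per_pair=600, seed=9, per_pair_rates=rates)

cfg, idx = CallingConfig(), LibraryIndex(lib)
exp, _ = call_reads((r.sequence for r in ds.experimental), idx, cfg)
ctrl, _ = call_reads((r.sequence for r in ds.control), idx, cfg)
final = subtract_background(exp, ctrl)
for p in lib[:5]:
    prof = final[p.pair_id]
    top = prof.repair_types()[0]
    print(p.pair_id, f"{rates[p.pair_id]:.3f}", f"{indel_frequency(prof, cfg):.3f}",
          serialize_repair_type(top))
```

prints (true rate, estimated frequency, most common repair type):

```
gene0000_00 0.231 0.242 [(26, 1)]:8
gene0000_01 0.495 0.455 [(23, 4)]:16
gene0000_02 0.227 0.219 [(8, 24)]:9
gene0000_03 0.415 0.391 [(26, 1)]:17
gene0000_04 0.448 0.405 [(25, 1)]:18
```

The estimated frequencies track the simulated per-pair editing rates to
within binomial noise at depth 600, and the top repair types cluster at the
staggered cut site (positions ~22–27), e.g. `[(23, 4)]:16` is a 4-bp
deletion of positions 23–26 seen in 16 reads.

The same steps are available as a shell pipeline:

```sh
paircut design --fasta genes.fasta --pam-preset lib-a --seed 1 -o out/
paircut simulate --library out/library.tsv --depth 1000 --seed 1 -o out/
paircut call --exp out/experimental.fastq --ctrl out/control.fastq \
             --library out/library.tsv -o out/
paircut profile --profiles out/profiles.tsv --library out/library.tsv -o out/
paircut plan --titration titration.tsv --target-moi 0.6 --cells 4e6
```

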