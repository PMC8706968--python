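"""File formats, configuration and logging shared across the pipeline.

FASTA/FASTQ go through Bio.SeqIO (gzip transparently supported for FASTQ);
tables are tab-separated with a header row, UTF-8, '.' decimal.
"""

from __future__ import annotations

import gzip
import logging
import sys
from pathlib import Path
from typing import Iterable, List, NamedTuple, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("paircut")


class FastqRead(NamedTuple):
    id: str
    sequence: str
    quality: str


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> List[Tuple[str, str]]:
    """(id, sequence) records, sequences uppercased."""
    records = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append((rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with _open_text(path, "wt") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_fastq(path) -> List[FastqRead]:
    """4-line FASTQ records; raises with the record index on malformed input."""
    reads = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                reads.append(FastqRead(rec.id, str(rec.seq), qual))
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ in {path} near record {len(reads) + 1}: {exc}"
            ) from exc
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            if len(r.sequence) != len(r.quality):
                raise ValueError(f"sequence/quality length mismatch for read {r.id}")
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def setup_logging(level: str = "INFO", log_file=None) -> None:
    handlers: list = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
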