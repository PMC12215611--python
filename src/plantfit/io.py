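"""Readers and writers for the plain-text formats the pipeline exchanges.

Mapping tables, count matrices and design tables travel as TSV/CSV;
synthetic reads as FASTQ (optionally gzipped); protein families as FASTA
plus a TSV metadata sidecar.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import validate_design

_DNA = np.array(list("ACGT"))


def write_mapping_tsv(mapping: pd.DataFrame, path) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_mapping_tsv(path) -> pd.DataFrame:
    mapping = pd.read_csv(path, sep="\t")
    mapping["locus_tag"] = mapping["locus_tag"].where(mapping["locus_tag"].notna(), None)
    mapping["central"] = mapping["central"].astype(bool)
    return mapping


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="barcode")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path))


def _open_maybe_gz(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_sample_fastq(
    sample_counts: pd.Series,
    path,
    anchor: str = "GTCGAC",
    read_length: int = 50,
    max_offset: int = 10,
    seed: int = 0,
) -> int:
    """Write synthetic amplicon reads for one sample.

    Each read is random filler, the anchor, the 20-mer barcode, then filler
    to ``read_length``.  The random prefix is re-drawn if it would create a
    spurious earlier anchor occurrence, so extraction recovers every read's
    barcode exactly.  Returns the number of reads written.
    """
    rng = np.random.default_rng(seed)
    bc_len = len(sample_counts.index[0])
    if read_length < max_offset + len(anchor) + bc_len:
        raise ValueError("read_length too short for offset + anchor + barcode")
    n_written = 0
    with _open_maybe_gz(path, "w") as fh:
        records = []
        for barcode, count in sample_counts.items():
            for _ in range(int(count)):
                while True:
                    offset = int(rng.integers(0, max_offset + 1))
                    prefix = "".join(rng.choice(_DNA, size=offset))
                    tail_len = read_length - offset - len(anchor) - bc_len
                    tail = "".join(rng.choice(_DNA, size=tail_len))
                    read = prefix + anchor + barcode + tail
                    if read.find(anchor) == offset:
                        break
                n_written += 1
                records.append(
                    SeqRecord(
                        Seq(read),
                        id=f"read_{n_written}",
                        description="",
                        letter_annotations={"phred_quality": [40] * len(read)},
                    )
                )
        SeqIO.write(records, fh, "fastq")
    return n_written


def read_fastq_sequences(path) -> Iterable[str]:
    """Yield read sequences (uppercase strings) from a FASTQ file."""
    with _open_maybe_gz(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ril_csv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index_label="line")


def read_ril_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="line")
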