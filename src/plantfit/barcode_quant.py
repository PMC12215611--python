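"""Barcode extraction, counting, and usability filtering.

Reads from a barcode amplicon run carry a fixed 6-nt anchor immediately
upstream of a random 20-mer barcode.  Extraction locates the first exact
anchor occurrence in each read and takes the following 20 bases; counting
matches barcodes exactly against a mapping table (barcode -> insertion
site and gene); filtering keeps barcodes that are usable for fitness
estimation (in a gene body, centrally inserted, adequately covered in the
soil reference samples).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io
from .design import soil_samples

__all__ = [
    "ExtractionResult",
    "extract_barcodes",
    "extract_from_fastq",
    "count_barcodes",
    "filter_barcodes",
]


@dataclass
class ExtractionResult:
    """Barcode multiset for one sample plus discard bookkeeping."""

    barcodes: Counter
    n_reads: int
    n_discarded: int


def _validate_anchor(anchor: str) -> None:
    if len(anchor) != 6:
        raise ValueError(f"anchor must be a 6-mer, got {anchor!r}")
    if set(anchor) - set("ACGT"):
        raise ValueError(f"anchor contains ambiguous bases: {anchor!r}")


def extract_barcodes(
    reads: Iterable[str],
    anchor: str = "GTCGAC",
    barcode_length: int = 20,
) -> ExtractionResult:
    """Extract barcodes from an iterable of read sequences.

    The first exact occurrence of ``anchor`` is located in each read and
    the following ``barcode_length`` bases are emitted.  Reads without the
    anchor, or too short to hold a full barcode after it, are discarded
    and counted.
    """
    _validate_anchor(anchor)
    counts: Counter = Counter()
    n_reads = n_discarded = 0
    for read in reads:
        n_reads += 1
        pos = read.find(anchor)
        if pos < 0:
            n_discarded += 1
            continue
        start = pos + len(anchor)
        barcode = read[start : start + barcode_length]
        if len(barcode) < barcode_length:
            n_discarded += 1
            continue
        counts[barcode] += 1
    return ExtractionResult(barcodes=counts, n_reads=n_reads, n_discarded=n_discarded)


def extract_from_fastq(path, anchor: str = "GTCGAC", barcode_length: int = 20) -> ExtractionResult:
    """Extract barcodes from a FASTQ file (optionally gzipped)."""
    return extract_barcodes(io.read_fastq_sequences(Path(path)), anchor, barcode_length)


def count_barcodes(
    samples: Mapping[str, Counter],
    mapping: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Count extracted barcodes against the mapping table.

    Returns the barcodes x samples integer matrix (row order follows the
    mapping table) and a per-sample tally of reads whose barcode is absent
    from the map.  An empty sample yields an all-zero column.
    """
    if len(mapping) == 0:
        raise ValueError("mapping table is empty")
    index = pd.Index(mapping["barcode"], name="barcode")
    known = set(index)
    cols, unmapped = {}, {}
    for sample_id, multiset in samples.items():
        col = pd.Series(0, index=index, dtype=int)
        miss = 0
        for barcode, n in multiset.items():
            if barcode in known:
                col.loc[barcode] += n
            else:
                miss += n
        cols[sample_id] = col
        unmapped[sample_id] = miss
    counts = pd.DataFrame(cols)
    return counts, unmapped


def filter_barcodes(
    counts: pd.DataFrame,
    mapping: pd.DataFrame,
    design: pd.DataFrame,
    min_reference_reads: float = 3,
    central_only: bool = True,
) -> pd.DataFrame:
    """Retain barcodes usable for fitness estimation.

    A barcode is kept when it carries a locus tag, is centrally inserted
    (if ``central_only``), and its mean raw count over the soil reference
    samples is at least ``min_reference_reads``.
    """
    soil = soil_samples(design)
    if not soil:
        raise ValueError("design contains no soil (reference) samples")
    meta = mapping.set_index("barcode").loc[counts.index]
    has_gene = meta["locus_tag"].notna()
    keep = has_gene & (meta["central"] | (not central_only))
    soil_mean = counts[soil].mean(axis=1)
    keep &= soil_mean >= min_reference_reads
    return counts.loc[keep.to_numpy()]
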