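"""Strain- and gene-level fitness scores against the soil reference.

Because bacteria colonize plants from the surrounding substrate, the soil
samples play the role of the T0 control: a barcode's fitness in a sample
is the log2 ratio of its (pseudocounted) observed count to the count
expected from its mean depth-normalized soil abundance.  Gene fitness is
an inverse-variance weighted mean of the gene's member strains, followed
by per-sample median centering so a typical (neutral) gene scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import soil_samples

__all__ = [
    "GeneFitnessTable",
    "reference_profile",
    "strain_fitness",
    "gene_fitness",
]


def reference_profile(counts: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-barcode reference abundance: mean of depth-normalized soil counts."""
    soil = soil_samples(design)
    soil = [s for s in soil if s in counts.columns]
    if not soil:
        raise ValueError("no soil samples present in the count matrix")
    sub = counts[soil]
    depths = sub.sum(axis=0)
    if (depths == 0).all():
        raise ValueError("all soil samples are empty")
    props = sub / depths
    ref = props.mean(axis=1)
    if ref.sum() == 0:
        raise ValueError("reference profile is all zero")
    ref.name = "reference"
    return ref


def strain_fitness(
    counts: pd.DataFrame,
    reference: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-barcode log2 fitness versus the reference expectation.

    ``f(b, s) = log2((n(b,s) + pc) / (depth(s) * ref(b) + pc))``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ref = reference.loc[counts.index].to_numpy()[:, None]
    depth = counts.sum(axis=0).to_numpy()[None, :]
    expected = depth * ref
    f = np.log2((counts.to_numpy() + pseudocount) / (expected + pseudocount))
    return pd.DataFrame(f, index=counts.index, columns=counts.columns)


@dataclass
class GeneFitnessTable:
    """Genes x samples fitness scores (log2, median-centered per sample)."""

    scores: pd.DataFrame
    n_barcodes: pd.Series
    pseudocount: float
    centering: str = "median"


def gene_fitness(
    strain_table: pd.DataFrame,
    mapping: pd.DataFrame,
    counts: pd.DataFrame,
    reference: pd.Series,
    pseudocount: float = 1.0,
    center: bool = True,
) -> GeneFitnessTable:
    """Aggregate strain fitness to gene fitness.

    Per gene and sample, an inverse-variance weighted mean of member-strain
    fitness with Poisson-motivated weights
    ``w(b, s) = 1 / (1/(1 + n(b,s)) + 1/(1 + depth(s) * ref(b)))``,
    then per-sample centering so the median gene fitness is 0.
    Genes with no retained barcode are absent from the result.
    """
    tags = mapping.set_index("barcode")["locus_tag"].loc[strain_table.index]
    if tags.isna().any():
        raise ValueError("every retained barcode must carry a locus_tag")
    ref = reference.loc[strain_table.index].to_numpy()[:, None]
    depth = counts.sum(axis=0).loc[strain_table.columns].to_numpy()[None, :]
    n = counts.loc[strain_table.index, strain_table.columns].to_numpy()
    w = 1.0 / (1.0 / (1.0 + n) + 1.0 / (1.0 + depth * ref))
    fw = strain_table.to_numpy() * w

    gene_index = pd.Index(tags.to_numpy(), name="gene")
    w_sum = pd.DataFrame(w, index=gene_index, columns=strain_table.columns).groupby(level=0).sum()
    fw_sum = pd.DataFrame(fw, index=gene_index, columns=strain_table.columns).groupby(level=0).sum()
    scores = fw_sum / w_sum
    n_barcodes = tags.groupby(tags).size()
    n_barcodes.index.name = "gene"
    n_barcodes.name = "n_barcodes"
    if center:
        scores = scores - scores.median(axis=0)
    return GeneFitnessTable(
        scores=scores,
        n_barcodes=n_barcodes.loc[scores.index],
        pseudocount=pseudocount,
        centering="median" if center else "none",
    )
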