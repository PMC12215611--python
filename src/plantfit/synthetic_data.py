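"""Generators for every input the pipeline consumes.

The colonization screen's statistical structure is emulated end to end:

* a barcoded transposon library with a Poisson number of insertions per
  gene (positions uniform in the central 10-90% of the gene body) and
  lognormal inoculum abundances;
* sequencing counts per sample: soil samples are a multinomial draw from
  the inoculum (times any soil effect), while plant samples first pass
  through a per-sample founder bottleneck — a limited number of
  colonization events subsamples the library — before habitat-specific
  multiplicative fitness effects and multinomial sequencing;
* a recombinant inbred line (RIL) population over five chromosomes with
  Poisson crossovers, phenotyped by the glucosinolate rule engine;
* a protein family containing one designed tight clade, for the
  clade-calling procedure;
* Hill-shaped dose-response growth data.

Every generator takes a seed and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import HABITATS
from .host_genetics import GslGenotype, RILPopulation, gsl_product

__all__ = [
    "SimParams",
    "TrueEffects",
    "ProteinFamily",
    "simulate_library",
    "simulate_counts",
    "simulate_ril_population",
    "simulate_protein_family",
    "simulate_dose_response",
]

_DNA = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimParams:
    """Parameters of the barcoded-library generator.

    ``insertions_per_gene_mean`` defaults to 8.5, the per-gene insertion
    density of the screen this generator emulates.  ``inoculum_logsd`` is
    the standard deviation of barcode abundance in log2 units.
    ``bottleneck_founders`` is the number of barcodes seeding each plant
    sample (None disables the bottleneck).
    """

    n_genes: int = 500
    insertions_per_gene_mean: float = 8.5
    read_depth: int = 100_000
    inoculum_logsd: float = 1.0
    bottleneck_founders: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.insertions_per_gene_mean <= 0:
            raise ValueError("insertions_per_gene_mean must be > 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.inoculum_logsd <= 0:
            raise ValueError("inoculum_logsd must be > 0")
        if self.bottleneck_founders is not None and self.bottleneck_founders < 1:
            raise ValueError("bottleneck_founders must be >= 1 or None")


@dataclass
class TrueEffects:
    """Ground-truth fitness effects: gene -> habitat -> log2 effect.

    Unlisted genes and habitats are neutral (effect 0).  The soil effect
    defaults to 0 and may be set explicitly.
    """

    effects: dict = field(default_factory=dict)

    def get(self, gene: str, habitat: str) -> float:
        return float(self.effects.get(gene, {}).get(habitat, 0.0))

    def genes(self) -> list[str]:
        return list(self.effects)

    def array(self, locus_tags: Sequence, habitat: str) -> np.ndarray:
        """Per-barcode effect vector for one habitat (0 for intergenic)."""
        return np.array(
            [
                0.0 if tag is None or tag != tag else self.get(tag, habitat)
                for tag in locus_tags
            ]
        )


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_DNA, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_library(
    params: SimParams,
    gene_length: int = 1000,
    intergenic_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a barcode mapping table and an inoculum abundance vector.

    Each gene receives a Poisson(``insertions_per_gene_mean``) number of
    unique 20-mer barcodes with insertion positions uniform in the central
    10-90% of the gene body.  A small fraction of additional barcodes land
    between genes (no locus tag, not central).  Abundances are lognormal
    (log2 sd ``inoculum_logsd``), normalized to proportions.

    Returns ``(mapping, inoculum)``: the mapping table has columns
    ``barcode, scaffold, position, strand, locus_tag, central``; the
    inoculum is indexed by barcode.
    """
    rng = np.random.default_rng(params.seed)
    spacing = 200
    n_per_gene = rng.poisson(params.insertions_per_gene_mean, size=params.n_genes)
    total_genic = int(n_per_gene.sum())
    n_intergenic = int(round(total_genic * intergenic_fraction))
    total = total_genic + n_intergenic
    if total == 0:
        raise ValueError("simulated library contains zero barcodes; increase "
                         "n_genes or insertions_per_gene_mean")

    rows = []
    for g in range(params.n_genes):
        start = 1 + g * (gene_length + spacing)
        lo = start + int(0.10 * gene_length)
        hi = start + int(0.90 * gene_length)
        for _ in range(n_per_gene[g]):
            rows.append(
                {
                    "scaffold": "scaffold_1",
                    "position": int(rng.integers(lo, hi + 1)),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "locus_tag": f"gene_{g + 1:04d}",
                    "central": True,
                }
            )
    genome_end = params.n_genes * (gene_length + spacing)
    for _ in range(n_intergenic):
        g = int(rng.integers(0, params.n_genes))
        gap_start = 1 + g * (gene_length + spacing) + gene_length
        rows.append(
            {
                "scaffold": "scaffold_1",
                "position": int(rng.integers(gap_start, min(gap_start + spacing, genome_end) + 1)),
                "strand": "+" if rng.random() < 0.5 else "-",
                "locus_tag": None,
                "central": False,
            }
        )
    mapping = pd.DataFrame(rows)
    mapping.insert(0, "barcode", _random_barcodes(rng, total))
    abundance = np.exp2(rng.normal(0.0, params.inoculum_logsd, size=total))
    inoculum = pd.Series(abundance / abundance.sum(), index=mapping["barcode"], name="inoculum")
    return mapping, inoculum


def simulate_counts(
    mapping: pd.DataFrame,
    inoculum: pd.Series,
    design: pd.DataFrame,
    effects: TrueEffects,
    params: SimParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a barcodes x samples count matrix under the generative model.

    Soil samples are multinomial(``read_depth``) draws from the inoculum
    scaled by ``2**soil_effect``.  Plant samples first subsample
    ``bottleneck_founders`` barcodes without replacement (weighted by the
    inoculum), then grow deterministically by ``2**habitat_effect`` before
    multinomial sequencing.
    """
    known = set(mapping["locus_tag"].dropna())
    unknown = [g for g in effects.genes() if g not in known]
    if unknown:
        raise ValueError(f"effects refer to genes absent from the map: {unknown[:5]}")
    n = len(mapping)
    if params.bottleneck_founders is not None and params.bottleneck_founders > n:
        raise ValueError(
            f"bottleneck_founders={params.bottleneck_founders} exceeds library size {n}"
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    base = inoculum.loc[mapping["barcode"]].to_numpy()
    p_founder = base / base.sum()
    tags = mapping["locus_tag"].to_numpy(dtype=object)

    cols = {}
    for _, row in design.iterrows():
        habitat = row["habitat"]
        w = base * np.exp2(effects.array(tags, habitat))
        if habitat != "soil" and params.bottleneck_founders is not None:
            founders = rng.choice(n, size=params.bottleneck_founders,
                                  replace=False, p=p_founder)
            mask = np.zeros(n, dtype=bool)
            mask[founders] = True
            w = np.where(mask, w, 0.0)
        cols[row["sample_id"]] = rng.multinomial(params.read_depth, w / w.sum())
    return pd.DataFrame(cols, index=pd.Index(mapping["barcode"], name="barcode"))


#: Default causal-locus placement: ESP-like on chr1, AOP3-like on chr4,
#: MAM-like on chr5 (middle marker of each chromosome).
def default_causal_loci(markers_per_chrom: int) -> dict:
    mid = markers_per_chrom // 2 + 1
    return {
        "esp": f"c1m{mid:02d}",
        "aop3": f"c4m{mid:02d}",
        "mam": f"c5m{mid:02d}",
    }


def simulate_ril_population(
    n_lines: int = 98,
    markers_per_chrom: int = 20,
    recomb_per_chrom: float = 1.5,
    causal_loci: Mapping[str, str] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> RILPopulation:
    """Simulate a Col-0 x Ler-1 RIL population over five chromosomes.

    Each line carries Poisson(``recomb_per_chrom``) crossovers per
    chromosome at uniform positions; genotypes are homozygous 'C' or 'L'.
    The phenotype of each line is computed by the glucosinolate rule engine
    from its alleles at the three causal loci (ESP-, MAM- and AOP3-like),
    which must lie on distinct chromosomes.
    """
    if n_lines < 1 or markers_per_chrom < 1:
        raise ValueError("n_lines and markers_per_chrom must be >= 1")
    if recomb_per_chrom < 0:
        raise ValueError("recomb_per_chrom must be >= 0")
    rng = np.random.default_rng(seed)

    markers, chroms, positions = [], [], []
    for c in range(1, 6):
        for m in range(1, markers_per_chrom + 1):
            markers.append(f"c{c}m{m:02d}")
            chroms.append(c)
            positions.append(float(m) / (markers_per_chrom + 1))
    marker_map = pd.DataFrame(
        {"marker": markers, "chromosome": chroms, "position": positions}
    )
    if causal_loci is None:
        causal_loci = default_causal_loci(markers_per_chrom)
    for key in ("esp", "mam", "aop3"):
        if key not in causal_loci:
            raise ValueError(f"causal_loci must define {key!r}")
        if causal_loci[key] not in markers:
            raise ValueError(f"causal locus {causal_loci[key]!r} not in marker map")
    causal_chroms = {
        int(marker_map.set_index("marker").loc[causal_loci[k], "chromosome"])
        for k in ("esp", "mam", "aop3")
    }
    if len(causal_chroms) != 3:
        raise ValueError("the three causal loci must lie on distinct chromosomes")

    pos_by_chrom = {
        c: marker_map.loc[marker_map["chromosome"] == c, "position"].to_numpy()
        for c in range(1, 6)
    }
    geno = np.empty((n_lines, len(markers)), dtype=object)
    for i in range(n_lines):
        offset = 0
        for c in range(1, 6):
            pos = pos_by_chrom[c]
            allele = rng.random() < 0.5  # True = Ler
            n_x = rng.poisson(recomb_per_chrom)
            breaks = np.sort(rng.random(n_x))
            # allele at a marker flips once per crossover to its left
            crossings = np.searchsorted(breaks, pos)
            states = allele ^ (crossings % 2).astype(bool)
            geno[i, offset : offset + len(pos)] = np.where(states, "L", "C")
            offset += len(pos)
    genotypes = pd.DataFrame(
        geno,
        index=[f"RIL_{i + 1:03d}" for i in range(n_lines)],
        columns=markers,
    )
    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes = genotypes.mask(mask)

    phen = []
    for line in genotypes.index:
        alleles = {k: genotypes.loc[line, causal_loci[k]] for k in ("esp", "mam", "aop3")}
        if any(a != a for a in alleles.values()):  # missing causal call
            phen.append(np.nan)
            continue
        g = GslGenotype.from_alleles(alleles["esp"], alleles["mam"], alleles["aop3"])
        phen.append(gsl_product(g).toxicity)
    phenotypes = pd.Series(phen, index=genotypes.index, name="phenotype")
    return RILPopulation(
        genotypes=genotypes,
        marker_map=marker_map,
        phenotypes=phenotypes,
        causal_loci=dict(causal_loci),
    )


@dataclass
class ProteinFamily:
    """A simulated protein family with one designed monophyletic clade."""

    sequences: dict
    metadata: pd.DataFrame  # seq_id, genome_id, class, is_anchor
    clade_ids: list


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _AA[_AA != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def simulate_protein_family(
    n_background: int = 15,
    clade_size: int = 6,
    clade_divergence: float = 0.05,
    background_divergence: float = 0.4,
    seed: int = 0,
    length: int = 500,
) -> ProteinFamily:
    """Simulate a protein family with a designed tight clade.

    All sequences derive from one ancestral peptide.  Background members
    are mutated independently at ``background_divergence``; the clade
    descends from a shared clade ancestor at background-level distance
    from the rest and splits into two lineages, each headed by one anchor
    (mirroring functionally tested genes from two different genomes on
    opposite sides of the clade root), so the anchors' most recent common
    ancestor is the clade root.  Remaining members alternate between the
    two lineages; total within-clade divergence is ``clade_divergence``.
    """
    for name, div in (("clade_divergence", clade_divergence),
                      ("background_divergence", background_divergence)):
        if not 0.0 < div < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {div}")
    if clade_divergence >= background_divergence:
        raise ValueError("clade_divergence must be < background_divergence")
    if clade_size < 1:
        raise ValueError("clade_size must be >= 1")
    rng = np.random.default_rng(seed)
    root = rng.choice(_AA, size=length)
    clade_ancestor = _mutate(rng, root, background_divergence)
    # two anchored lineages under the clade root
    lineages = [
        _mutate(rng, clade_ancestor, clade_divergence / 2.0),
        _mutate(rng, clade_ancestor, clade_divergence / 2.0),
    ]

    classes = ("Alphaproteobacteria", "Betaproteobacteria", "Gammaproteobacteria")
    seqs, meta = {}, []
    for i in range(clade_size):
        sid = f"clade_{i + 1:02d}"
        lineage = lineages[i % 2] if clade_size > 1 else lineages[0]
        seqs[sid] = "".join(_mutate(rng, lineage, clade_divergence / 2.0))
        meta.append(
            {
                "seq_id": sid,
                "genome_id": f"genome_c{i + 1:02d}",
                "class": classes[i % 3],
                "is_anchor": i < 2,
            }
        )
    for i in range(n_background):
        sid = f"bg_{i + 1:02d}"
        seqs[sid] = "".join(_mutate(rng, root, background_divergence))
        meta.append(
            {
                "seq_id": sid,
                "genome_id": f"genome_b{i + 1:02d}",
                "class": classes[i % 3],
                "is_anchor": False,
            }
        )
    return ProteinFamily(
        sequences=seqs,
        metadata=pd.DataFrame(meta),
        clade_ids=[f"clade_{i + 1:02d}" for i in range(clade_size)],
    )


def simulate_additive_tree(n_taxa: int, seed: int | np.random.Generator = 0):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf distance matrix (an additive matrix by construction).

    Returns ``(tree, distance_matrix)`` with skbio containers.
    """
    from skbio import DistanceMatrix, TreeNode

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(0.1, 2.0))
    tree = TreeNode(children=nodes)
    tips = sorted(t.name for t in tree.tips())
    d = np.zeros((len(tips), len(tips)))
    for x in range(len(tips)):
        for y in range(x + 1, len(tips)):
            d[x, y] = d[y, x] = tree.find(tips[x]).distance(tree.find(tips[y]))
    return tree, DistanceMatrix(d, tips)


def simulate_dose_response(
    top: float = 1.0,
    ic50: float = 10.0,
    hill: float = 2.0,
    doses: Sequence[float] | None = None,
    noise_sd: float = 0.02,
    replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate growth inhibition along a dose gradient.

    OD(c) = top / (1 + (c / ic50) ** hill) plus Gaussian noise, floored at
    zero.  Default doses are a 1.5-fold dilution series spanning the IC50.
    Returns a frame with columns ``dose, replicate, od``.
    """
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be > 0")
    if doses is None:
        doses = [0.0] + list(ic50 * 1.5 ** np.arange(-5, 7, dtype=float))
    doses = np.asarray(doses, dtype=float)
    if (doses < 0).any():
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for c in doses:
        expected = top / (1.0 + (c / ic50) ** hill) if c > 0 else top
        for r in range(replicates):
            od = max(0.0, expected + rng.normal(0.0, noise_sd))
            rows.append({"dose": float(c), "replicate": r + 1, "od": od})
    return pd.DataFrame(rows)
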