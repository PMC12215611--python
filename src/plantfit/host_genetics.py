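"""Host-genetics analyses: the glucosinolate rule engine and the RIL scan.

Two tools live here.  The first is a combinatorial rule engine for aliphatic
glucosinolate breakdown chemistry in a Col-0 x Ler-1 *Arabidopsis thaliana*
cross.  Three unlinked loci differ between the parents and jointly determine
the dominant breakdown product of a line:

* **ESP** (epithiospecifier protein) — when functional (Ler-1 allele) it
  diverts myrosinase-mediated breakdown towards nitriles; when absent
  (Col-0 allele) the spontaneous product is an isothiocyanate (ITC).
* **MAM** (chain elongation, GSL-Elong) — the Col-0 *MAM1* allele makes
  longer, four-carbon (4C) glucosinolates; the Ler-1 *MAM2* allele makes
  three-carbon (3C) ones.
* **AOP3** (side-chain modification) — active in Ler-1 shoots, converting
  the methylsulfinyl (MSO) side chain to a hydroxyl; inactive in Col-0.

Hydroxyl-bearing isothiocyanates cyclize spontaneously (3C to
1,3-Oxazinane-2-thione, 4C to 1,3-Oxazepane-2-thione), so they are reported
as their cyclization products.  Toxicity towards the bacterial efflux-pump
deletion mutant follows the product: all nitriles are non-toxic; 4MSO-ITC
(sulforaphane), 3MSO-ITC (iberin) and 1,3-Oxazepane-2-thione inhibit only
the pump mutant (``d90_toxic``); 1,3-Oxazinane-2-thione inhibits the wild
type too (``WT_toxic``).

The second tool is an allele-fraction linkage scan over a recombinant
inbred line (RIL) population: within a phenotype group the fraction of
Ler-1 alleles is computed at each marker, tested against the Mendelian 0.5
with an exact binomial test, and runs of strongly skewed markers are merged
into candidate intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GslGenotype",
    "GslProduct",
    "RILPopulation",
    "gsl_product",
    "enumerate_products",
    "allele_fraction_scan",
    "peak_intervals",
]

TOXICITY_CLASSES = ("non_toxic", "d90_toxic", "WT_toxic")

#: Fixed product -> toxicity lookup.
PRODUCT_TOXICITY = {
    "4MSO-ITC": "d90_toxic",
    "3MSO-ITC": "d90_toxic",
    "1,3-Oxazepane-2-thione": "d90_toxic",
    "1,3-Oxazinane-2-thione": "WT_toxic",
    "4MSO-Nitrile": "non_toxic",
    "3MSO-Nitrile": "non_toxic",
    "4OHB-Nitrile": "non_toxic",
    "3OHP-Nitrile": "non_toxic",
}


@dataclass(frozen=True)
class GslGenotype:
    """Allelic state at the three glucosinolate loci.

    ``esp``: "functional" (Ler-1) or "non_functional" (Col-0);
    ``mam``: "MAM1" (Col-0, 4C chains) or "MAM2" (Ler-1, 3C chains);
    ``aop3``: "active" (Ler-1) or "inactive" (Col-0).
    """

    esp: str
    mam: str
    aop3: str

    def __post_init__(self) -> None:
        if self.esp not in ("functional", "non_functional"):
            raise ValueError(f"esp must be functional/non_functional, got {self.esp!r}")
        if self.mam not in ("MAM1", "MAM2"):
            raise ValueError(f"mam must be MAM1/MAM2, got {self.mam!r}")
        if self.aop3 not in ("active", "inactive"):
            raise ValueError(f"aop3 must be active/inactive, got {self.aop3!r}")

    @classmethod
    def from_alleles(cls, esp: str, mam: str, aop3: str) -> "GslGenotype":
        """Build from parental allele codes ('C' for Col-0, 'L' for Ler-1)."""
        for a in (esp, mam, aop3):
            if a not in ("C", "L"):
                raise ValueError(f"allele codes must be 'C' or 'L', got {a!r}")
        return cls(
            esp="functional" if esp == "L" else "non_functional",
            mam="MAM1" if mam == "C" else "MAM2",
            aop3="active" if aop3 == "L" else "inactive",
        )


#: Parental genotypes, for convenience.
COL0 = GslGenotype(esp="non_functional", mam="MAM1", aop3="inactive")
LER1 = GslGenotype(esp="functional", mam="MAM2", aop3="active")


@dataclass(frozen=True)
class GslProduct:
    """A glucosinolate breakdown product and its bacterial toxicity class."""

    name: str
    precursor_chain: str  # "3C" or "4C"
    side_chain: str  # "MSO" or "hydroxyl"
    moiety: str  # "isothiocyanate" or "nitrile"
    cyclized_name: str | None
    toxicity: str


def gsl_product(genotype: GslGenotype) -> GslProduct:
    """Dominant breakdown product of a three-locus glucosinolate genotype.

    Chain length follows MAM (MAM1 -> 4C, MAM2 -> 3C), side chain follows
    AOP3 (active -> hydroxyl, inactive -> MSO), and the breakdown moiety
    follows ESP (functional -> nitrile, otherwise isothiocyanate).
    Hydroxyl isothiocyanates are reported as their spontaneous cyclization
    products.
    """
    chain = "4C" if genotype.mam == "MAM1" else "3C"
    side = "hydroxyl" if genotype.aop3 == "active" else "MSO"
    moiety = "nitrile" if genotype.esp == "functional" else "isothiocyanate"

    if side == "MSO":
        base = "4MSO" if chain == "4C" else "3MSO"
    else:
        # hydroxyl side chains: 4C = 4-hydroxybutyl, 3C = 3-hydroxypropyl
        base = "4OHB" if chain == "4C" else "3OHP"
    name = f"{base}-{'ITC' if moiety == 'isothiocyanate' else 'Nitrile'}"

    cyclized = None
    if moiety == "isothiocyanate" and side == "hydroxyl":
        cyclized = (
            "1,3-Oxazepane-2-thione" if chain == "4C" else "1,3-Oxazinane-2-thione"
        )
        name = cyclized

    return GslProduct(
        name=name,
        precursor_chain=chain,
        side_chain=side,
        moiety=moiety,
        cyclized_name=cyclized,
        toxicity=PRODUCT_TOXICITY[name],
    )


def enumerate_products() -> pd.DataFrame:
    """Products of all 2 x 2 x 2 genotypes, one row per genotype.

    The image contains eight distinct products in three toxicity classes.
    """
    rows = []
    for esp, mam, aop3 in itertools.product(
        ("functional", "non_functional"), ("MAM1", "MAM2"), ("active", "inactive")
    ):
        g = GslGenotype(esp=esp, mam=mam, aop3=aop3)
        p = gsl_product(g)
        rows.append(
            {
                "esp": esp,
                "mam": mam,
                "aop3": aop3,
                "product": p.name,
                "precursor_chain": p.precursor_chain,
                "side_chain": p.side_chain,
                "moiety": p.moiety,
                "toxicity": p.toxicity,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RILPopulation:
    """A recombinant inbred line population.

    ``genotypes``: lines x markers frame with values 'C', 'L' or NaN;
    ``marker_map``: one row per marker with columns ``marker``,
    ``chromosome`` (1-5) and ``position``, ordered by position within
    chromosome; ``phenotypes``: per-line toxicity class.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    phenotypes: pd.Series
    causal_loci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.marker_map["chromosome"]) - set(range(1, 6)):
            raise ValueError("markers must lie on chromosomes 1-5")
        if list(self.genotypes.columns) != list(self.marker_map["marker"]):
            raise ValueError("genotype columns must match the marker map order")
        for chrom, sub in self.marker_map.groupby("chromosome"):
            if not sub["position"].is_monotonic_increasing:
                raise ValueError(f"markers on chromosome {chrom} not position-ordered")

    @property
    def lines(self) -> list[str]:
        return list(self.genotypes.index)


def allele_fraction_scan(pop: RILPopulation, group: str) -> pd.DataFrame:
    """Per-marker Ler-1 allele fraction within one phenotype group.

    For every marker, the fraction of non-missing group lines carrying the
    Ler-1 allele, with a two-sided exact binomial test against the
    Mendelian expectation of 0.5.  Rows are ordered by concatenated
    chromosome position.  Markers with no genotyped group line get a NaN
    fraction and are flagged.
    """
    members = pop.phenotypes.index[pop.phenotypes == group]
    if len(members) == 0:
        raise ValueError(f"no lines with phenotype {group!r}")
    geno = pop.genotypes.loc[members]
    rows = []
    for _, m in pop.marker_map.iterrows():
        col = geno[m["marker"]]
        called = col.dropna()
        n = len(called)
        k = int((called == "L").sum())
        if n == 0:
            frac, p = np.nan, np.nan
        else:
            frac = k / n
            p = stats.binomtest(k, n, 0.5).pvalue
        rows.append(
            {
                "marker": m["marker"],
                "chromosome": int(m["chromosome"]),
                "position": m["position"],
                "n_lines": n,
                "ler_fraction": frac,
                "p_value": p,
                "all_missing": n == 0,
            }
        )
    return pd.DataFrame(rows)


def peak_intervals(
    scan: pd.DataFrame,
    deviation_threshold: float = 0.25,
    min_run: int = 2,
) -> pd.DataFrame:
    """Candidate linkage intervals from an allele-fraction scan.

    Maximal runs of at least ``min_run`` consecutive markers (within a
    chromosome) whose Ler fraction deviates from 0.5 by at least
    ``deviation_threshold``.  Markers with missing fractions break runs.
    """
    intervals = []
    for chrom, sub in scan.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        dev = (sub["ler_fraction"] - 0.5).abs() >= deviation_threshold
        dev &= sub["ler_fraction"].notna()
        run: list[int] = []
        for idx, hit in zip(sub.index, dev):
            if hit:
                run.append(idx)
            else:
                if len(run) >= min_run:
                    intervals.append((chrom, run))
                run = []
        if len(run) >= min_run:
            intervals.append((chrom, run))
    rows = [
        {
            "chromosome": int(chrom),
            "start": scan.loc[run[0], "position"],
            "end": scan.loc[run[-1], "position"],
            "n_markers": len(run),
            "markers": [scan.loc[i, "marker"] for i in run],
            "mean_ler_fraction": float(scan.loc[run, "ler_fraction"].mean()),
        }
        for chrom, run in intervals
    ]
    if not rows:
        return pd.DataFrame(
            columns=[
                "chromosome",
                "start",
                "end",
                "n_markers",
                "markers",
                "mean_ler_fraction",
            ]
        )
    return pd.DataFrame(rows)
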