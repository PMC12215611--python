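"""Cross-habitat specificity profiles, upset counts, and COG enrichment.

Given per-contrast differential-fitness calls over the four plant habitats
(At_root, At_shoot, Bd_root, Bd_shoot), each gene is summarized by the set
of habitats where its mutants are depleted (association) or enriched
(negative association) and classified: ``general`` (all four habitats),
``host_specific`` (both organs of one host), ``organ_specific`` (one organ
in both hosts), ``single_habitat``, ``mixed`` (any other multi-habitat
pattern), or ``none``.  Upset-style intersection counts and Fisher-exact
COG-category enrichment against the genome background complete the
summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PLANT_HABITATS

__all__ = [
    "SpecificityProfile",
    "classify_pattern",
    "build_profiles",
    "upset_counts",
    "cog_enrichment",
]


@dataclass(frozen=True)
class SpecificityProfile:
    """Habitat subsets and derived classes for one gene."""

    gene: str
    association: frozenset
    negative: frozenset
    association_class: str
    negative_class: str


def _split(habitat: str) -> tuple[str, str]:
    host, organ = habitat.split("_")
    return host, organ


def classify_pattern(habitats: frozenset) -> str:
    """Deterministic class of one habitat subset."""
    bad = set(habitats) - set(PLANT_HABITATS)
    if bad:
        raise ValueError(f"unknown habitats: {sorted(bad)}")
    if not habitats:
        return "none"
    if len(habitats) == 4:
        return "general"
    if len(habitats) == 1:
        return f"single_habitat:{next(iter(habitats))}"
    hosts = {_split(h)[0] for h in habitats}
    organs = {_split(h)[1] for h in habitats}
    if len(habitats) == 2 and len(hosts) == 1:
        return f"host_specific:{next(iter(hosts))}"
    if len(habitats) == 2 and len(organs) == 1:
        return f"organ_specific:{next(iter(organs))}"
    return "mixed"


def build_profiles(results: pd.DataFrame) -> list:
    """Specificity profiles from a long per-gene, per-contrast call table.

    ``results`` needs columns ``gene``, ``contrast`` and ``category``
    (as produced by the differential-fitness step).
    """
    profiles = []
    for gene, sub in results.groupby("gene", sort=True):
        assoc = frozenset(sub.loc[sub["category"] == "association", "contrast"])
        neg = frozenset(sub.loc[sub["category"] == "negative_association", "contrast"])
        profiles.append(
            SpecificityProfile(
                gene=gene,
                association=assoc,
                negative=neg,
                association_class=classify_pattern(assoc),
                negative_class=classify_pattern(neg),
            )
        )
    return profiles


def _pattern_key(habitats: frozenset) -> str:
    return "+".join(h for h in PLANT_HABITATS if h in habitats)


def upset_counts(profiles: list) -> pd.DataFrame:
    """Intersection-pattern counts, separately per effect direction.

    Each gene contributes to exactly one pattern per direction; genes with
    an empty set in a direction are excluded from that direction's tally.
    """
    rows = []
    for direction in ("association", "negative"):
        tally: dict = {}
        for p in profiles:
            habitats = getattr(p, direction)
            if not habitats:
                continue
            tally[_pattern_key(habitats)] = tally.get(_pattern_key(habitats), 0) + 1
        for pattern, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"direction": direction, "pattern": pattern, "count": n})
    return pd.DataFrame(rows, columns=["direction", "pattern", "count"])


def cog_enrichment(
    gene_set: set,
    annotation: dict,
    background: set,
) -> pd.DataFrame:
    """Per-COG-category Fisher exact enrichment of a gene set.

    For every category present in the annotated background, a two-sided
    Fisher exact test on the 2x2 table (in set vs not) x (in category vs
    not), BH-adjusted across categories.  Genes lacking an annotation are
    excluded.  Categories carried only by gene-set members outside the
    background are skipped with a warning.
    """
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    bg_cats = pd.Series({g: annotation[g] for g in background if g in annotation})
    set_cats = bg_cats.loc[bg_cats.index.isin(gene_set)]
    orphan = {annotation[g] for g in gene_set if g in annotation} - set(bg_cats.unique())
    if orphan:
        warnings.warn(f"categories absent from background skipped: {sorted(orphan)}")
    rows = []
    n_bg, n_set = len(bg_cats), len(set_cats)
    categories = sorted(bg_cats.unique()) if n_set else []
    for cat in categories:
        a = int((set_cats == cat).sum())  # in set, in category
        b = n_set - a
        c = int((bg_cats == cat).sum()) - a  # outside set, in category
        d = (n_bg - n_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "n_set": a,
                "n_background": a + c,
                "fraction_set": a / n_set if n_set else float("nan"),
                "fraction_background": (a + c) / n_bg,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_set",
            "n_background",
            "fraction_set",
            "fraction_background",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
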