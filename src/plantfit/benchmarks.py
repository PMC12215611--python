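"""Self-contained recovery benchmarks over synthetic data.

Each function simulates inputs with the package's own generators, runs the
corresponding analysis stage, and returns summary metrics.  They are used
by the test suite and by ``scripts/acceptance.py`` so the same code path
produces both.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import (
    assay_models,
    barcode_quant,
    differential_fitness,
    fitness_scores,
    host_genetics,
    io,
    pump_clade,
    specificity_enrichment,
    synthetic_data,
)
from .design import PLANT_HABITATS, make_design

__all__ = [
    "recovery_benchmark",
    "null_benchmark",
    "nj_benchmark",
    "clade_benchmark",
    "ril_benchmark",
    "hill_benchmark",
    "roundtrip_benchmark",
    "rule_engine_summary",
]


def _subseed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


def _run_pipeline(params, mapping, inoculum, design, effects, seed):
    counts = synthetic_data.simulate_counts(
        mapping, inoculum, design, effects, params, seed=seed
    )
    filtered = barcode_quant.filter_barcodes(counts, mapping, design)
    ref = fitness_scores.reference_profile(filtered, design)
    strains = fitness_scores.strain_fitness(filtered, ref)
    gft = fitness_scores.gene_fitness(strains, mapping, filtered, ref)
    return differential_fitness.run_contrasts(gft, design)


def recovery_benchmark(
    seed: int,
    n_replicates: int = 8,
    n_genes: int = 500,
    insertions_per_gene: float = 5.0,
    n_true: int = 30,
    effect: float = -2.0,
    habitat: str = "At_shoot",
    n_per_habitat: int = 6,
    n_soil: int = 6,
    read_depth: int = 100_000,
) -> dict:
    """Planted-effect recovery of the differential-fitness pipeline.

    ``n_true`` genes carry ``effect`` in one habitat only; sensitivity,
    empirical FDR, and the fraction of true positives profiled as
    single-habitat are pooled over ``n_replicates`` independent simulations.
    """
    design = make_design(n_per_habitat=n_per_habitat, n_soil=n_soil)
    tp = fp = total_true = single = 0
    for k in range(n_replicates):
        params = synthetic_data.SimParams(
            n_genes=n_genes,
            insertions_per_gene_mean=insertions_per_gene,
            read_depth=read_depth,
            seed=_subseed(seed, 3 * k),
        )
        mapping, inoculum = synthetic_data.simulate_library(params)
        genes = sorted(set(mapping["locus_tag"].dropna()))
        rng = np.random.default_rng(_subseed(seed, 3 * k + 1))
        true = set(rng.choice(genes, size=n_true, replace=False))
        effects = synthetic_data.TrueEffects({g: {habitat: effect} for g in true})
        res = _run_pipeline(params, mapping, inoculum, design, effects,
                            _subseed(seed, 3 * k + 2))
        at = res.contrast(habitat)
        called = set(at.index[at["category"] == "association"])
        rep_tp = called & true
        tp += len(rep_tp)
        fp += len(called - true)
        total_true += n_true
        profiles = {p.gene: p for p in specificity_enrichment.build_profiles(res.table)}
        single += sum(
            1 for g in rep_tp if profiles[g].association == frozenset({habitat})
        )
    n_called = tp + fp
    return {
        "sensitivity": tp / total_true,
        "fdr": fp / n_called if n_called else 0.0,
        "single_habitat_fraction": single / tp if tp else float("nan"),
        "n_true": total_true,
        "n_called": n_called,
        "n_replicates": n_replicates,
    }


def null_benchmark(
    seed: int,
    n_genes: int = 500,
    insertions_per_gene: float = 5.0,
    read_depth: int = 100_000,
) -> dict:
    """Global null: rate of non-indifferent calls among retained genes."""
    design = make_design(n_per_habitat=6, n_soil=6)
    params = synthetic_data.SimParams(
        n_genes=n_genes,
        insertions_per_gene_mean=insertions_per_gene,
        read_depth=read_depth,
        seed=_subseed(seed, 7),
    )
    mapping, inoculum = synthetic_data.simulate_library(params)
    res = _run_pipeline(params, mapping, inoculum, design,
                        synthetic_data.TrueEffects(), _subseed(seed, 8))
    rates = {}
    for habitat in PLANT_HABITATS:
        sub = res.contrast(habitat)
        retained = sub[sub["category"] != "omitted_nonnormal"]
        called = (retained["category"] != "indifferent").sum()
        n = len(retained)
        rates[habitat] = {
            "call_rate": called / n if n else 0.0,
            "n_retained": int(n),
            "bound": 0.05 + 2 * float(np.sqrt(0.05 * 0.95 / max(n, 1))),
        }
    return rates


def _bipartitions(tree) -> set:
    """Non-trivial unrooted bipartitions of a tree's tip set."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(min(side, all_tips - side, key=sorted))
    return splits


def nj_benchmark(seed: int, n_trees: int = 50, max_taxa: int = 8) -> dict:
    """Neighbor joining on random additive matrices.

    A tree is recovered when every estimated leaf-to-leaf path length
    matches the generating tree to 1e-9 and the unrooted Robinson-Foulds
    distance (symmetric difference of non-trivial bipartitions) is zero.
    """
    rng = np.random.default_rng(_subseed(seed, 11))
    recovered = 0
    for _ in range(n_trees):
        n_taxa = int(rng.integers(4, max_taxa + 1))
        true_tree, dm = synthetic_data.simulate_additive_tree(n_taxa, rng)
        est = pump_clade.neighbor_joining(dm)
        ok = True
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                d_est = est.find(a).distance(est.find(b))
                if abs(d_est - dm[a, b]) > 1e-9:
                    ok = False
        rf = len(_bipartitions(true_tree) ^ _bipartitions(est))
        recovered += ok and rf == 0
    return {"recovered_fraction": recovered / n_trees, "n_trees": n_trees}


def clade_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """Exact recovery of the designed clade by the full calling pipeline."""
    exact = 0
    for k in range(n_seeds):
        fam = synthetic_data.simulate_protein_family(seed=_subseed(seed, 100 + k))
        report = pump_clade.call_clade(fam.sequences, fam.metadata)
        exact += report.members == sorted(fam.clade_ids)
    return {"exact_fraction": exact / n_seeds, "n_seeds": n_seeds}


def ril_benchmark(seed: int, n_pops: int = 100, n_lines: int = 98) -> dict:
    """Causal-locus localization and neutrality of the RIL scan."""
    hits = 0
    for k in range(n_pops):
        pop = synthetic_data.simulate_ril_population(
            n_lines=n_lines, seed=_subseed(seed, 200 + k)
        )
        scan = host_genetics.allele_fraction_scan(pop, "d90_toxic")
        frac = scan.set_index("marker")["ler_fraction"]
        hits += frac[pop.causal_loci["esp"]] <= frac.min() + 1e-12
    neutral = synthetic_data.simulate_ril_population(
        n_lines=200, seed=_subseed(seed, 300)
    )
    mean_frac = float((neutral.genotypes == "L").to_numpy().mean())
    se = 0.5 / np.sqrt(200 * 5)
    return {
        "causal_extreme_fraction": hits / n_pops,
        "n_populations": n_pops,
        "neutral_mean_ler_fraction": mean_frac,
        "neutral_band_halfwidth": 3 * se,
    }


def hill_benchmark(seed: int, n_fits: int = 100, ic50: float = 10.0) -> dict:
    """IC50 recovery rate from noisy simulated dose-response data."""
    ok = 0
    errors = []
    for k in range(n_fits):
        tab = synthetic_data.simulate_dose_response(
            top=1.0, ic50=ic50, hill=2.0, noise_sd=0.02, replicates=4,
            seed=_subseed(seed, 400 + k),
        )
        fit = assay_models.fit_hill(tab["dose"], tab["od"])
        rel_err = abs(fit.ic50 - ic50) / ic50
        errors.append(rel_err)
        ok += rel_err <= 0.10
    return {
        "within_10pct_fraction": ok / n_fits,
        "median_rel_error": float(np.median(errors)),
        "n_fits": n_fits,
    }


def roundtrip_benchmark(seed: int, n_genes: int = 60, read_depth: int = 20_000,
                        n_samples: int = 3) -> dict:
    """FASTQ write -> extract -> count must reproduce the count matrix."""
    params = synthetic_data.SimParams(
        n_genes=n_genes, insertions_per_gene_mean=5.0, read_depth=read_depth,
        seed=_subseed(seed, 500),
    )
    mapping, inoculum = synthetic_data.simulate_library(params)
    design = make_design(n_per_habitat=1, n_soil=2)
    counts = synthetic_data.simulate_counts(
        mapping, inoculum, design, synthetic_data.TrueEffects(), params,
        seed=_subseed(seed, 501),
    )
    anchor = "GTCGAC"
    mismatches = 0
    checked = 0
    with tempfile.TemporaryDirectory() as tmp:
        samples = {}
        for k, sample_id in enumerate(list(counts.columns)[:n_samples]):
            path = Path(tmp) / f"{sample_id}.fastq"
            io.write_sample_fastq(counts[sample_id], path, anchor=anchor,
                                  seed=_subseed(seed, 600 + k))
            samples[sample_id] = barcode_quant.extract_from_fastq(path, anchor=anchor).barcodes
        recounted, unmapped = barcode_quant.count_barcodes(samples, mapping)
        for sample_id in samples:
            checked += len(recounted)
            mismatches += int(
                (recounted[sample_id] != counts[sample_id]).sum()
            ) + unmapped[sample_id]
    return {"n_cells_checked": checked, "n_mismatches": mismatches}


def rule_engine_summary() -> dict:
    """Exact combinatorics of the glucosinolate rule engine."""
    table = host_genetics.enumerate_products()
    return {
        "n_products": int(table["product"].nunique()),
        "n_d90_toxic": int((table.drop_duplicates("product")["toxicity"] == "d90_toxic").sum()),
        "n_toxicity_classes": int(table["toxicity"].nunique()),
        "col0_product": host_genetics.gsl_product(host_genetics.COL0).name,
        "ler1_product": host_genetics.gsl_product(host_genetics.LER1).name,
    }
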