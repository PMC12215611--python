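"""Generator behavior: determinism, marginal moments, structural invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plantfit import synthetic_data as sd
from plantfit.design import make_design


class TestSimulateLibrary:
    def test_mean_insertions_per_gene(self):
        params = sd.SimParams(n_genes=3000, insertions_per_gene_mean=8.5, seed=0)
        mapping, _ = sd.simulate_library(params, intergenic_fraction=0.0)
        per_gene = mapping.groupby("locus_tag").size()
        # Poisson mean 8.5 over 3000 genes: SE ~ 0.053 (genes with zero
        # insertions are absent from the grouping, so add them back)
        mean = len(mapping) / params.n_genes
        assert mean == pytest.approx(8.5, abs=0.2)
        assert per_gene.min() >= 1

    def test_deterministic_for_fixed_seed(self):
        params = sd.SimParams(n_genes=40, seed=11)
        m1, a1 = sd.simulate_library(params)
        m2, a2 = sd.simulate_library(params)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(a1, a2)

    def test_positions_in_central_window(self):
        params = sd.SimParams(n_genes=1, insertions_per_gene_mean=1000, seed=3)
        mapping, _ = sd.simulate_library(params, gene_length=1000,
                                         intergenic_fraction=0.0)
        # gene spans 1..1000; central 10-90% window is 101..901
        assert mapping["position"].between(101, 901).all()
        assert mapping["central"].all()

    def test_barcodes_unique_20mers(self, small_library):
        mapping, _ = small_library
        assert mapping["barcode"].is_unique
        assert mapping["barcode"].str.len().eq(20).all()
        assert mapping["barcode"].str.fullmatch("[ACGT]+").all()

    def test_zero_library_is_error(self):
        params = sd.SimParams(n_genes=1, insertions_per_gene_mean=1e-9, seed=0)
        with pytest.raises(ValueError, match="zero barcodes"):
            sd.simulate_library(params)


class TestSimulateCounts:
    def test_deterministic(self, small_library, small_design, small_params):
        mapping, inoculum = small_library
        eff = sd.TrueEffects()
        c1 = sd.simulate_counts(mapping, inoculum, small_design, eff, small_params, seed=9)
        c2 = sd.simulate_counts(mapping, inoculum, small_design, eff, small_params, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_neutral_proportions_match_across_habitats(self):
        """With no effects and no bottleneck, habitat columns are draws from
        one multinomial; a chi-square GOF against the inoculum should not
        reject at alpha=0.01 in the vast majority of seeds."""
        params = sd.SimParams(n_genes=30, insertions_per_gene_mean=4,
                              read_depth=50_000, seed=1)
        mapping, inoculum = sd.simulate_library(params, intergenic_fraction=0.0)
        design = make_design(n_per_habitat=1, n_soil=2)
        rejections = 0
        n_tests = 0
        for seed in range(10):
            counts = sd.simulate_counts(mapping, inoculum, design,
                                        sd.TrueEffects(), params, seed=seed)
            expected = inoculum.to_numpy() * params.read_depth
            for col in counts.columns:
                p = stats.chisquare(counts[col].to_numpy(), expected).pvalue
                n_tests += 1
                rejections += p < 0.01
        assert rejections / n_tests < 0.05

    def test_effect_shifts_expected_proportion(self):
        """A gene with effect -2 in At_shoot sits at ~2^-2 of its soil
        proportion, averaged over seeds (closed-form multinomial mean)."""
        params = sd.SimParams(n_genes=30, insertions_per_gene_mean=4,
                              read_depth=50_000, seed=2)
        mapping, inoculum = sd.simulate_library(params, intergenic_fraction=0.0)
        gene = mapping["locus_tag"].iloc[0]
        member = mapping["locus_tag"] == gene
        effects = sd.TrueEffects({gene: {"At_shoot": -2.0}})
        design = make_design(n_per_habitat=1, n_soil=2)
        ratios = []
        for seed in range(50):
            counts = sd.simulate_counts(mapping, inoculum, design, effects,
                                        params, seed=100 + seed)
            soil_prop = counts.loc[member.to_numpy(), ["soil_01", "soil_02"]].sum().sum() / (
                2 * params.read_depth
            )
            shoot_prop = counts.loc[member.to_numpy(), "At_shoot_01"].sum() / params.read_depth
            ratios.append(shoot_prop / soil_prop)
        # exact expectation is 2^-2 / (1 - p_g + p_g * 2^-2) ~ 0.25 for small p_g
        assert np.mean(ratios) == pytest.approx(0.25, rel=0.15)

    def test_bottleneck_reduces_barcode_richness(self, small_library, small_design,
                                                 small_params):
        mapping, inoculum = small_library
        params = sd.SimParams(
            n_genes=small_params.n_genes,
            insertions_per_gene_mean=small_params.insertions_per_gene_mean,
            read_depth=small_params.read_depth,
            bottleneck_founders=30,
            seed=small_params.seed,
        )
        counts = sd.simulate_counts(mapping, inoculum, small_design,
                                    sd.TrueEffects(), params, seed=5)
        soil_rich = (counts[["soil_01", "soil_02"]] > 0).sum()
        plant_cols = [c for c in counts.columns if not c.startswith("soil")]
        plant_rich = (counts[plant_cols] > 0).sum()
        assert plant_rich.max() <= 30
        assert (plant_rich < soil_rich.min()).all()

    def test_bottleneck_larger_than_library_is_error(self, small_library,
                                                     small_design):
        mapping, inoculum = small_library
        params = sd.SimParams(bottleneck_founders=10**6, seed=0)
        with pytest.raises(ValueError, match="exceeds library size"):
            sd.simulate_counts(mapping, inoculum, small_design,
                               sd.TrueEffects(), params)

    def test_unknown_effect_gene_is_error(self, small_library, small_design,
                                          small_params):
        mapping, inoculum = small_library
        effects = sd.TrueEffects({"no_such_gene": {"At_shoot": -1.0}})
        with pytest.raises(ValueError, match="absent from the map"):
            sd.simulate_counts(mapping, inoculum, small_design, effects, small_params)


class TestSimulateRIL:
    def test_no_recombination_gives_parental_chromosomes(self):
        pop = sd.simulate_ril_population(n_lines=200, markers_per_chrom=10,
                                         recomb_per_chrom=0.0, seed=0)
        for _, row in pop.genotypes.iterrows():
            for c in range(1, 6):
                markers = pop.marker_map.loc[
                    pop.marker_map["chromosome"] == c, "marker"
                ]
                assert row[markers].nunique() == 1
        ler_frac = (pop.genotypes == "L").to_numpy().mean()
        assert ler_frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(200 * 5))

    def test_all_col_causal_alleles_give_d90_toxic(self):
        pop = sd.simulate_ril_population(n_lines=60, seed=1)
        loci = [pop.causal_loci[k] for k in ("esp", "mam", "aop3")]
        all_col = (pop.genotypes[loci] == "C").all(axis=1)
        assert all_col.any()
        assert (pop.phenotypes[all_col] == "d90_toxic").all()

    def test_deterministic(self):
        p1 = sd.simulate_ril_population(n_lines=20, seed=9)
        p2 = sd.simulate_ril_population(n_lines=20, seed=9)
        pd.testing.assert_frame_equal(p1.genotypes, p2.genotypes)
        pd.testing.assert_series_equal(p1.phenotypes, p2.phenotypes)

    def test_causal_loci_must_be_distinct_chromosomes(self):
        with pytest.raises(ValueError, match="distinct chromosomes"):
            sd.simulate_ril_population(
                n_lines=5,
                causal_loci={"esp": "c1m01", "mam": "c1m05", "aop3": "c4m05"},
                seed=0,
            )


class TestSimulateProteinFamily:
    def test_tight_pair_are_mutual_nearest_neighbors(self):
        from plantfit.pump_clade import pairwise_distance

        fam = sd.simulate_protein_family(
            n_background=5, clade_size=2, clade_divergence=0.01,
            background_divergence=0.5, seed=0
        )
        dm = pairwise_distance(fam.sequences)
        a, b = fam.clade_ids
        others = [s for s in fam.sequences if s not in (a, b)]
        assert dm[a, b] < min(dm[a, o] for o in others)
        assert dm[a, b] < min(dm[b, o] for o in others)

    def test_no_background_means_one_clade(self):
        fam = sd.simulate_protein_family(n_background=0, clade_size=4, seed=1)
        assert set(fam.sequences) == set(fam.clade_ids)

    def test_divergence_validation(self):
        with pytest.raises(ValueError, match="must be in"):
            sd.simulate_protein_family(clade_divergence=0.0, seed=0)
        with pytest.raises(ValueError, match="must be <"):
            sd.simulate_protein_family(clade_divergence=0.5,
                                       background_divergence=0.4, seed=0)


class TestSimulateDoseResponse:
    def test_noise_free_hits_defining_points(self):
        tab = sd.simulate_dose_response(top=2.0, ic50=5.0, hill=3.0,
                                        doses=[0.0, 5.0], noise_sd=0.0,
                                        replicates=1, seed=0)
        by_dose = tab.set_index("dose")["od"]
        assert by_dose.loc[0.0] == pytest.approx(2.0)
        assert by_dose.loc[5.0] == pytest.approx(1.0)

    def test_steep_hill_kills_growth_above_ic50(self):
        tab = sd.simulate_dose_response(top=1.0, ic50=1.0, hill=50.0,
                                        doses=[2.0], noise_sd=0.0,
                                        replicates=1, seed=0)
        assert tab["od"].iloc[0] < 1e-10

    def test_negative_dose_is_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            sd.simulate_dose_response(doses=[-1.0], seed=0)
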