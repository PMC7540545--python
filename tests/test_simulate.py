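"""Generators: determinism, truth structure, planting and PRS cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sibshare.simulate import (
    AscertainmentError,
    ExomeSimSpec,
    PlantedCandidate,
    PlantingError,
    PrsCohortSpec,
    SimParams,
    _truth_strict_ibd2_spans,
    read_ped_map,
    simulate_exome_table,
    simulate_families,
    simulate_family,
    simulate_prs_cohorts,
    write_ped_map,
)


SMALL = dict(n_markers=400, n_chromosomes=4, n_sibs=3)


class TestSimParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_markers", 3),  # fewer than 2 per chromosome
            ("marker_maf_range", (0.0, 0.5)),
            ("marker_maf_range", (0.1, 0.6)),
            ("genotype_error_rate", 0.5),
            ("n_sibs", 1),
            ("marker_spacing_cM", 0.0),
        ],
    )
    def test_invalid_params_name_offending_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimParams(**{**SMALL, field: value})


class TestSimulateFamily:
    def test_same_seed_is_bit_identical(self):
        p = SimParams(**SMALL, seed=5)
        a, b = simulate_family(p), simulate_family(p)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.marker_map, b.marker_map)
        assert np.array_equal(a.truth_ibd, b.truth_ibd)
        assert np.array_equal(a.truth_parent_haplotypes, b.truth_parent_haplotypes)

    def test_map_positions_increasing_within_chromosome(self):
        ds = simulate_family(SimParams(**SMALL, seed=1))
        for _, g in ds.marker_map.groupby("chrom", sort=False):
            assert np.all(np.diff(g["pos_bp"]) > 0)

    def test_genotypes_consistent_with_haplotypes_except_errors(self):
        ds = simulate_family(SimParams(**SMALL, genotype_error_rate=0.05, seed=2))
        M = len(ds.marker_map)
        for s, sib in enumerate(ds.sibship.sib_ids):
            hap_a = ds.truth_parent_haplotypes[ds.truth_inheritance[s, 0], np.arange(M)]
            hap_b = ds.truth_parent_haplotypes[2 + ds.truth_inheritance[s, 1], np.arange(M)]
            expected = hap_a + hap_b
            mismatch = ds.genotypes.loc[sib].to_numpy() != expected
            assert np.array_equal(mismatch, ds.error_mask[s])

    def test_truth_ibd_from_inheritance_and_symmetric(self):
        ds = simulate_family(SimParams(**SMALL, seed=3))
        # pair (i, j) recomputed by hand equals the recorded matrix
        for p, (i, j) in enumerate(
            [(i, j) for i in range(3) for j in range(i + 1, 3)]
        ):
            expected = (
                ds.truth_inheritance[i, 0] == ds.truth_inheritance[j, 0]
            ).astype(int) + (
                ds.truth_inheritance[i, 1] == ds.truth_inheritance[j, 1]
            ).astype(int)
            assert np.array_equal(ds.truth_ibd[p], expected)

    def test_pair_ibd2_fraction_near_quarter(self):
        p = SimParams(
            n_markers=1000, n_chromosomes=10, n_sibs=2, n_families=60, seed=17
        )
        fracs = [
            np.mean(np.all(ds.truth_ibd == 2, axis=0)) for ds in simulate_families(p)
        ]
        assert abs(np.mean(fracs) - 0.25) < 0.03

    def test_unlinked_markers_reach_stationary_transitions(self):
        # infinite spacing: adjacent truth-IBD states independent with the
        # stationary law (1/4, 1/2, 1/4); chi-square on ~10^4 transitions
        p = SimParams(
            n_markers=10004,
            n_chromosomes=2,
            marker_spacing_cM=np.inf,
            n_sibs=2,
            genotype_error_rate=0.0,
            seed=23,
        )
        states = simulate_family(p).truth_ibd[0]
        counts = np.bincount(states, minlength=3)
        chi2, pval = stats.chisquare(counts, len(states) * np.array([0.25, 0.5, 0.25]))
        assert pval > 1e-3
        # independence of consecutive states
        table = np.zeros((3, 3))
        np.add.at(table, (states[:-1], states[1:]), 1)
        _, pval2, _, _ = stats.chi2_contingency(table)[0:4]
        assert pval2 > 1e-3

    def test_families_are_independent_but_reproducible(self):
        p = SimParams(**SMALL, n_families=3, seed=9)
        fams1, fams2 = simulate_families(p), simulate_families(p)
        for a, b in zip(fams1, fams2):
            pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        assert not fams1[0].genotypes.equals(
            fams1[1].genotypes.set_axis(fams1[0].genotypes.index)
        )


class TestSimulateExome:
    def test_same_seed_gives_identical_vcf_bytes(self):
        ds = simulate_family(SimParams(**SMALL, seed=4))
        spec = ExomeSimSpec(n_decoy_variants=200, seed=8)
        a, b = simulate_exome_table(ds, spec), simulate_exome_table(ds, spec)
        assert a.vcf_text.encode() == b.vcf_text.encode()
        pd.testing.assert_frame_equal(a.variants, b.variants)

    @pytest.mark.parametrize(
        "mechanism", ["homozygous-ptv", "compound-het", "homozygous-missense"]
    )
    def test_planted_candidate_inside_truth_strict_region(self, mechanism):
        ds = simulate_family(SimParams(**SMALL, seed=6))
        spec = ExomeSimSpec(
            n_decoy_variants=50,
            planted=[PlantedCandidate(mechanism, gene="PLANTX")],
            seed=10,
        )
        exome = simulate_exome_table(ds, spec)
        spans = _truth_strict_ibd2_spans(ds)
        planted = exome.truth.loc[exome.truth["origin"] != "decoy"]
        assert len(planted) >= 1
        for _, row in planted.iterrows():
            assert any(
                c == row["chrom"] and lo <= row["pos"] <= hi for c, lo, hi in spans
            )

    def test_planted_genotypes_match_mechanism(self):
        ds = simulate_family(SimParams(**SMALL, seed=6))
        spec = ExomeSimSpec(
            n_decoy_variants=0,
            planted=[PlantedCandidate("compound-het", gene="PLANTX")],
            seed=10,
        )
        variants = simulate_exome_table(ds, spec).variants
        assert list(variants["genotype"]) == ["het", "het"]
        assert set(variants["func_class"]) == {"stop-gained", "missense"}
        assert (variants["carrier_count"] == 3).all()

    def test_planting_without_shared_region_fails_naming_family(self):
        ds = simulate_family(SimParams(**SMALL, seed=6))
        ds.truth_ibd = np.ones_like(ds.truth_ibd)  # no all-IBD2 marker anywhere
        spec = ExomeSimSpec(planted=[PlantedCandidate("homozygous-ptv")], seed=1)
        with pytest.raises(PlantingError, match=ds.sibship.family_id):
            simulate_exome_table(ds, spec)

    def test_vcf_text_parses_with_cyvcf2(self, tmp_path):
        from sibshare.filters import read_vcf_genotypes

        ds = simulate_family(SimParams(**SMALL, seed=4))
        exome = simulate_exome_table(ds, ExomeSimSpec(n_decoy_variants=30, seed=2))
        vcf = tmp_path / "proband.vcf"
        tsv = tmp_path / "annot.tsv"
        exome.write(vcf, tsv)
        parsed = read_vcf_genotypes(vcf)
        assert len(parsed) == len(exome.variants)
        assert list(parsed["genotype"]) == list(exome.variants["genotype"])


class TestSimulatePrsCohorts:
    def test_same_seed_gives_identical_tables(self):
        spec = PrsCohortSpec(n_controls=50, n_cases=50, n_sibships=3, seed=12)
        a, b = simulate_prs_cohorts(spec), simulate_prs_cohorts(spec)
        pd.testing.assert_frame_equal(a.controls, b.controls)
        pd.testing.assert_frame_equal(a.cases, b.cases)
        pd.testing.assert_frame_equal(a.sibships, b.sibships)

    def test_null_panel_gives_zero_scores_everywhere(self):
        from sibshare.prs import prs_raw

        spec = PrsCohortSpec(
            n_controls=40, n_cases=40, n_sibships=3, or_range=(1.0, 1.0), seed=13
        )
        cohorts = simulate_prs_cohorts(spec)
        for df in (cohorts.controls, cohorts.cases, cohorts.sibships):
            assert np.allclose(prs_raw(df, cohorts.panel), 0.0)

    def test_effect_creates_group_mean_ordering(self):
        from sibshare.prs import normalize_scores, prs_raw

        spec = PrsCohortSpec(n_controls=600, n_cases=600, n_sibships=20, seed=14)
        cohorts = simulate_prs_cohorts(spec)
        ctrl = prs_raw(cohorts.controls, cohorts.panel)
        case = normalize_scores(prs_raw(cohorts.cases, cohorts.panel), ctrl)
        sibs = normalize_scores(prs_raw(cohorts.sibships, cohorts.panel), ctrl)
        assert 0.0 < case.mean() < sibs.mean()

    def test_sibship_structure(self):
        spec = PrsCohortSpec(n_controls=20, n_cases=20, n_sibships=4, n_sibs=3, seed=15)
        cohorts = simulate_prs_cohorts(spec)
        assert len(cohorts.sibships) == 12
        assert cohorts.family_ids.value_counts().eq(3).all()
        assert len(cohorts.probands) == 4

    def test_ascertainment_budget_exhaustion_fails(self):
        spec = PrsCohortSpec(
            n_controls=5, n_cases=5, n_sibships=50, max_family_attempts=64, seed=16
        )
        with pytest.raises(AscertainmentError, match="sibships"):
            simulate_prs_cohorts(spec)


def test_ped_map_round_trip(tmp_path):
    ds = simulate_family(SimParams(**SMALL, seed=20))
    ped, mapf = tmp_path / "f.ped", tmp_path / "f.map"
    write_ped_map(ds, ped, mapf)
    genotypes, marker_map = read_ped_map(ped, mapf)
    assert np.array_equal(genotypes.to_numpy(), ds.genotypes.to_numpy())
    assert list(marker_map["chrom"]) == list(ds.marker_map["chrom"])
    assert np.array_equal(
        marker_map["pos_bp"].to_numpy(), ds.marker_map["pos_bp"].to_numpy()
    )
    assert np.allclose(marker_map["freq"], ds.marker_map["freq"], rtol=1e-5)
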