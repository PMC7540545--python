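"""Recessive cascade and panel scan against worked examples and oracles."""

import numpy as np
import pandas as pd
import pytest

from sibshare.filters import (
    ChromosomeDialectError,
    GenePanel,
    default_gene_panel,
    frequency_filter,
    is_ptv,
    max_reference_af,
    missense_recessive_scan,
    panel_scan,
    read_annotation_tsv,
    region_filter,
    run_recessive_filter,
    second_hit_search,
)
from sibshare.regions import Region, SharedRegionSet

from conftest import make_variant, variant_table


REGION = SharedRegionSet("F1", "strict", [Region("chr1", 101, 399)])


class TestRegionFilter:
    @pytest.mark.parametrize(
        "pos,kept", [(101, True), (150, True), (399, True), (400, False), (100, False)]
    )
    def test_inclusive_boundaries(self, pos, kept):
        table = variant_table([make_variant(pos=pos)])
        assert (len(region_filter(table, REGION)) == 1) is kept

    def test_dialect_mismatch_raises_instead_of_dropping(self):
        table = variant_table([make_variant(chrom="1", pos=150)])
        with pytest.raises(ChromosomeDialectError):
            region_filter(table, REGION)

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(5)
        regions = [
            Region(f"chr{c}", int(s), int(s) + int(w))
            for c, s, w in zip(
                rng.integers(1, 4, 12), rng.integers(1, 5000, 12), rng.integers(1, 800, 12)
            )
        ]
        rset = SharedRegionSet("F1", "strict", regions)
        table = variant_table(
            [
                make_variant(chrom=f"chr{rng.integers(1, 4)}", pos=int(rng.integers(1, 6500)))
                for _ in range(200)
            ]
        )
        got = region_filter(table, rset)
        expected = [
            i
            for i, row in table.iterrows()
            if any(r.contains(row["chrom"], row["pos"]) for r in regions)
        ]
        assert list(got.index) == expected


class TestPtvAndFrequency:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            ("stop-gained", True),
            ("frameshift", True),
            ("canonical-splice", True),
            ("missense", False),
            ("synonymous", False),
        ],
    )
    def test_ptv_classes(self, cls, expected):
        assert is_ptv(cls) is expected

    def test_reference_filter_examples(self):
        table = variant_table(
            [
                make_variant(af_gonl=0.065, af_internal=0.10),  # kept
                make_variant(af_gonl=0.12),  # dropped: > 10% in a database
                make_variant(af_internal=0.35),  # dropped: internal artifact
                make_variant(af_internal=np.nan),  # no info at all: kept
            ]
        )
        assert list(frequency_filter(table)) == [True, False, False, True]

    def test_absent_sources_ignored_not_zero(self):
        table = variant_table([make_variant(af_gonl=np.nan, af_exac=0.05)])
        assert frequency_filter(table).all()
        assert max_reference_af(table).iloc[0] == 0.05


class TestSecondHitSearch:
    def test_sibship_screen_prioritizes_only_the_rare_pair(self, sibling_ptv_table):
        result = second_hit_search(sibling_ptv_table, causal_max=0.02)
        by_gene = result.pairs.groupby("gene").size()
        assert set(by_gene.index) == {"PDIA2", "TLR5", "TRPM1", "UNC93A", "PLXNB3", "CCHCR1"}
        assert by_gene["CCHCR1"] == 2  # one PTV x two missense partners
        prioritized = set(result.prioritized_pairs["gene"])
        assert prioritized == {"PDIA2"}

    def test_lone_het_ptv_yields_no_pair(self):
        table = variant_table(
            [
                make_variant(gene="G1", func_class="stop-gained", af_gonl=0.001),
                make_variant(gene="G2", func_class="missense", pos=2000, af_gonl=0.001),
            ]
        )
        assert len(second_hit_search(table).pairs) == 0

    def test_homozygous_ptv_reported_singly(self):
        table = variant_table(
            [make_variant(func_class="stop-gained", genotype="hom-alt", af_gonl=0.005)]
        )
        result = second_hit_search(table)
        assert len(result.homozygous) == 1
        assert result.homozygous["prioritized"].iloc[0]

    def test_synonymous_never_a_second_hit(self):
        table = variant_table(
            [
                make_variant(gene="G1", func_class="stop-gained", af_gonl=0.001),
                make_variant(gene="G1", func_class="synonymous", pos=2000, af_gonl=0.001),
            ]
        )
        assert len(second_hit_search(table).pairs) == 0

    def test_ptv_ptv_pair_emitted_once(self):
        table = variant_table(
            [
                make_variant(gene="G1", func_class="stop-gained", pos=1000, af_gonl=0.001),
                make_variant(gene="G1", func_class="frameshift", pos=2000, af_gonl=0.001),
            ]
        )
        assert len(second_hit_search(table).pairs) == 1


class TestMissenseRecessiveScan:
    def test_threshold_gates(self):
        rows = [
            make_variant(af_gonl=0.005, polyphen=0.9, grantham=80, genotype="hom-alt"),
            make_variant(af_gonl=0.005, polyphen=0.5, grantham=80, pos=2000),
            make_variant(af_gonl=0.005, polyphen=0.9, grantham=60, pos=3000),
            make_variant(af_gonl=0.02, polyphen=0.9, grantham=80, pos=4000),
        ]
        result = missense_recessive_scan(variant_table(rows))
        assert len(result.homozygous) == 1
        assert result.homozygous["pos"].iloc[0] == 1000

    def test_missing_scores_fail_and_are_counted(self):
        rows = [make_variant(af_gonl=0.001, polyphen=np.nan, grantham=100)]
        result = missense_recessive_scan(variant_table(rows))
        assert len(result.homozygous) == 0 and len(result.pairs) == 0
        assert result.n_missing_scores == 1

    def test_same_gene_het_pair_reported(self):
        rows = [
            make_variant(gene="GX", af_gonl=0.001, polyphen=0.9, grantham=90, pos=1000),
            make_variant(gene="GX", af_gonl=0.002, polyphen=0.8, grantham=100, pos=2000),
        ]
        result = missense_recessive_scan(variant_table(rows))
        assert len(result.pairs) == 1

    def test_twenty_variant_table_matches_row_oracle(self):
        rng = np.random.default_rng(9)
        rows = [
            make_variant(
                pos=1000 + 100 * i,
                gene=f"G{i}",
                af_gonl=float(rng.uniform(0, 0.03)),
                polyphen=float(rng.uniform(0.3, 1.0)),
                grantham=float(rng.uniform(40, 160)),
                genotype="hom-alt" if rng.random() < 0.5 else "het",
            )
            for i in range(20)
        ]
        table = variant_table(rows)
        result = missense_recessive_scan(table)
        expected_hom = {
            row["pos"]
            for row in rows
            if row["af_gonl"] < 0.01
            and row["polyphen"] > 0.7
            and row["grantham"] > 75
            and row["genotype"] == "hom-alt"
        }
        assert set(result.homozygous["pos"]) == expected_hom


class TestPanelScan:
    def test_worked_examples(self, panel_table):
        result = panel_scan(panel_table)
        kept = set(zip(result.findings["gene"], result.findings["pos"]))
        assert ("CHEK2", 1100) in kept  # frameshift at 1% under moderate 2%
        assert ("BRCA1", 2000) not in kept  # 0.5% exceeds the 0.1% tier
        assert ("BRCA2", 3000) in kept  # rare missense, CADD 35
        assert ("BARD1", 4000) not in kept  # low CADD, level-3 gene
        assert ("ATM", 5000) in kept  # level-2 rule rescues low CADD
        assert ("CHEK2", 6000) not in kept  # 15% missense too common
        assert result.n_nonpanel == 1

    def test_co_segregation_reported(self, panel_table):
        result = panel_scan(panel_table)
        chek2 = result.findings.loc[result.findings["pos"] == 1100].iloc[0]
        assert chek2["co_segregation"] == "3/3"

    def test_default_panel_contract(self):
        panel = default_gene_panel()
        assert len(panel.levels) == 35
        assert {"BRCA1", "BRCA2", "PALB2", "TP53", "PTEN", "CDH1"} <= panel.genes
        assert {"ATM", "CHEK2"} <= panel.genes
        assert panel.high_risk_ptv_max == 0.001
        assert panel.moderate_risk_ptv_max == 0.02

    def test_panel_missing_required_gene_rejected(self):
        with pytest.raises(ValueError, match="BRCA1"):
            GenePanel(levels={"ATM": "2", "CHEK2": "2"})

    def test_panel_tsv_round_trip(self, tmp_path):
        panel = default_gene_panel()
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        assert GenePanel.from_tsv(path).levels == panel.levels


class TestCascade:
    def _random_table(self, rng, n=60):
        rows = []
        for i in range(n):
            af = float(np.exp(rng.uniform(np.log(1e-4), np.log(0.4))))
            rows.append(
                make_variant(
                    chrom=f"chr{rng.integers(1, 3)}",
                    pos=int(rng.integers(1, 5000)),
                    gene=f"G{rng.integers(0, 12)}",
                    func_class=str(
                        rng.choice(
                            ["stop-gained", "missense", "synonymous"], p=[0.3, 0.5, 0.2]
                        )
                    ),
                    genotype="hom-alt" if rng.random() < 0.1 else "het",
                    af_gonl=af,
                    af_exac=af * float(rng.uniform(0.5, 1.5)),
                    polyphen=float(rng.uniform(0, 1)),
                    grantham=float(rng.uniform(0, 200)),
                )
            )
        return variant_table(rows)

    def test_stage_counts_never_increase(self):
        rng = np.random.default_rng(21)
        rset = SharedRegionSet(
            "F1", "strict", [Region("chr1", 1, 3000), Region("chr2", 1000, 4000)]
        )
        report = run_recessive_filter(self._random_table(rng), rset)
        c = report.stage_counts
        assert c["input"] >= c["region_pass"] >= c["freq_pass"] >= c["ptv"]
        assert c["prioritized"] <= c["compound_het_pairs"] + c["homozygous_ptv"]

    @pytest.mark.parametrize(
        "tight",
        [
            {"causal_max": 0.01},
            {"reference_max": 0.05},
            {"missense_af_max": 0.005},
            {"polyphen_min": 0.9},
        ],
    )
    def test_tightening_thresholds_never_grows_candidates(self, tight):
        rng = np.random.default_rng(22)
        rset = SharedRegionSet("F1", "strict", [Region("chr1", 1, 5000), Region("chr2", 1, 5000)])
        table = self._random_table(rng, n=120)
        base = run_recessive_filter(table, rset)
        tightened = run_recessive_filter(table, rset, **tight)
        assert tightened.second_hits.n_prioritized <= base.second_hits.n_prioritized
        assert len(tightened.missense.homozygous) <= len(base.missense.homozygous)
        assert tightened.stage_counts["freq_pass"] <= base.stage_counts["freq_pass"]


class TestAnnotationIO:
    def test_round_trip_and_contract(self, tmp_path, sibling_ptv_table):
        path = tmp_path / "annot.tsv"
        sibling_ptv_table.to_csv(path, sep="\t", index=False)
        back = read_annotation_tsv(path)
        assert len(back) == len(sibling_ptv_table)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"chrom": ["chr1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_annotation_tsv(path)

    def test_unknown_class_rejected(self, tmp_path, sibling_ptv_table):
        bad = sibling_ptv_table.copy()
        bad.loc[0, "func_class"] = "weird"
        path = tmp_path / "bad2.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="functional class"):
            read_annotation_tsv(path)
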