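"""Recessive-candidate filtering and the known-gene panel scan.

The recessive cascade over an annotated exome table runs: restrict to
the family's "two haplotypes shared" regions; select protein-truncating
variants (PTVs: stop-gained, frameshift, canonical splice site); drop
variants above 10% allele frequency in any reference database or above
30% in the internal cohort (likely platform artifacts); then, in genes
with a heterozygous PTV, search for a second hit (another PTV or a
missense variant passing the same cut-offs), prioritizing gene pairs
whose members are all below 2% — the frequency regime plausible for a
causal recessive allele.  A parallel scan keeps rare (<1%) missense
variants with deleteriousness support (PolyPhen > 0.7 and Grantham >
75) that are homozygous or paired within a gene.

Independently of haplotype sharing, a panel of known and suspected
breast-cancer susceptibility genes is scanned: PTVs pass an allele
frequency cut-off of 0.1% in high-risk genes and 2% in moderate-risk
genes; missense variants pass below 2% when supported by CADD > 20 or
located in a level-1/2 gene.

Variant tables are pandas DataFrames with the columns in
:data:`ANNOTATION_COLUMNS`.  "Allele frequency" comparisons use the
maximum over the available reference databases; absent entries are
ignored, never treated as zero-failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import SharedRegionSet

#: Reference-population allele-frequency columns (fractions in [0, 1]).
REFERENCE_AF_COLUMNS = ["af_evs", "af_hapmap", "af_1000g", "af_exac", "af_gonl"]

#: Canonical column order of an annotated variant table.
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "func_class",
    "genotype",  # proband genotype: "het" | "hom-alt"
    "carrier_count",  # sibs carrying the allele (co-segregation numerator)
    "n_sibs_tested",
    *REFERENCE_AF_COLUMNS,
    "af_internal",
    "polyphen",
    "grantham",
    "cadd",
]

PTV_CLASSES = frozenset({"stop-gained", "frameshift", "canonical-splice"})


class ChromosomeDialectError(ValueError):
    """Variant and region chromosome names use different dialects."""


def is_ptv(func_class: str) -> bool:
    """True iff the functional class is protein-truncating."""
    return func_class in PTV_CLASSES


def ptv_mask(variants: pd.DataFrame) -> pd.Series:
    return variants["func_class"].isin(PTV_CLASSES)


def max_reference_af(variants: pd.DataFrame) -> pd.Series:
    """Maximum allele frequency across available reference databases.

    NaN when the variant is absent from every database.
    """
    return variants[REFERENCE_AF_COLUMNS].max(axis=1, skipna=True)


def region_filter(
    variants: pd.DataFrame, region_set: SharedRegionSet
) -> pd.DataFrame:
    """Keep variants lying inside any shared region (1-based inclusive).

    Raises :class:`ChromosomeDialectError` when variant and region
    chromosome names would only match after adding/stripping a ``chr``
    prefix, rather than silently dropping everything.
    """
    if len(variants) == 0 or not region_set.regions:
        return variants.iloc[0:0]
    var_chroms = set(variants["chrom"].astype(str))
    reg_chroms = {r.chrom for r in region_set.regions}
    if not var_chroms & reg_chroms:
        strip = lambda c: c[3:] if c.startswith("chr") else c
        if {strip(c) for c in var_chroms} & {strip(c) for c in reg_chroms}:
            raise ChromosomeDialectError(
                f"chromosome naming mismatch between variants ({sorted(var_chroms)[:3]}...) "
                f"and regions ({sorted(reg_chroms)[:3]}...)"
            )
    trees: dict[str, IntervalTree] = {}
    for r in region_set.regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
    keep = np.array(
        [
            chrom in trees and bool(trees[chrom].overlaps_point(pos))
            for chrom, pos in zip(variants["chrom"], variants["pos"])
        ]
    )
    return variants.loc[keep]


def frequency_filter(
    variants: pd.DataFrame,
    reference_max: float = 0.10,
    internal_max: float = 0.30,
) -> pd.Series:
    """Keep-mask of the reference/internal allele-frequency filter.

    A variant is dropped iff any available reference-database frequency
    exceeds ``reference_max`` or the internal cohort frequency exceeds
    ``internal_max`` (the latter flags experiment-specific artifacts).
    """
    ref_excess = (variants[REFERENCE_AF_COLUMNS] > reference_max).any(axis=1)
    internal_excess = variants["af_internal"] > internal_max
    return ~(ref_excess | internal_excess.fillna(False))


@dataclass
class SecondHitResult:
    """Compound-het gene pairs and homozygous single-variant candidates.

    ``pairs`` has one row per (het PTV, second het variant) combination
    within a gene; ``homozygous`` one row per homozygous PTV.  Both
    carry a ``prioritized`` flag: True iff every available reference
    frequency of every member variant is strictly below the causal
    cut-off.
    """

    pairs: pd.DataFrame
    homozygous: pd.DataFrame

    @property
    def prioritized_pairs(self) -> pd.DataFrame:
        return self.pairs.loc[self.pairs["prioritized"]]

    @property
    def prioritized_homozygous(self) -> pd.DataFrame:
        return self.homozygous.loc[self.homozygous["prioritized"]]

    @property
    def n_prioritized(self) -> int:
        return int(self.pairs["prioritized"].sum()) + int(
            self.homozygous["prioritized"].sum()
        )


def _all_refs_below(row: pd.Series, cutoff: float) -> bool:
    vals = row[REFERENCE_AF_COLUMNS].astype(float)
    return bool((vals.dropna() < cutoff).all())


def second_hit_search(
    variants: pd.DataFrame, causal_max: float = 0.02
) -> SecondHitResult:
    """Search genes carrying a heterozygous PTV for a second hit.

    ``variants`` must already be region- and frequency-filtered at the
    10%/30% stage.  For each gene with a het PTV, every other het
    variant in the gene that is a PTV or missense is reported as a
    candidate pair; homozygous PTVs are reported as single-variant
    candidates.  Pairs/candidates are prioritized when all member
    variants sit below ``causal_max`` in every database where they are
    observed.
    """
    ptvs = variants.loc[ptv_mask(variants)]
    hom = ptvs.loc[ptvs["genotype"] == "hom-alt"]
    hom_rows = []
    for idx, row in hom.iterrows():
        hom_rows.append(
            {
                "gene": row["gene"],
                "chrom": row["chrom"],
                "pos": row["pos"],
                "func_class": row["func_class"],
                "max_ref_af": max_reference_af(hom.loc[[idx]]).iloc[0],
                "prioritized": _all_refs_below(row, causal_max),
            }
        )

    het_ptvs = ptvs.loc[ptvs["genotype"] == "het"]
    pair_rows = []
    second_ok = variants["func_class"].isin(PTV_CLASSES | {"missense"})
    for gene, gene_ptvs in het_ptvs.groupby("gene", sort=False):
        gene_vars = variants.loc[
            (variants["gene"] == gene)
            & (variants["genotype"] == "het")
            & second_ok
        ]
        for pidx, prow in gene_ptvs.iterrows():
            for sidx, srow in gene_vars.iterrows():
                if sidx == pidx:
                    continue
                # emit each unordered pair once (PTV-PTV pairs would
                # otherwise appear twice)
                if is_ptv(srow["func_class"]) and sidx < pidx:
                    continue
                pair_rows.append(
                    {
                        "gene": gene,
                        "chrom": prow["chrom"],
                        "ptv_pos": prow["pos"],
                        "ptv_class": prow["func_class"],
                        "second_pos": srow["pos"],
                        "second_class": srow["func_class"],
                        "prioritized": _all_refs_below(prow, causal_max)
                        and _all_refs_below(srow, causal_max),
                    }
                )

    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "gene",
            "chrom",
            "ptv_pos",
            "ptv_class",
            "second_pos",
            "second_class",
            "prioritized",
        ],
    )
    homozygous = pd.DataFrame(
        hom_rows,
        columns=["gene", "chrom", "pos", "func_class", "max_ref_af", "prioritized"],
    )
    return SecondHitResult(pairs=pairs, homozygous=homozygous)


@dataclass
class MissenseScanResult:
    """Rare deleterious missense candidates (homozygous or gene pairs)."""

    homozygous: pd.DataFrame
    pairs: pd.DataFrame
    n_missing_scores: int


def missense_recessive_scan(
    variants: pd.DataFrame,
    af_max: float = 0.01,
    polyphen_min: float = 0.7,
    grantham_min: float = 75.0,
) -> MissenseScanResult:
    """Scan in-region missense variants for a recessive configuration.

    Keeps missense variants with every available reference frequency
    below ``af_max`` and both deleteriousness scores above their gates
    (a missing score fails the gate and is counted, not imputed), then
    reports homozygotes and same-gene het pairs.
    """
    mis = variants.loc[variants["func_class"] == "missense"]
    missing_scores = int(
        (mis["polyphen"].isna() | mis["grantham"].isna()).sum()
    )
    rare = mis.apply(lambda r: _all_refs_below(r, af_max), axis=1) if len(mis) else pd.Series(dtype=bool)
    deleterious = (mis["polyphen"] > polyphen_min) & (mis["grantham"] > grantham_min)
    kept = mis.loc[rare & deleterious] if len(mis) else mis

    homozygous = kept.loc[kept["genotype"] == "hom-alt"]
    het = kept.loc[kept["genotype"] == "het"]
    pair_rows = []
    for gene, g in het.groupby("gene", sort=False):
        if len(g) >= 2:
            idxs = list(g.index)
            for a in range(len(idxs)):
                for b in range(a + 1, len(idxs)):
                    pair_rows.append(
                        {
                            "gene": gene,
                            "chrom": g.loc[idxs[a], "chrom"],
                            "pos1": g.loc[idxs[a], "pos"],
                            "pos2": g.loc[idxs[b], "pos"],
                        }
                    )
    pairs = pd.DataFrame(pair_rows, columns=["gene", "chrom", "pos1", "pos2"])
    return MissenseScanResult(
        homozygous=homozygous, pairs=pairs, n_missing_scores=missing_scores
    )


# ---------------------------------------------------------------------------
# Known-gene panel scan
# ---------------------------------------------------------------------------

#: Genes screened at the stringent high-risk PTV cut-off (0.1%).
HIGH_RISK_GENES = frozenset({"BRCA1", "BRCA2", "PALB2", "TP53", "PTEN", "CDH1"})
#: Genes screened at the moderate-risk PTV cut-off (2%).
MODERATE_RISK_GENES = frozenset({"ATM", "CHEK2"})

_DEFAULT_PANEL_LEVELS: dict[str, str] = {
    # level 1: established high-risk
    "BRCA1": "1", "BRCA2": "1", "PALB2": "1",
    # syndromic: high-risk within broader cancer syndromes
    "TP53": "syndromic", "CDH1": "syndromic", "PTEN": "syndromic",
    # level 2: established moderate-risk
    "ATM": "2", "CHEK2": "2",
    # level 3: suspected, evidence accumulating
    "BARD1": "3", "BRIP1": "3", "RAD51C": "3", "RAD51D": "3", "NBN": "3",
    "NF1": "3", "STK11": "3", "FANCM": "3", "RECQL": "3", "MSH6": "3",
    "PMS2": "3", "CDKN2A": "3",
    # level 4: reported, evidence weak or conflicting
    "MLH1": "4", "MSH2": "4", "EPCAM": "4", "MRE11A": "4", "RAD50": "4",
    "XRCC2": "4", "XRCC3": "4", "AXIN2": "4", "BLM": "4", "FANCC": "4",
    "GEN1": "4", "PPM1D": "4", "RINT1": "4", "SLX4": "4", "MUTYH": "4",
}


@dataclass
class GenePanel:
    """Susceptibility-gene panel with evidence levels and PTV tiers.

    ``levels`` maps gene symbol to evidence level in
    ``{"1", "2", "3", "4", "syndromic"}``.  PTV frequency cut-offs are
    per risk tier: ``high_risk_ptv_max`` for the six high-risk genes and
    ``moderate_risk_ptv_max`` for the moderate-risk genes; PTVs in the
    remaining genes are not tier-filtered here.
    """

    levels: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PANEL_LEVELS)
    )
    high_risk_genes: frozenset = HIGH_RISK_GENES
    moderate_risk_genes: frozenset = MODERATE_RISK_GENES
    high_risk_ptv_max: float = 0.001
    moderate_risk_ptv_max: float = 0.02

    def __post_init__(self) -> None:
        required = self.high_risk_genes | self.moderate_risk_genes
        missing = required - set(self.levels)
        if missing:
            raise ValueError(f"panel is missing required genes: {sorted(missing)}")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.levels)

    def is_level12(self, gene: str) -> bool:
        """Level-1/2 evidence (high-risk, syndromic high-risk, or moderate)."""
        return self.levels.get(gene) in {"1", "2", "syndromic"}

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "GenePanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(levels=dict(zip(df["gene"], df["level"])), **kwargs)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene": list(self.levels), "level": list(self.levels.values())}
        ).to_csv(path, sep="\t", index=False)


def default_gene_panel() -> GenePanel:
    """The default 35-gene panel.

    The eight genes with a fixed tier assignment (six high-risk, two
    moderate) are those universally present on diagnostic breast-cancer
    panels; the remaining membership is a representative choice and is
    user-replaceable via :meth:`GenePanel.from_tsv`.
    """
    return GenePanel()


@dataclass
class PanelScanResult:
    findings: pd.DataFrame
    n_nonpanel: int  #: variants in genes outside the panel (ignored)


def panel_scan(
    variants: pd.DataFrame,
    panel: GenePanel | None = None,
    missense_af_max: float = 0.02,
    cadd_min: float = 20.0,
) -> PanelScanResult:
    """Scan panel genes for qualifying variants, regardless of sharing.

    PTVs in high/moderate-risk genes are kept when their maximum
    reference frequency does not exceed the tier cut-off (0.1% / 2%).
    Missense variants in any panel gene are kept when their maximum
    reference frequency is below ``missense_af_max`` and either their
    CADD score exceeds ``cadd_min`` or the gene has level-1/2 evidence.
    Findings carry co-segregation counts when sib genotypes are present.
    """
    if panel is None:
        panel = default_gene_panel()
    in_panel = variants["gene"].isin(panel.genes)
    n_nonpanel = int((~in_panel).sum())
    pv = variants.loc[in_panel]

    rows = []
    max_af = max_reference_af(pv)
    for idx, row in pv.iterrows():
        gene = row["gene"]
        af = max_af.loc[idx]
        reason = None
        if is_ptv(row["func_class"]):
            if gene in panel.high_risk_genes:
                cutoff = panel.high_risk_ptv_max
            elif gene in panel.moderate_risk_genes:
                cutoff = panel.moderate_risk_ptv_max
            else:
                continue
            if pd.isna(af) or af <= cutoff:
                reason = f"PTV<= {cutoff:g}"
        elif row["func_class"] == "missense":
            rare = pd.isna(af) or af < missense_af_max
            cadd_ok = pd.notna(row["cadd"]) and row["cadd"] > cadd_min
            if rare and (cadd_ok or panel.is_level12(gene)):
                reason = "missense CADD" if cadd_ok else "missense level-1/2"
        if reason is not None:
            rows.append(
                {
                    "gene": gene,
                    "level": panel.levels[gene],
                    "chrom": row["chrom"],
                    "pos": row["pos"],
                    "func_class": row["func_class"],
                    "genotype": row["genotype"],
                    "max_ref_af": af,
                    "cadd": row["cadd"],
                    "co_segregation": (
                        f"{int(row['carrier_count'])}/{int(row['n_sibs_tested'])}"
                        if pd.notna(row.get("carrier_count"))
                        else None
                    ),
                    "reason": reason,
                }
            )
    findings = pd.DataFrame(
        rows,
        columns=[
            "gene", "level", "chrom", "pos", "func_class", "genotype",
            "max_ref_af", "cadd", "co_segregation", "reason",
        ],
    )
    return PanelScanResult(findings=findings, n_nonpanel=n_nonpanel)


# ---------------------------------------------------------------------------
# Cascade driver
# ---------------------------------------------------------------------------


@dataclass
class CandidateReport:
    """Stage-tagged result of the recessive cascade for one family."""

    family_id: str
    mode: str
    excluded_sib: str | None
    stage_counts: dict[str, int]
    variants: pd.DataFrame  # region-pass variants with boolean stage tags
    second_hits: SecondHitResult
    missense: MissenseScanResult


def run_recessive_filter(
    variants: pd.DataFrame,
    region_set: SharedRegionSet,
    *,
    reference_max: float = 0.10,
    internal_max: float = 0.30,
    causal_max: float = 0.02,
    missense_af_max: float = 0.01,
    polyphen_min: float = 0.7,
    grantham_min: float = 75.0,
    excluded_sib: str | None = None,
) -> CandidateReport:
    """Run the full recessive cascade over one family's variant table."""
    n_input = len(variants)
    in_region = region_filter(variants, region_set).copy()
    freq_keep = frequency_filter(in_region, reference_max, internal_max)
    filtered = in_region.loc[freq_keep]
    ptvs = filtered.loc[ptv_mask(filtered)]
    second = second_hit_search(filtered, causal_max=causal_max)
    mis = missense_recessive_scan(
        filtered,
        af_max=missense_af_max,
        polyphen_min=polyphen_min,
        grantham_min=grantham_min,
    )

    tagged = in_region.copy()
    tagged["region_pass"] = True
    tagged["freq_pass"] = freq_keep
    tagged["ptv"] = ptv_mask(in_region) & freq_keep
    counts = {
        "input": n_input,
        "region_pass": len(in_region),
        "freq_pass": int(freq_keep.sum()),
        "ptv": len(ptvs),
        "compound_het_pairs": len(second.pairs),
        "homozygous_ptv": len(second.homozygous),
        "prioritized": second.n_prioritized,
        "missense_candidates": len(mis.homozygous) + len(mis.pairs),
    }
    return CandidateReport(
        family_id=region_set.family_id,
        mode=region_set.mode,
        excluded_sib=excluded_sib,
        stage_counts=counts,
        variants=tagged,
        second_hits=second,
        missense=mis,
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read an annotated variant table, checking the column contract."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad_class = ~df["func_class"].isin(
        PTV_CLASSES | {"missense", "synonymous", "other"}
    )
    if bad_class.any():
        raise ValueError(
            f"unknown functional classes: {sorted(df.loc[bad_class, 'func_class'].unique())}"
        )
    for col in REFERENCE_AF_COLUMNS + ["af_internal"]:
        v = df[col]
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read proband genotypes from a VCF into (chrom, pos, ref, alt, genotype).

    Multi-allelic records are split into biallelic rows.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for rec in vcf:
        gts = rec.genotypes[0] if rec.genotypes else None
        for ai, alt in enumerate(rec.ALT, start=1):
            if gts is None:
                genotype = None
            else:
                n_alt = sum(1 for a in gts[:2] if a == ai)
                genotype = {2: "hom-alt", 1: "het"}.get(n_alt)
            if genotype is None:
                continue
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "genotype": genotype,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype"])
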