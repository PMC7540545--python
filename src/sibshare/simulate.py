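"""Seeded generators for every pipeline input.

Three generators cover the three data kinds the pipeline consumes:

* :func:`simulate_family` — linkage-density marker genotypes for a
  sibship of affected sibs descending from two unobserved parents, with
  the true per-pair IBD state recorded at every marker.  Meioses follow
  a crossover process with recombination fractions from the Haldane map
  function, so the truth process is exactly the Markov chain the IBD
  HMM assumes.
* :func:`simulate_exome_table` — an annotated exome variant table (plus
  a VCF of the proband's genotypes) containing planted recessive
  candidates (homozygous PTV, compound-het PTV+missense, or homozygous
  missense) inside regions where the sibship truly shares two
  haplotypes, surrounded by decoy variants drawn uniformly over the
  same chromosome scaffold.
* :func:`simulate_prs_cohorts` — risk-allele dosages for population
  controls, population cases and ascertained affected sibships under a
  log-additive liability model, for exercising the polygenic risk score
  analysis.

Parents are never emitted (the study design has no parental DNA); truth
labels live in dedicated fields/files that the analysis pipeline never
reads.  All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ibd import MISSING, haldane_theta

# ---------------------------------------------------------------------------
# Sibship marker-genotype simulation
# ---------------------------------------------------------------------------


@dataclass
class SimParams:
    """Parameters of the sibship marker-genotype simulation.

    Defaults emulate a genome-wide linkage panel: ~6,000 biallelic
    markers spread over 22 autosomes at roughly 0.6 cM spacing,
    moderately informative allele frequencies, and a small per-genotype
    error rate.
    """

    n_markers: int = 6000
    n_chromosomes: int = 22
    marker_spacing_cM: float = 0.6
    marker_maf_range: tuple[float, float] = (0.2, 0.5)
    genotype_error_rate: float = 0.005
    n_sibs: int = 3
    n_families: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        if self.n_markers < 2 * self.n_chromosomes:
            raise ValueError(
                f"n_markers={self.n_markers}: need >= 2 markers per chromosome"
            )
        lo, hi = self.marker_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"marker_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.marker_maf_range}"
            )
        if not 0.0 <= self.genotype_error_rate < 0.5:
            raise ValueError(
                f"genotype_error_rate must lie in [0, 0.5), got {self.genotype_error_rate}"
            )
        if self.n_sibs < 2:
            raise ValueError(f"n_sibs must be >= 2, got {self.n_sibs}")
        if self.n_families < 1:
            raise ValueError(f"n_families must be >= 1, got {self.n_families}")
        if not self.marker_spacing_cM > 0:
            raise ValueError(
                f"marker_spacing_cM must be positive, got {self.marker_spacing_cM}"
            )


@dataclass
class Sibship:
    family_id: str
    sib_ids: list[str]
    proband: str

    @property
    def n_sibs(self) -> int:
        return len(self.sib_ids)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        ids = self.sib_ids
        return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


@dataclass
class SibshipDataset:
    """One simulated family: genotypes plus private truth labels.

    ``genotypes`` is sibs x markers of counted-allele dosages (``-1``
    missing); ``truth_ibd`` is pairs x markers of true IBD states,
    derived from the transmitted parental haplotype labels and never
    visible to the estimation pipeline.
    """

    sibship: Sibship
    marker_map: pd.DataFrame
    genotypes: pd.DataFrame  # index: sib ids, columns: marker ids
    truth_ibd: np.ndarray  # (n_pairs, n_markers) int8
    truth_parent_haplotypes: np.ndarray  # (4, n_markers) alleles in {0,1}
    truth_inheritance: np.ndarray = field(repr=False, default=None)  # (n_sibs, 2, M)
    error_mask: np.ndarray = field(repr=False, default=None)  # (n_sibs, M) bool

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return self.sibship.pairs


def _build_marker_map(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = params.n_markers // params.n_chromosomes
    counts = [per_chrom] * params.n_chromosomes
    for i in range(params.n_markers - per_chrom * params.n_chromosomes):
        counts[i] += 1
    rows = []
    lo, hi = params.marker_maf_range
    finite_spacing = math.isfinite(params.marker_spacing_cM)
    # unlinked (infinite) spacing is stored as a huge finite gap so the
    # Haldane recombination fraction saturates at exactly 0.5
    spacing = params.marker_spacing_cM if finite_spacing else 1e7
    for c, n in enumerate(counts, start=1):
        cm = np.arange(n) * spacing
        # physical scale: 1 Mb per cM; unlinked maps fall back to 1 Mb
        # between markers so the bp scaffold stays sane
        step_bp = int(spacing * 1_000_000) if finite_spacing else 1_000_000
        bp = 1_000_000 + np.arange(n, dtype=np.int64) * step_bp
        freqs = rng.uniform(lo, hi, size=n)
        rows.append(
            pd.DataFrame(
                {"chrom": f"chr{c}", "pos_bp": bp, "pos_cM": cm, "freq": freqs}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.index = [f"rs{i:06d}" for i in range(len(out))]
    return out


def _meiosis(
    rng: np.random.Generator, n_markers_per_chrom: list[int], thetas_per_chrom: list[np.ndarray]
) -> np.ndarray:
    """One gamete's haplotype labels (0/1) along the genome."""
    labels = []
    for n, thetas in zip(n_markers_per_chrom, thetas_per_chrom):
        lab = np.empty(n, dtype=np.int8)
        lab[0] = rng.integers(0, 2)
        flips = rng.random(n - 1) < thetas
        lab[1:] = flips
        labels.append(np.bitwise_xor.accumulate(lab) if n > 1 else lab)
    return np.concatenate(labels)


def simulate_family(
    params: SimParams, family_id: str = "F1", rng: np.random.Generator | None = None
) -> SibshipDataset:
    """Simulate one sibship's linkage-marker genotypes with known truth.

    Parents are drawn under Hardy-Weinberg from per-marker counted-allele
    frequencies; each sib receives one recombinant haplotype per parent
    with crossovers given by the Haldane map function on the cM spacing.
    True IBD per pair per marker is the number of parents from whom the
    two sibs received the same haplotype.  Genotype errors replace the
    true genotype with a uniformly chosen different genotype,
    independently at the configured rate.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    marker_map = _build_marker_map(params, rng)
    M = len(marker_map)
    freqs = marker_map["freq"].to_numpy()

    # four parental haplotypes: rows 0,1 = parent A; 2,3 = parent B
    parent_haps = (rng.random((4, M)) < freqs).astype(np.int8)

    chrom_sizes = [len(g) for _, g in marker_map.groupby("chrom", sort=False)]
    thetas = [
        haldane_theta(np.diff(g["pos_cM"].to_numpy()))
        for _, g in marker_map.groupby("chrom", sort=False)
    ]

    n = params.n_sibs
    inheritance = np.empty((n, 2, M), dtype=np.int8)
    genotypes = np.empty((n, M), dtype=np.int8)
    for s in range(n):
        lab_a = _meiosis(rng, chrom_sizes, thetas)
        lab_b = _meiosis(rng, chrom_sizes, thetas)
        inheritance[s, 0] = lab_a
        inheritance[s, 1] = lab_b
        hap_a = parent_haps[lab_a, np.arange(M)]
        hap_b = parent_haps[2 + lab_b, np.arange(M)]
        genotypes[s] = hap_a + hap_b

    # symmetric genotype errors: replace with a uniform different genotype
    error_mask = rng.random((n, M)) < params.genotype_error_rate
    if error_mask.any():
        shift = rng.integers(1, 3, size=error_mask.sum())
        idx = np.nonzero(error_mask)
        genotypes[idx] = ((genotypes[idx] + shift) % 3).astype(np.int8)

    sib_ids = [f"{family_id}_S{i+1}" for i in range(n)]
    sibship = Sibship(family_id=family_id, sib_ids=sib_ids, proband=sib_ids[0])
    pairs_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    truth_ibd = np.empty((len(pairs_idx), M), dtype=np.int8)
    for p, (i, j) in enumerate(pairs_idx):
        truth_ibd[p] = (inheritance[i, 0] == inheritance[j, 0]).astype(np.int8) + (
            inheritance[i, 1] == inheritance[j, 1]
        ).astype(np.int8)

    return SibshipDataset(
        sibship=sibship,
        marker_map=marker_map,
        genotypes=pd.DataFrame(genotypes, index=sib_ids, columns=marker_map.index),
        truth_ibd=truth_ibd,
        truth_parent_haplotypes=parent_haps,
        truth_inheritance=inheritance,
        error_mask=error_mask,
    )


def simulate_families(params: SimParams) -> list[SibshipDataset]:
    """Simulate ``params.n_families`` independent sibships from one seed."""
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_families)
    return [
        simulate_family(params, family_id=f"F{i+1}", rng=np.random.default_rng(child))
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# Exome variant-table simulation
# ---------------------------------------------------------------------------

from .filters import ANNOTATION_COLUMNS, REFERENCE_AF_COLUMNS  # noqa: E402

_DECOY_CLASSES = np.array(
    ["synonymous", "missense", "other", "stop-gained", "frameshift", "canonical-splice"]
)
_DECOY_CLASS_PROBS = np.array([0.35, 0.45, 0.12, 0.03, 0.03, 0.02])


@dataclass
class PlantedCandidate:
    """A recessive candidate to plant inside a truth IBD2-shared region.

    ``mechanism`` is one of ``homozygous-ptv``, ``compound-het``,
    ``homozygous-missense`` or ``none``.  ``allele_frequency`` feeds
    every reference-database AF column (with the compound-het missense
    partner using ``partner_frequency``).
    """

    mechanism: str
    gene: str = "PLANT1"
    allele_frequency: float = 0.005
    partner_frequency: float = 0.013
    polyphen: float = 0.95
    grantham: float = 110.0
    cadd: float = 28.0

    _MECHANISMS = ("homozygous-ptv", "compound-het", "homozygous-missense", "none")

    def __post_init__(self) -> None:
        if self.mechanism not in self._MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {self._MECHANISMS}, got {self.mechanism!r}"
            )


@dataclass
class ExomeSimSpec:
    """Specification of one family's simulated exome table."""

    n_decoy_variants: int = 1500
    planted: list[PlantedCandidate] = field(default_factory=list)
    frequency_spectrum: tuple[float, float] = (1e-4, 0.5)  # log-uniform bounds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoy_variants < 0:
            raise ValueError("n_decoy_variants must be >= 0")
        lo, hi = self.frequency_spectrum
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError(
                f"frequency_spectrum bounds must satisfy 0 < lo < hi <= 1, got {self.frequency_spectrum}"
            )


class PlantingError(RuntimeError):
    """Planting a candidate was impossible for the given family."""


@dataclass
class SimulatedExome:
    """Annotated variant table plus proband VCF text for one family."""

    family_id: str
    proband: str
    variants: pd.DataFrame  # ANNOTATION_COLUMNS order
    truth: pd.DataFrame  # chrom, pos, gene, origin (planted mechanism | decoy)
    vcf_text: str

    def write(self, vcf_path, tsv_path, truth_path=None) -> None:
        with open(vcf_path, "w") as fh:
            fh.write(self.vcf_text)
        self.variants.to_csv(tsv_path, sep="\t", index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _truth_strict_ibd2_spans(dataset: SibshipDataset) -> list[tuple[str, int, int]]:
    """Maximal (chrom, start_bp, end_bp) spans where truth IBD = 2 for all pairs."""
    shared = np.all(dataset.truth_ibd == 2, axis=0)
    spans: list[tuple[str, int, int]] = []
    mm = dataset.marker_map
    chroms = mm["chrom"].to_numpy()
    pos = mm["pos_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sel = shared[idx]
        m = 0
        while m < len(idx):
            if sel[m]:
                start = m
                while m + 1 < len(idx) and sel[m + 1]:
                    m += 1
                spans.append((chrom, int(pos[idx[start]]), int(pos[idx[m]])))
            m += 1
    return spans


def _decoy_gene(chrom: str, pos: int) -> str:
    """Deterministic gene assignment: ~100 kb gene bins along each chromosome."""
    return f"G{chrom[3:]}_{pos // 100_000:05d}"


def simulate_exome_table(dataset: SibshipDataset, spec: ExomeSimSpec) -> SimulatedExome:
    """Simulate the proband's annotated exome for one sibship.

    Decoys are placed uniformly over the chromosome scaffold spanned by
    the linkage markers, with log-uniform reference allele frequencies,
    genotypes drawn from HWE conditional on the proband carrying the
    alternate allele, and in-silico scores typical of their functional
    class.  Planted candidates are positioned inside spans where the
    whole sibship truly shares two haplotypes, with genotypes consistent
    with their recessive mechanism in every affected sib.
    """
    rng = np.random.default_rng(spec.seed)
    mm = dataset.marker_map
    fam = dataset.sibship
    n_sibs = fam.n_sibs

    chrom_bounds = {
        chrom: (int(g["pos_bp"].iloc[0]), int(g["pos_bp"].iloc[-1]))
        for chrom, g in mm.groupby("chrom", sort=False)
    }
    chrom_names = list(chrom_bounds)
    chrom_lengths = np.array(
        [hi - lo + 1 for lo, hi in chrom_bounds.values()], dtype=float
    )
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    rows: list[dict] = []
    truth_rows: list[dict] = []

    # --- decoys ---------------------------------------------------------
    lo_f, hi_f = spec.frequency_spectrum
    for _ in range(spec.n_decoy_variants):
        ci = rng.choice(len(chrom_names), p=chrom_probs)
        chrom = chrom_names[ci]
        lo, hi = chrom_bounds[chrom]
        pos = int(rng.integers(lo, hi + 1))
        af = float(np.exp(rng.uniform(np.log(lo_f), np.log(hi_f))))
        func = str(rng.choice(_DECOY_CLASSES, p=_DECOY_CLASS_PROBS))
        p_hom = af / (2.0 - af)  # P(hom-alt | carries >= 1 alt) under HWE
        genotype = "hom-alt" if rng.random() < p_hom else "het"
        ref_afs = {}
        for col in REFERENCE_AF_COLUMNS:
            if rng.random() < 0.8:
                ref_afs[col] = min(1.0, af * float(rng.lognormal(0.0, 0.25)))
            else:
                ref_afs[col] = np.nan
        internal = min(
            1.0, max(0.0, af + rng.normal(0.0, 0.02)) + (0.3 if rng.random() < 0.01 else 0.0)
        )
        is_missense = func == "missense"
        carriers = 1 + int(rng.binomial(n_sibs - 1, min(1.0, 2 * af)))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "T" if func != "frameshift" else "TA",
                "gene": _decoy_gene(chrom, pos),
                "func_class": func,
                "genotype": genotype,
                "carrier_count": carriers,
                "n_sibs_tested": n_sibs,
                **ref_afs,
                "af_internal": internal,
                "polyphen": float(rng.uniform(0, 1)) if is_missense else np.nan,
                "grantham": float(rng.uniform(5, 215)) if is_missense else np.nan,
                "cadd": float(rng.gamma(2.0, 6.0)),
            }
        )
        truth_rows.append({"chrom": chrom, "pos": pos, "gene": rows[-1]["gene"], "origin": "decoy"})

    # --- planted candidates --------------------------------------------
    spans = _truth_strict_ibd2_spans(dataset)
    any_planting = any(p.mechanism != "none" for p in spec.planted)
    if any_planting and not spans:
        raise PlantingError(
            f"family {fam.family_id}: no truth IBD2-shared span exists to plant into"
        )
    for cand in spec.planted:
        if cand.mechanism == "none":
            continue
        # plant inside the central half of the longest truth span: the
        # candidate must sit where the sharing signal is well supported
        # by flanking markers, as a true recessive allele would be
        chrom, lo, hi = max(spans, key=lambda s: s[2] - s[1])
        width = hi - lo
        lo_c, hi_c = lo + width // 4, hi - width // 4
        positions = sorted(
            int(p) for p in rng.choice(np.arange(lo_c, hi_c + 1), size=2, replace=False)
        )

        def _plant_row(pos, func, genotype, af, polyphen=np.nan, grantham=np.nan):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": "G",
                    "alt": "A" if func != "frameshift" else "AG",
                    "gene": cand.gene,
                    "func_class": func,
                    "genotype": genotype,
                    "carrier_count": n_sibs,
                    "n_sibs_tested": n_sibs,
                    **{col: af for col in REFERENCE_AF_COLUMNS},
                    "af_internal": min(1.0, af + 0.01),
                    "polyphen": polyphen,
                    "grantham": grantham,
                    "cadd": cand.cadd,
                }
            )
            truth_rows.append(
                {"chrom": chrom, "pos": pos, "gene": cand.gene, "origin": cand.mechanism}
            )

        if cand.mechanism == "homozygous-ptv":
            _plant_row(positions[0], "stop-gained", "hom-alt", cand.allele_frequency)
        elif cand.mechanism == "compound-het":
            _plant_row(positions[0], "stop-gained", "het", cand.allele_frequency)
            _plant_row(
                positions[1],
                "missense",
                "het",
                cand.partner_frequency,
                polyphen=cand.polyphen,
                grantham=cand.grantham,
            )
        elif cand.mechanism == "homozygous-missense":
            _plant_row(
                positions[0],
                "missense",
                "hom-alt",
                cand.allele_frequency,
                polyphen=cand.polyphen,
                grantham=cand.grantham,
            )

    variants = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    order = np.lexsort(
        (variants["pos"].to_numpy(), variants["chrom"].str[3:].astype(int).to_numpy())
    )
    variants = variants.iloc[order].reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)

    vcf_text = _variants_to_vcf(variants, fam.proband, chrom_bounds)
    return SimulatedExome(
        family_id=fam.family_id,
        proband=fam.proband,
        variants=variants,
        truth=truth,
        vcf_text=vcf_text,
    )


def _variants_to_vcf(variants: pd.DataFrame, proband: str, chrom_bounds: dict) -> str:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=sibshare-simulate\n")
    for chrom, (_, hi) in chrom_bounds.items():
        buf.write(f"##contig=<ID={chrom},length={hi + 1_000_000}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{proband}\n")
    for row in variants.itertuples(index=False):
        gt = "1/1" if row.genotype == "hom-alt" else "0/1"
        buf.write(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gt}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# PRS cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class PrsCohortSpec:
    """Specification of the simulated PRS cohorts.

    Disease follows a log-additive liability model: the log-odds of
    affection equal a baseline (set by ``prevalence``) plus the
    individual's centred raw PRS, a family-shared normal effect and an
    individual residual.  Sibships are ascertained by requiring all
    ``n_sibs`` siblings affected, mimicking selection of families with
    several affected sisters.
    """

    n_snps: int = 160
    or_range: tuple[float, float] = (1.05, 1.3)
    freq_range: tuple[float, float] = (0.1, 0.9)
    n_controls: int = 327
    n_cases: int = 357
    n_sibships: int = 19
    n_sibs: int = 3
    prevalence: float = 0.1
    family_sd: float = 0.8
    residual_sd: float = 0.8
    max_family_attempts: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.or_range[0] <= 0:
            raise ValueError("odds ratios must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"freq_range must lie inside (0, 1), got {self.freq_range}")
        if self.n_sibs < 2:
            raise ValueError("n_sibs must be >= 2")


class AscertainmentError(RuntimeError):
    """The sibship ascertainment budget was exhausted."""


@dataclass
class PrsCohorts:
    """Simulated dosage tables for the three PRS study groups."""

    panel: pd.DataFrame  # snp, risk_allele, OR, freq
    controls: pd.DataFrame  # individuals x snps
    cases: pd.DataFrame
    sibships: pd.DataFrame  # affected sibs; index "<family>_S<i>"
    family_ids: pd.Series  # per sibship row

    @property
    def probands(self) -> pd.DataFrame:
        first = ~self.family_ids.duplicated()
        return self.sibships.loc[first.to_numpy()]


def default_prs_panel(spec: PrsCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    snps = [f"prs_snp_{i+1:03d}" for i in range(spec.n_snps)]
    return pd.DataFrame(
        {
            "snp": snps,
            "risk_allele": rng.choice(["A", "C", "G", "T"], size=spec.n_snps),
            "OR": rng.uniform(*spec.or_range, size=spec.n_snps),
            "freq": rng.uniform(*spec.freq_range, size=spec.n_snps),
        }
    )


def simulate_prs_cohorts(
    spec: PrsCohortSpec, panel: pd.DataFrame | None = None
) -> PrsCohorts:
    """Simulate controls, population cases and ascertained affected sibships.

    Founder dosages are Binomial(2, freq) per SNP; sibship members share
    parental haplotype draws.  Affection is Bernoulli with log-odds
    ``logit(prevalence) + (raw PRS - E[raw PRS]) + family effect +
    residual``.  Controls are unaffected founders; cases are affected
    founders; sibships are retained only when all siblings are affected,
    up to ``max_family_attempts`` candidate families.
    """
    rng = np.random.default_rng(spec.seed)
    if panel is None:
        panel = default_prs_panel(spec, rng)
    beta = np.log(panel["OR"].to_numpy(dtype=float))
    freq = panel["freq"].to_numpy(dtype=float)
    base = float(np.log(spec.prevalence / (1.0 - spec.prevalence)))
    mean_raw = float(2.0 * freq @ beta)

    def _affected(dosages: np.ndarray, fam_eff: np.ndarray) -> np.ndarray:
        logit = (
            base
            + dosages @ beta
            - mean_raw
            + fam_eff
            + rng.normal(0.0, spec.residual_sd, size=dosages.shape[0])
        )
        p = 1.0 / (1.0 + np.exp(-logit))
        return rng.random(dosages.shape[0]) < p

    def _sample_founders(n_needed: int, want_affected: bool) -> np.ndarray:
        kept = []
        total = 0
        while total < n_needed:
            batch = max(256, int(2.5 * (n_needed - total) / max(spec.prevalence, 0.05)))
            dos = rng.binomial(2, freq, size=(batch, spec.n_snps)).astype(np.int8)
            fam = rng.normal(0.0, spec.family_sd, size=batch)
            aff = _affected(dos, fam)
            sel = dos[aff] if want_affected else dos[~aff]
            kept.append(sel)
            total += len(sel)
        return np.concatenate(kept)[:n_needed]

    controls = _sample_founders(spec.n_controls, want_affected=False)
    cases = _sample_founders(spec.n_cases, want_affected=True)

    sib_rows: list[np.ndarray] = []
    fam_labels: list[str] = []
    families_found = 0
    attempts = 0
    batch_fams = 512
    while families_found < spec.n_sibships:
        if attempts >= spec.max_family_attempts:
            raise AscertainmentError(
                f"found only {families_found}/{spec.n_sibships} fully affected "
                f"sibships after {attempts} attempts"
            )
        n_batch = min(batch_fams, spec.max_family_attempts - attempts)
        attempts += n_batch
        # parental haplotype allele draws: (fam, parent, haplotype, snp)
        par = (rng.random((n_batch, 2, 2, spec.n_snps)) < freq).astype(np.int8)
        # each sib inherits one haplotype from each parent
        pick = rng.integers(0, 2, size=(n_batch, spec.n_sibs, 2, spec.n_snps))
        fam_idx = np.arange(n_batch)[:, None, None]
        snp_idx = np.arange(spec.n_snps)[None, None, :]
        mat = par[fam_idx, 0, pick[:, :, 0, :], snp_idx]
        pat = par[fam_idx, 1, pick[:, :, 1, :], snp_idx]
        dos = (mat + pat).astype(np.int8)  # (fam, sib, snp)
        fam_eff = rng.normal(0.0, spec.family_sd, size=n_batch)
        flat = dos.reshape(-1, spec.n_snps)
        aff = _affected(flat, np.repeat(fam_eff, spec.n_sibs)).reshape(
            n_batch, spec.n_sibs
        )
        for f in np.flatnonzero(aff.all(axis=1)):
            families_found += 1
            fid = f"PF{families_found}"
            for s in range(spec.n_sibs):
                sib_rows.append(dos[f, s])
                fam_labels.append(fid)
            if families_found == spec.n_sibships:
                break

    snps = panel["snp"].tolist()
    controls_df = pd.DataFrame(
        controls, columns=snps, index=[f"ctrl_{i+1}" for i in range(len(controls))]
    )
    cases_df = pd.DataFrame(
        cases, columns=snps, index=[f"case_{i+1}" for i in range(len(cases))]
    )
    sib_index = []
    counter: dict[str, int] = {}
    for fid in fam_labels:
        counter[fid] = counter.get(fid, 0) + 1
        sib_index.append(f"{fid}_S{counter[fid]}")
    sib_df = pd.DataFrame(np.array(sib_rows), columns=snps, index=sib_index)
    return PrsCohorts(
        panel=panel,
        controls=controls_df,
        cases=cases_df,
        sibships=sib_df,
        family_ids=pd.Series(fam_labels, index=sib_index),
    )


# ---------------------------------------------------------------------------
# Text output (PED/MAP-style)
# ---------------------------------------------------------------------------


def write_ped_map(dataset: SibshipDataset, ped_path, map_path) -> None:
    """Write genotypes as whitespace-delimited PED/MAP-style text.

    PED rows: family, individual, father(0), mother(0), sex(0),
    phenotype(2 = affected), then one dosage per marker (-1 missing).
    MAP rows: chrom, marker id, cM, bp, counted-allele frequency.
    """
    mm = dataset.marker_map
    with open(map_path, "w") as fh:
        for marker_id, row in mm.iterrows():
            fh.write(
                f"{row['chrom']}\t{marker_id}\t{row['pos_cM']:.6g}\t{int(row['pos_bp'])}\t{row['freq']:.6g}\n"
            )
    with open(ped_path, "w") as fh:
        fam = dataset.sibship.family_id
        for sib in dataset.sibship.sib_ids:
            dosages = " ".join(str(int(g)) for g in dataset.genotypes.loc[sib])
            fh.write(f"{fam} {sib} 0 0 0 2 {dosages}\n")


def read_ped_map(ped_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read PED/MAP-style text back into (genotypes, marker_map)."""
    mm = pd.read_csv(
        map_path,
        sep="\t",
        names=["chrom", "marker", "pos_cM", "pos_bp", "freq"],
    ).set_index("marker")
    mm = mm[["chrom", "pos_bp", "pos_cM", "freq"]]
    rows = {}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            rows[parts[1]] = np.array(parts[6:], dtype=np.int8)
    genotypes = pd.DataFrame.from_dict(rows, orient="index", columns=mm.index)
    return genotypes, mm
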