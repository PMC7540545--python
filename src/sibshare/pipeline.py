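"""End-to-end orchestration: simulate -> IBD -> regions -> filter -> PRS.

One :class:`RunConfig` (a YAML file or plain dict) drives the whole
pipeline.  Every filtering threshold is a named key with the standard
default; data either comes from the seeded generators (``sibsim``,
``exome``, ``prs`` blocks) or from files on disk (PED/MAP genotypes,
VCF + annotation TSV, panel/dosage TSVs) — exactly one source per data
kind.  Each run writes its stage outputs plus a JSON manifest recording
the seed, thresholds, package version and per-stage counts, and is
bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filters import (
    GenePanel,
    default_gene_panel,
    panel_scan,
    read_annotation_tsv,
    run_recessive_filter,
)
from .ibd import calibrate_cutoff, sibpair_posteriors, write_posterior_tsv
from .prs import analyze_prs_groups, prs_raw
from .regions import (
    calls_from_posteriors,
    phenocopy_shared_positions,
    positions_to_regions,
    strict_shared_positions,
    write_bed,
)
from .simulate import (
    ExomeSimSpec,
    PlantedCandidate,
    PrsCohortSpec,
    SibshipDataset,
    SimParams,
    read_ped_map,
    simulate_exome_table,
    simulate_families,
    simulate_prs_cohorts,
    write_ped_map,
)

log = logging.getLogger("sibshare")


@dataclass
class Thresholds:
    """Every tunable cut-off of the pipeline, with its standard default."""

    reference_max: float = 0.10
    internal_max: float = 0.30
    causal_max: float = 0.02
    missense_af_max: float = 0.01
    polyphen_min: float = 0.7
    grantham_min: float = 75.0
    panel_missense_af_max: float = 0.02
    cadd_min: float = 20.0
    ibd_cutoff_default: float = 0.05
    min_fraction: float = 0.25
    ibd_error_rate: float = 0.01

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("grantham_min", "cadd_min"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must lie in [0, 1], got {v}")


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "sibshare_run"
    seed: int = 0
    phenocopy: bool = True
    thresholds: Thresholds = field(default_factory=Thresholds)
    # simulation blocks (None -> use file inputs)
    sibsim: SimParams | None = None
    exome: ExomeSimSpec | None = None
    prs: PrsCohortSpec | None = None
    # file inputs
    ped_path: str | None = None
    map_path: str | None = None
    annot_path: str | None = None
    prs_panel_path: str | None = None
    prs_dosage_paths: dict[str, str] | None = None
    gene_panel_path: str | None = None

    def __post_init__(self) -> None:
        if self.sibsim is not None and self.ped_path is not None:
            raise ConfigError("give either a sibsim block or PED/MAP paths, not both")
        if self.sibsim is None and (self.ped_path is None or self.map_path is None):
            raise ConfigError("no genotype source: need a sibsim block or PED/MAP paths")
        if self.exome is not None and self.annot_path is not None:
            raise ConfigError("give either an exome block or an annotation path, not both")
        if self.exome is not None and self.sibsim is None:
            raise ConfigError("an exome simulation block requires a sibsim block")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        kwargs: dict = {
            "outdir": raw.get("outdir", "sibshare_run"),
            "seed": seed,
            "phenocopy": bool(raw.get("phenocopy", True)),
            "thresholds": Thresholds(**raw.get("thresholds", {})),
        }
        if "sibsim" in raw:
            sib = dict(raw["sibsim"])
            sib.setdefault("seed", seed)
            if "marker_maf_range" in sib:
                sib["marker_maf_range"] = tuple(sib["marker_maf_range"])
            kwargs["sibsim"] = SimParams(**sib)
        if "exome" in raw:
            ex = dict(raw["exome"])
            ex.setdefault("seed", seed + 1)
            ex["planted"] = [PlantedCandidate(**p) for p in ex.get("planted", [])]
            if "frequency_spectrum" in ex:
                ex["frequency_spectrum"] = tuple(ex["frequency_spectrum"])
            kwargs["exome"] = ExomeSimSpec(**ex)
        if "prs" in raw:
            pr = dict(raw["prs"])
            pr.setdefault("seed", seed + 2)
            kwargs["prs"] = PrsCohortSpec(**pr)
        for key in (
            "ped_path",
            "map_path",
            "annot_path",
            "prs_panel_path",
            "gene_panel_path",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "prs_dosage_paths" in raw:
            kwargs["prs_dosage_paths"] = dict(raw["prs_dosage_paths"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _dataset_from_files(config: RunConfig) -> SibshipDataset:
    from .simulate import Sibship

    genotypes, marker_map = read_ped_map(config.ped_path, config.map_path)
    sib_ids = list(genotypes.index)
    sibship = Sibship(family_id="F1", sib_ids=sib_ids, proband=sib_ids[0])
    return SibshipDataset(
        sibship=sibship,
        marker_map=marker_map,
        genotypes=genotypes,
        truth_ibd=None,
        truth_parent_haplotypes=None,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all pipeline stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(thr),
        "stages": {},
        "outputs": [],
    }

    def _emit(name: str) -> Path:
        path = outdir / name
        manifest["outputs"].append(name)
        return path

    # --- genotypes ------------------------------------------------------
    if config.sibsim is not None:
        datasets = simulate_families(config.sibsim)
        for ds in datasets:
            write_ped_map(
                ds,
                _emit(f"{ds.sibship.family_id}.ped"),
                _emit(f"{ds.sibship.family_id}.map"),
            )
    else:
        datasets = [_dataset_from_files(config)]
    manifest["stages"]["genotypes"] = {
        "n_families": len(datasets),
        "n_markers": int(len(datasets[0].marker_map)),
    }
    log.info("genotypes ready: %d families", len(datasets))

    # --- IBD posteriors and global calibration --------------------------
    all_posteriors = []
    per_family_posteriors: dict[str, list] = {}
    for ds in datasets:
        fam_posts = []
        for a, b in ds.pairs:
            post = sibpair_posteriors(
                ds.genotypes.loc[a].to_numpy(),
                ds.genotypes.loc[b].to_numpy(),
                ds.marker_map,
                error_rate=thr.ibd_error_rate,
                pair=(a, b),
            )
            fam_posts.append(post)
            write_posterior_tsv(post, _emit(f"{ds.sibship.family_id}_{a}_{b}.ibd.tsv"))
        per_family_posteriors[ds.sibship.family_id] = fam_posts
        all_posteriors.extend(fam_posts)
    cutoff = calibrate_cutoff(
        all_posteriors, min_fraction=thr.min_fraction, default=thr.ibd_cutoff_default
    )
    manifest["stages"]["ibd"] = {
        "n_pairs": len(all_posteriors),
        "cutoff": cutoff.value,
        "largest_admissible": cutoff.largest_admissible,
        "default_admissible": cutoff.default_admissible,
    }
    log.info("IBD cutoff calibrated: %.4g", cutoff.value)

    # --- shared regions -------------------------------------------------
    region_sets: dict[str, dict] = {}
    region_stage: dict[str, dict] = {}
    for ds in datasets:
        fid = ds.sibship.family_id
        calls = calls_from_posteriors(per_family_posteriors[fid], cutoff.value)
        strict = positions_to_regions(
            strict_shared_positions(calls), ds.marker_map, family_id=fid, mode="strict"
        )
        write_bed(strict, _emit(f"{fid}.strict.bed"))
        entry = {"strict": strict, "phenocopy": {}}
        stage = {
            "strict_regions": len(strict.regions),
            "strict_coverage": strict.coverage_fraction(ds.marker_map),
        }
        if config.phenocopy and ds.sibship.n_sibs >= 3:
            pheno = phenocopy_shared_positions(
                calls, ds.sibship.sib_ids, ds.sibship.proband
            )
            for excluded, sel in pheno.items():
                rset = positions_to_regions(
                    sel,
                    ds.marker_map,
                    family_id=fid,
                    mode="phenocopy",
                    excluded_sib=excluded,
                )
                write_bed(rset, _emit(f"{fid}.phenocopy.{excluded}.bed"))
                entry["phenocopy"][excluded] = rset
            stage["phenocopy_sets"] = len(entry["phenocopy"])
        region_sets[fid] = entry
        region_stage[fid] = stage
    manifest["stages"]["regions"] = region_stage

    # --- exome filtering ------------------------------------------------
    gene_panel = (
        GenePanel.from_tsv(config.gene_panel_path)
        if config.gene_panel_path
        else default_gene_panel()
    )
    filter_stage: dict[str, dict] = {}
    if config.exome is not None or config.annot_path is not None:
        for i, ds in enumerate(datasets):
            fid = ds.sibship.family_id
            if config.exome is not None:
                spec = dataclasses.replace(config.exome, seed=config.exome.seed + i)
                exome = simulate_exome_table(ds, spec)
                exome.write(
                    _emit(f"{fid}.vcf"),
                    _emit(f"{fid}.annot.tsv"),
                    outdir / f"{fid}.truth.tsv",
                )
                variants = exome.variants
            else:
                variants = read_annotation_tsv(config.annot_path)
            report = run_recessive_filter(
                variants,
                region_sets[fid]["strict"],
                reference_max=thr.reference_max,
                internal_max=thr.internal_max,
                causal_max=thr.causal_max,
                missense_af_max=thr.missense_af_max,
                polyphen_min=thr.polyphen_min,
                grantham_min=thr.grantham_min,
            )
            report.second_hits.pairs.to_csv(
                _emit(f"{fid}.pairs.tsv"), sep="\t", index=False
            )
            report.second_hits.homozygous.to_csv(
                _emit(f"{fid}.homozygous.tsv"), sep="\t", index=False
            )
            pscan = panel_scan(
                variants,
                gene_panel,
                missense_af_max=thr.panel_missense_af_max,
                cadd_min=thr.cadd_min,
            )
            pscan.findings.to_csv(_emit(f"{fid}.panel.tsv"), sep="\t", index=False)
            filter_stage[fid] = {
                **report.stage_counts,
                "panel_findings": len(pscan.findings),
            }
            pheno_counts = {}
            for excluded, rset in region_sets[fid]["phenocopy"].items():
                prep = run_recessive_filter(
                    variants,
                    rset,
                    reference_max=thr.reference_max,
                    internal_max=thr.internal_max,
                    causal_max=thr.causal_max,
                    missense_af_max=thr.missense_af_max,
                    polyphen_min=thr.polyphen_min,
                    grantham_min=thr.grantham_min,
                    excluded_sib=excluded,
                )
                pheno_counts[excluded] = prep.stage_counts["prioritized"]
            if pheno_counts:
                filter_stage[fid]["phenocopy_prioritized"] = pheno_counts
        manifest["stages"]["filter"] = filter_stage

    # --- PRS ------------------------------------------------------------
    if config.prs is not None or config.prs_dosage_paths is not None:
        if config.prs is not None:
            cohorts = simulate_prs_cohorts(config.prs)
            panel = cohorts.panel
            groups = {
                "control": cohorts.controls,
                "population-case": cohorts.cases,
                "familial-case": cohorts.sibships,
                "proband": cohorts.probands,
            }
            panel.to_csv(_emit("prs_panel.tsv"), sep="\t", index=False)
            for name, df in groups.items():
                df.to_csv(_emit(f"prs_dosages_{name}.tsv"), sep="\t")
        else:
            from .prs import read_panel_tsv

            panel = read_panel_tsv(config.prs_panel_path)
            groups = {
                name: pd.read_csv(path, sep="\t", index_col=0)
                for name, path in config.prs_dosage_paths.items()
            }
            if "control" not in groups:
                raise ConfigError("PRS dosage paths must include a 'control' group")
        raw = {name: prs_raw(df, panel) for name, df in groups.items()}
        result = analyze_prs_groups(raw)
        result.summary_frame().to_csv(_emit("prs_summary.tsv"), sep="\t", index=False)
        manifest["stages"]["prs"] = {
            "or_per_sd": round(result.or_per_sd.odds_ratio, 3),
            "groups": {
                s.group: {"n": s.n, "mean": round(s.mean, 3), "or_for_mean": round(s.or_for_mean, 3)}
                for s in result.summaries
            },
            "welch_p": {
                f"{a}_vs_{b}": float(f"{w.p_value:.2g}")
                for (a, b), w in result.welch.items()
            },
        }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %s", manifest_path)
    return manifest
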