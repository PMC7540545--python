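"""Family-level "two haplotypes shared" regions.

Per-pair IBD2 calls (posterior P2 above the calibrated cut-off) are
combined into family-level marker selections — *strict* mode requires
every sib pair to share two alleles IBD at the marker; *phenocopy* mode
requires it only of the pairs within an all-but-one-sib subset that
contains the sequenced proband — and maximal runs of selected markers
are converted to base-pair intervals.  Each interval starts one base
pair after the nearest upstream marker at which sharing failed and ends
one base pair before the nearest downstream such marker; runs touching
a chromosome edge are bounded by the outermost marker positions.
Intervals are stored 1-based inclusive and written as standard 0-based
half-open BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class Ibd2CallMatrix:
    """Boolean IBD2 calls, pairs x markers, for one family."""

    pairs: list[tuple[str, str]]
    calls: np.ndarray  # (n_pairs, n_markers) bool

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape[0] != len(self.pairs):
            raise ValueError("calls row count must match number of pairs")


def calls_from_posteriors(posteriors, cutoff: float) -> Ibd2CallMatrix:
    """Threshold per-pair posteriors (strictly ``P2 > cutoff``) into calls."""
    return Ibd2CallMatrix(
        pairs=[p.pair for p in posteriors],
        calls=np.stack([p.p2 > cutoff for p in posteriors]),
    )


def strict_shared_positions(calls: Ibd2CallMatrix) -> np.ndarray:
    """Markers at which every sib pair is called IBD2."""
    if len(calls.pairs) == 0:
        raise ValueError("need at least one sib pair")
    return calls.calls.all(axis=0)


def phenocopy_shared_positions(
    calls: Ibd2CallMatrix, sibs: list[str], proband: str
) -> dict[str, np.ndarray]:
    """Per excluded-sib marker selections allowing one phenocopy.

    For each candidate excluded sib (never the proband, whose exome the
    downstream filter uses), a marker is selected iff all pairs within
    the remaining sibs are called IBD2.  Requires at least three sibs.
    """
    if len(sibs) < 3:
        raise ValueError("phenocopy mode needs at least three sibs")
    if proband not in sibs:
        raise ValueError(f"proband {proband!r} not among sibs")
    pair_index = {frozenset(p): i for i, p in enumerate(calls.pairs)}
    out: dict[str, np.ndarray] = {}
    for excluded in sibs:
        if excluded == proband:
            continue
        subset = [s for s in sibs if s != excluded]
        idx = []
        for a, b in combinations(subset, 2):
            key = frozenset((a, b))
            if key not in pair_index:
                raise ValueError(f"missing calls for pair {(a, b)}")
            idx.append(pair_index[key])
        out[excluded] = calls.calls[idx].all(axis=0)
    return out


@dataclass
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    excluded_sib: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SharedRegionSet:
    """Intervals over which the required sib subset shares two haplotypes."""

    family_id: str
    mode: str  # "strict" | "phenocopy"
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "phenocopy"):
            raise ValueError(f"mode must be 'strict' or 'phenocopy', got {self.mode!r}")

    def total_length(self) -> int:
        return sum(r.length for r in self.regions)

    def coverage_fraction(self, marker_map: pd.DataFrame) -> float:
        """Covered fraction of the genome spanned by the marker scaffold."""
        span = 0
        for _, g in marker_map.groupby("chrom", sort=False):
            span += int(g["pos_bp"].iloc[-1]) - int(g["pos_bp"].iloc[0]) + 1
        return self.total_length() / span if span else 0.0


def positions_to_regions(
    selected: np.ndarray,
    marker_map: pd.DataFrame,
    family_id: str = "F1",
    mode: str = "strict",
    excluded_sib: str | None = None,
) -> SharedRegionSet:
    """Convert a per-marker selection into base-pair regions.

    Each maximal run of selected markers becomes one region running from
    one base pair after the nearest upstream unselected marker to one
    base pair before the nearest downstream unselected marker; at
    chromosome edges the region is bounded by the first/last marker
    position of that chromosome.
    """
    selected = np.asarray(selected, dtype=bool)
    if len(selected) != len(marker_map):
        raise ValueError("selection vector must align with the marker map")
    regions: list[Region] = []
    chroms = marker_map["chrom"].to_numpy()
    pos = marker_map["pos_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sel = selected[idx]
        cpos = pos[idx]
        m = 0
        while m < len(idx):
            if not sel[m]:
                m += 1
                continue
            run_start = m
            while m + 1 < len(idx) and sel[m + 1]:
                m += 1
            start = int(cpos[run_start - 1]) + 1 if run_start > 0 else int(cpos[0])
            end = int(cpos[m + 1]) - 1 if m + 1 < len(idx) else int(cpos[-1])
            regions.append(Region(chrom, start, end, excluded_sib))
            m += 1
    return SharedRegionSet(family_id=family_id, mode=mode, regions=regions)


def write_bed(region_set: SharedRegionSet, path) -> None:
    """Write regions as 0-based half-open BED (3+1 columns).

    The name column holds the family id, suffixed with the excluded sib
    in phenocopy mode.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# sibshare shared regions: family={region_set.family_id} mode={region_set.mode}\n"
        )
        for r in region_set.regions:
            name = region_set.family_id
            if r.excluded_sib is not None:
                name += f"|excluded={r.excluded_sib}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_bed(path) -> SharedRegionSet:
    """Read a BED file written by :func:`write_bed` back into regions."""
    family_id = "unknown"
    mode = "strict"
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("family="):
                        family_id = tok.split("=", 1)[1]
                    elif tok.startswith("mode="):
                        mode = tok.split("=", 1)[1]
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            excluded = None
            if len(parts) > 3 and "|excluded=" in parts[3]:
                excluded = parts[3].split("|excluded=", 1)[1]
            regions.append(Region(chrom, start0 + 1, end, excluded))
    return SharedRegionSet(family_id=family_id, mode=mode, regions=regions)
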