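"""Multipoint sib-pair IBD estimation.

For each pair of full siblings, the number of alleles shared identical by
descent (IBD) at a locus is 0, 1 or 2.  Along a chromosome this number
follows a Markov chain driven by recombination: the paternal-match and
maternal-match indicators each persist between adjacent loci with
probability ``psi = theta**2 + (1 - theta)**2``, where ``theta`` is the
recombination fraction.  This module runs a forward-backward pass over
that chain, with genotype-pair emission probabilities computed under
Hardy-Weinberg equilibrium, to obtain per-marker posterior probabilities
``(P0, P1, P2)`` for every sib pair.  It also provides the cut-off
calibration used to turn posteriors into IBD2 calls (a threshold chosen
so that every pair selects at least a given fraction of markers) and the
closed-form expected genome fraction over which k sibs all share two
haplotypes, ``(1/4)**(k-1)``.

Genotypes are minor/counted-allele dosages in ``{0, 1, 2}`` with ``-1``
for missing.  Marker maps are pandas DataFrames with columns ``chrom``,
``pos_bp``, ``pos_cM`` and ``freq`` (frequency of the counted allele),
sorted by chromosome and strictly increasing position within each
chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Stationary distribution of the sib-pair IBD chain (and the prior at
#: each chromosome start): IBD 0/1/2 with probability 1/4, 1/2, 1/4.
IBD_PRIOR = np.array([0.25, 0.5, 0.25])

MAP_COLUMNS = ("chrom", "pos_bp", "pos_cM", "freq")


class MarkerMapError(ValueError):
    """Raised when a marker map violates its ordering/frequency contract."""


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check the marker-map contract and return the map unchanged.

    Requires columns ``chrom``, ``pos_bp``, ``pos_cM``, ``freq``;
    positions strictly increasing within each chromosome (in order of
    appearance); frequencies strictly inside (0, 1).
    """
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise MarkerMapError(f"marker map missing columns: {missing}")
    for _, sub in marker_map.groupby("chrom", sort=False):
        for col in ("pos_bp", "pos_cM"):
            v = sub[col].to_numpy(dtype=float)
            if np.any(np.diff(v) <= 0):
                raise MarkerMapError(
                    f"{col} not strictly increasing within a chromosome"
                )
    f = marker_map["freq"].to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0) or np.any(f >= 1):
        raise MarkerMapError("marker frequencies must lie strictly in (0, 1)")
    return marker_map


def haldane_theta(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from map distance under the Haldane model.

    ``theta = (1 - exp(-2 d / 100)) / 2`` for ``d`` in centimorgans; an
    infinite distance gives the unlinked value 0.5.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cM) else theta


def transition_matrix(theta: float) -> np.ndarray:
    """3x3 transition matrix of the sib-pair IBD chain between two loci.

    The paternal and maternal allele-match indicators evolve
    independently, each persisting with probability
    ``psi = theta**2 + (1 - theta)**2``.  IBD state = number of matching
    indicators, so the IBD transition matrix is the aggregation of the
    two-indicator product chain.  Rows sum to 1; the chain is reversible
    with stationary distribution (1/4, 1/2, 1/4).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    psi = theta**2 + (1.0 - theta) ** 2
    q = 1.0 - psi
    return np.array(
        [
            [psi**2, 2 * psi * q, q**2],
            [psi * q, psi**2 + q**2, psi * q],
            [q**2, 2 * psi * q, psi**2],
        ]
    )


def _hwe_probs(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for dosages (0, 1, 2)."""
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def emission_probs(
    g1: int, g2: int, p: float, error_rate: float = 0.0
) -> np.ndarray:
    """Likelihood triple ``(L0, L1, L2)`` of a genotype pair given IBD state.

    Under HWE with counted-allele frequency ``p``:

    * IBD 0: the genotypes are independent, ``L0 = HWE(g1) * HWE(g2)``.
    * IBD 2: the genotypes are a single draw, ``L2 = HWE(g1) * [g1 == g2]``.
    * IBD 1: one allele is shared; summing over the shared allele ``s``,
      ``L1 = sum_s P(s) * P(g1 | s) * P(g2 | s)`` where ``P(g | s)`` is the
      probability of genotype ``g`` given one allele fixed to ``s`` and the
      other drawn from the population.

    A missing genotype contributes a factor of 1 to every state.  With
    ``error_rate > 0`` each state's likelihood is mixed with the uniform
    average over the nine observable genotype pairs,
    ``L <- (1 - e) * L + e / 9``, which absorbs occasional miscalled
    genotypes without letting a single marker force an IBD switch.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must lie in (0, 1), got {p}")
    if g1 == MISSING or g2 == MISSING:
        return np.ones(3)
    hwe = _hwe_probs(p)
    q = 1.0 - p
    # P(g | shared allele): rows = shared allele (non-counted, counted)
    cond = np.array([[q, p, 0.0], [0.0, q, p]])
    l0 = hwe[g1] * hwe[g2]
    l1 = q * cond[0, g1] * cond[0, g2] + p * cond[1, g1] * cond[1, g2]
    l2 = hwe[g1] * (1.0 if g1 == g2 else 0.0)
    lik = np.array([l0, l1, l2])
    if error_rate > 0.0:
        lik = (1.0 - error_rate) * lik + error_rate / 9.0
    return lik


def _emission_table(p: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-marker emission likelihoods for all genotype pairs.

    Returns an array of shape ``(n_markers, 4, 4, 3)`` indexed by
    ``(marker, g1 + 1, g2 + 1, state)`` so that missing (-1) maps to
    index 0.
    """
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (M, 3)
    cond0 = np.stack([q, p, np.zeros_like(p)], axis=-1)  # shared = non-counted
    cond1 = np.stack([np.zeros_like(p), q, p], axis=-1)  # shared = counted
    M = p.shape[0]
    table = np.ones((M, 4, 4, 3))
    l0 = hwe[:, :, None] * hwe[:, None, :]
    l1 = (
        q[:, None, None] * cond0[:, :, None] * cond0[:, None, :]
        + p[:, None, None] * cond1[:, :, None] * cond1[:, None, :]
    )
    l2 = hwe[:, :, None] * np.eye(3)[None, :, :]
    lik = np.stack([l0, l1, l2], axis=-1)  # (M, 3, 3, 3)
    if error_rate > 0.0:
        lik = (1.0 - error_rate) * lik + error_rate / 9.0
    table[:, 1:, 1:, :] = lik
    return table


@dataclass
class IbdPosterior:
    """Per-marker posterior IBD-state probabilities for one sib pair.

    ``probs`` has shape ``(n_markers, 3)`` with columns P0, P1, P2, each
    row summing to 1.
    """

    pair: tuple[str, str]
    probs: np.ndarray
    marker_map: pd.DataFrame = field(repr=False)

    @property
    def p2(self) -> np.ndarray:
        return self.probs[:, 2]

    def to_frame(self) -> pd.DataFrame:
        out = self.marker_map[["chrom", "pos_bp"]].copy()
        out[["P0", "P1", "P2"]] = self.probs
        return out


def sibpair_posteriors(
    genotypes1: np.ndarray,
    genotypes2: np.ndarray,
    marker_map: pd.DataFrame,
    *,
    error_rate: float = 0.01,
    pair: tuple[str, str] = ("sib1", "sib2"),
) -> IbdPosterior:
    """Forward-backward posteriors of IBD state for one sib pair.

    The chain starts from the prior (1/4, 1/2, 1/4) at each chromosome
    and resets at chromosome boundaries; transitions between adjacent
    markers use the Haldane recombination fraction of their cM distance.
    Posteriors are normalised marker by marker.
    """
    g1 = np.asarray(genotypes1)
    g2 = np.asarray(genotypes2)
    if g1.shape != g2.shape or g1.shape[0] != len(marker_map):
        raise ValueError("genotype vectors must match the marker map length")
    validate_marker_map(marker_map)

    probs = np.empty((len(marker_map), 3))
    freqs = marker_map["freq"].to_numpy(dtype=float)
    cm = marker_map["pos_cM"].to_numpy(dtype=float)
    chroms = marker_map["chrom"].to_numpy()
    emit_all = _emission_table(freqs, error_rate)
    emit = emit_all[np.arange(len(marker_map)), g1 + 1, g2 + 1, :]

    start = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        stop = start + len(idx)
        block = slice(start, stop)
        probs[block] = _forward_backward(emit[block], cm[idx])
        start = stop
    return IbdPosterior(pair=tuple(pair), probs=probs, marker_map=marker_map)


def _forward_backward(emit: np.ndarray, cm: np.ndarray) -> np.ndarray:
    """Scaled forward-backward over one chromosome. ``emit``: (M, 3)."""
    M = emit.shape[0]
    thetas = haldane_theta(np.diff(cm))
    trans = [transition_matrix(float(t)) for t in np.atleast_1d(thetas)]

    alpha = np.empty((M, 3))
    scale = np.empty(M)
    a = IBD_PRIOR * emit[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for m in range(1, M):
        a = (alpha[m - 1] @ trans[m - 1]) * emit[m]
        scale[m] = a.sum()
        alpha[m] = a / scale[m]

    beta = np.empty((M, 3))
    beta[-1] = 1.0
    for m in range(M - 2, -1, -1):
        beta[m] = (trans[m] @ (emit[m + 1] * beta[m + 1])) / scale[m + 1]

    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


@dataclass
class IbdCutoff:
    """Result of calibrating the posterior-P2 threshold.

    ``value`` is the threshold to use downstream: the configured default
    when it already satisfies the per-pair minimum-fraction rule,
    otherwise the largest admissible threshold.  ``fractions`` records
    the per-pair fraction of markers with ``P2 > value``.
    """

    value: float
    largest_admissible: float
    default: float
    default_admissible: bool
    min_fraction: float
    fractions: dict[tuple[str, str], float]


class CalibrationError(RuntimeError):
    """No threshold in [0, 1) satisfies the per-pair selection rule."""


def calibrate_cutoff(
    posteriors: list[IbdPosterior],
    min_fraction: float = 0.25,
    default: float = 0.05,
) -> IbdCutoff:
    """Calibrate the IBD2 call threshold over all sib pairs.

    Finds the largest threshold ``c`` such that for *every* pair the
    fraction of markers with ``P2 > c`` is at least ``min_fraction``
    (strict inequality, so the returned value sits just below the
    limiting order statistic).  If the configured default already
    satisfies the rule, the default is adopted as the working value and
    the largest admissible threshold is reported alongside it.
    """
    if not posteriors:
        raise ValueError("need at least one sib pair")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")

    if min_fraction == 0.0:
        sup = 1.0
    else:
        sup = math.inf
        for post in posteriors:
            p2 = np.sort(post.p2)[::-1]
            k = math.ceil(min_fraction * len(p2))
            sup = min(sup, p2[k - 1])
        if sup <= 0.0:
            raise CalibrationError(
                "no threshold in [0, 1) selects the required marker "
                "fraction for every pair (degenerate posteriors)"
            )
    largest = float(np.nextafter(sup, -np.inf))

    def _fractions(c: float) -> dict[tuple[str, str], float]:
        return {post.pair: float(np.mean(post.p2 > c)) for post in posteriors}

    default_ok = all(f >= min_fraction for f in _fractions(default).values())
    value = default if default_ok else largest
    return IbdCutoff(
        value=value,
        largest_admissible=largest,
        default=default,
        default_admissible=default_ok,
        min_fraction=min_fraction,
        fractions=_fractions(value),
    )


def expected_ibd2_fraction(k: int) -> float:
    """Expected genome fraction where k full sibs all share two haplotypes.

    Each additional sib must receive the same paternal and the same
    maternal haplotype as the first at the locus, a factor of 1/4, so
    the fraction is ``(1/4)**(k-1)``: 25% for a sib pair, 6.25% for
    three sibs, 1.5625% for four.
    """
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValueError(f"need at least two sibs, got {k!r}")
    return 0.25 ** (k - 1)


def write_posterior_tsv(posterior: IbdPosterior, path) -> None:
    """Write one pair's posteriors as a TSV (chrom, pos, P0, P1, P2)."""
    posterior.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
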