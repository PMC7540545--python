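"""Polygenic risk score computation and group comparison.

The score of individual j over a panel of independent risk SNPs is

    PRS_j = sum_i n_ij * ln(OR_i)

where ``n_ij`` is j's risk-allele dosage at SNP i (0, 1 or 2, or a
fractional imputed dosage) and ``OR_i`` the per-allele odds ratio.
Scores are normalized against the population controls so that one unit
corresponds to one control standard deviation; the odds ratio per SD is
the exponentiated slope of a univariate logistic regression of
case/control status on the normalized score, and a group's
mean-equivalent odds ratio is ``or_per_sd ** mean`` — the risk implied
by sitting at that group's average score.  Group means are compared
with Welch's two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class MissingDosageError(ValueError):
    """A profile lacks dosages for panel SNPs under the strict policy."""


class SeparationError(RuntimeError):
    """Logistic regression is degenerate (complete separation)."""


def prs_raw(
    dosages: pd.DataFrame | pd.Series,
    panel: pd.DataFrame,
    missing: str = "strict",
) -> pd.Series:
    """Raw polygenic risk scores, one per individual.

    ``dosages`` holds risk-allele counts with SNP ids as columns (a
    Series is treated as a single individual); ``panel`` needs columns
    ``snp`` and ``OR`` (and ``freq`` when ``missing="impute"``, which
    fills an absent SNP with its expected dosage ``2 * freq``).  The
    default policy fails listing the missing SNPs.
    """
    if (panel["OR"] <= 0).any():
        raise ValueError("panel odds ratios must be positive")
    single = isinstance(dosages, pd.Series)
    mat = dosages.to_frame().T if single else dosages
    snps = panel["snp"].tolist()
    absent = [s for s in snps if s not in mat.columns]
    if absent:
        if missing == "strict":
            raise MissingDosageError(
                f"dosages missing for {len(absent)} panel SNPs: {absent[:5]}..."
            )
        if missing != "impute":
            raise ValueError(f"unknown missing policy {missing!r}")
        if "freq" not in panel.columns:
            raise ValueError("imputation needs a 'freq' column in the panel")
        fill = dict(zip(panel["snp"], 2.0 * panel["freq"]))
        mat = mat.copy()
        for s in absent:
            mat[s] = fill[s]
    vals = mat[snps].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 2):
        raise ValueError("dosages must lie in [0, 2]")
    beta = np.log(panel["OR"].to_numpy(dtype=float))
    scores = vals @ beta
    out = pd.Series(scores, index=mat.index, name="prs_raw")
    return out.iloc[0] if single else out


def normalize_scores(
    scores: pd.Series | np.ndarray, control_scores: pd.Series | np.ndarray
) -> pd.Series | np.ndarray:
    """Standardize scores by the control mean and SD (one unit = one SD).

    The control SD uses the n-1 (sample) convention.
    """
    ctrl = np.asarray(control_scores, dtype=float)
    if len(ctrl) < 2:
        raise ValueError("need at least two control scores")
    mu = ctrl.mean()
    sd = ctrl.std(ddof=1)
    if sd == 0.0:
        raise ValueError("control scores have zero standard deviation")
    if isinstance(scores, pd.Series):
        return (scores - mu) / sd
    return (np.asarray(scores, dtype=float) - mu) / sd


@dataclass
class LogisticOrResult:
    """Odds ratio per SD with its Wald 95% confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    slope: float
    slope_se: float
    n_cases: int
    n_controls: int


def or_per_sd(
    normalized_scores: np.ndarray,
    is_case: np.ndarray,
    alpha: float = 0.05,
) -> LogisticOrResult:
    """Odds ratio per unit SD of the PRS via univariate logistic regression.

    Fits ``logit P(case) = a + b * score`` by Newton-type maximum
    likelihood; returns ``exp(b)`` with a Wald ``1 - alpha`` interval.
    Complete separation is reported, never silently estimated around.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(normalized_scores, dtype=float)
    y = np.asarray(is_case, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("need both cases and controls")
    # a score value above every control and below every case (or vice
    # versa) separates the labels perfectly
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        raise SeparationError("case and control scores are completely separated")
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
    except PerfectSeparationError as exc:  # pragma: no cover - guarded above
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic regression did not converge")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return LogisticOrResult(
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(slope - z * se)),
        ci_high=float(np.exp(slope + z * se)),
        slope=slope,
        slope_se=se,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def or_for_mean(mean_prs: float, or_per_sd_value: float) -> float:
    """Odds ratio implied by a group's mean normalized PRS.

    With odds multiplying by ``s`` per SD, a group sitting ``m`` SDs
    above the control mean has odds ratio ``s ** m = exp(m * ln s)``.
    """
    if or_per_sd_value <= 0:
        raise ValueError("odds ratio per SD must be positive")
    return float(np.exp(mean_prs * np.log(or_per_sd_value)))


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_test(group_a: np.ndarray, group_b: np.ndarray) -> WelchResult:
    """Welch two-sample t-test (unequal variances), two-sided.

    ``t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


@dataclass
class PrsGroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    or_for_mean: float


@dataclass
class PrsResult:
    """Full PRS analysis over labelled groups of raw scores."""

    summaries: list[PrsGroupSummary]
    or_per_sd: LogisticOrResult
    welch: dict[tuple[str, str], WelchResult]
    normalized: pd.Series  # all individuals, group label in .attrs["groups"]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": s.group,
                    "n": s.n,
                    "mean": round(s.mean, 2),
                    "sd": round(s.sd, 2),
                    "or_for_mean": round(s.or_for_mean, 2),
                }
                for s in self.summaries
            ]
        )


def analyze_prs_groups(
    raw_scores: dict[str, pd.Series],
    control_group: str = "control",
    case_group: str = "population-case",
    compare: list[tuple[str, str]] | None = None,
) -> PrsResult:
    """Normalize, estimate OR/SD, summarise groups and run Welch tests.

    ``raw_scores`` maps group label to per-individual raw scores.  The
    OR per SD comes from logistic regression of ``case_group`` vs
    ``control_group``; every group gets a mean-equivalent odds ratio;
    ``compare`` lists group pairs for Welch tests (default: every other
    group against the controls).
    """
    if control_group not in raw_scores:
        raise ValueError(f"missing control group {control_group!r}")
    ctrl_raw = raw_scores[control_group]
    norm = {g: normalize_scores(s, ctrl_raw) for g, s in raw_scores.items()}

    scores_cc = np.concatenate([norm[control_group], norm[case_group]])
    labels_cc = np.concatenate(
        [np.zeros(len(norm[control_group])), np.ones(len(norm[case_group]))]
    )
    orsd = or_per_sd(scores_cc, labels_cc)

    summaries = [
        PrsGroupSummary(
            group=g,
            n=len(s),
            mean=float(np.mean(s)),
            sd=float(np.std(s, ddof=1)),
            or_for_mean=or_for_mean(float(np.mean(s)), orsd.odds_ratio),
        )
        for g, s in norm.items()
    ]
    if compare is None:
        compare = [(g, control_group) for g in raw_scores if g != control_group]
    welch = {
        (a, b): welch_test(np.asarray(norm[a]), np.asarray(norm[b]))
        for a, b in compare
    }
    all_norm = pd.concat(norm.values())
    all_norm.attrs["groups"] = {g: len(s) for g, s in norm.items()}
    return PrsResult(
        summaries=summaries, or_per_sd=orsd, welch=welch, normalized=all_norm
    )


def read_panel_tsv(path) -> pd.DataFrame:
    """Read a PRS panel TSV (columns: snp, risk_allele, OR[, freq])."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "risk_allele", "OR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel TSV missing columns: {sorted(missing)}")
    if df["snp"].duplicated().any():
        raise ValueError("panel SNP identifiers must be unique")
    return df
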