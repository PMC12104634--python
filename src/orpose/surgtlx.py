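"""Modified SURG-TLX instrument: aggregation and rank statistics.

The Surgery Task Load Index scores six workload domains (mental, physical
and temporal demand, task complexity, situational stress, distractions) on
0-20 scales; this instrument adds a seventh, job satisfaction, on the same
scale. Every domain is scored per surgery type (open, minimally invasive,
robotic-assisted) and per clinical phase, giving up to 7 x 3 x 3 = 63 cells
per respondent.

Analysis follows a complete-case design: only respondents with all 63
cells present enter the quantitative analysis; no imputation. Scores are
compared across surgery types on phase-summed values and across phases on
type-summed values with the Friedman test (tie-corrected chi-square),
Nemenyi post-hoc pairwise comparisons (run only when the omnibus test is
significant at 0.05), and Kendall's W as the effect size. No multiple-
testing correction is applied across domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import ORIGINAL_DOMAINS, PHASES, SURGERY_TYPES, SURGTLX_DOMAINS

N_CELLS = len(SURGTLX_DOMAINS) * len(SURGERY_TYPES) * len(PHASES)


def complete_cases(responses: pd.DataFrame) -> pd.DataFrame:
    """Retain respondents with all 63 cells present; no imputation."""
    present = responses.dropna(subset=["score"])
    counts = present.groupby("respondent_id")["score"].count()
    keep = counts[counts == N_CELLS].index
    return responses[responses["respondent_id"].isin(keep)].copy()


def _require_complete(responses: pd.DataFrame) -> None:
    counts = responses.dropna(subset=["score"]).groupby("respondent_id")["score"].count()
    if (counts != N_CELLS).any():
        bad = counts[counts != N_CELLS].index.tolist()
        raise ValueError(
            f"responses contain incomplete respondents {bad}; run complete_cases first"
        )


def sum_over_phases(responses: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Per-respondent phase-summed score per surgery type (0-60 scale)."""
    if domain not in SURGTLX_DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    _require_complete(responses)
    sub = responses[responses["domain"] == domain]
    table = sub.pivot_table(
        index="respondent_id", columns="surgery_type", values="score", aggfunc="sum"
    )
    return table[list(SURGERY_TYPES)]


def sum_over_types(responses: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Per-respondent type-summed score per phase (0-60 scale)."""
    if domain not in SURGTLX_DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    _require_complete(responses)
    sub = responses[responses["domain"] == domain]
    table = sub.pivot_table(
        index="respondent_id", columns="phase", values="score", aggfunc="sum"
    )
    return table[list(PHASES)]


def mean_workload(responses: pd.DataFrame) -> pd.Series:
    """Overall workload score per surgery type.

    Per respondent and surgery type: phase-summed scores averaged over the
    six original workload domains (job satisfaction excluded), then
    averaged over respondents. All cells equal to c gives 3c.
    """
    _require_complete(responses)
    sub = responses[responses["domain"].isin(ORIGINAL_DOMAINS)]
    per_domain = sub.pivot_table(
        index=["respondent_id", "domain"],
        columns="surgery_type",
        values="score",
        aggfunc="sum",
    )
    per_respondent = per_domain.groupby("respondent_id").mean()
    return per_respondent.mean()[list(SURGERY_TYPES)]


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """Friedman omnibus result with optional Nemenyi post-hoc matrix.

    ``statistic`` carries the tie-corrected chi-square;
    ``statistic_uncorrected`` the classical formula (they coincide without
    ties). ``effect_size`` is Kendall's W = chi2 / (n (k - 1)).
    """

    statistic: float
    p_value: float
    effect_size: float
    n: int
    k: int
    statistic_uncorrected: float
    p_value_uncorrected: float
    condition_means: pd.Series
    condition_sds: pd.Series
    posthoc: Optional[pd.DataFrame] = None


def _as_matrix(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-dimensional (respondents x conditions)")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 respondents")
    if k < 3:
        raise ValueError("need at least 3 related conditions")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; filter complete cases first")
    return x


def friedman(matrix) -> tuple[float, float]:
    """Friedman chi-square for n respondents x k related conditions.

    Rows are ranked with average ranks for ties; the chi-square uses the
    standard tie correction (reducing to
    ``12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)`` without ties) and is referred
    to the upper tail of chi-square with k-1 degrees of freedom. Returns
    ``(statistic, p_value)``.
    """
    stat, _, p, _ = _friedman_full(_as_matrix(matrix))
    return stat, p


def _friedman_full(x: np.ndarray) -> tuple[float, float, float, float]:
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    # Conover's tie correction via the rank sum of squares
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    denom = a - c
    if denom <= 0:  # every row fully tied: no information
        corrected = 0.0
    else:
        numer = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
        corrected = (k - 1) * numer / denom
    p_corr = float(stats.chi2.sf(corrected, k - 1)) if corrected > 0 else 1.0
    p_unc = float(stats.chi2.sf(uncorrected, k - 1)) if uncorrected > 0 else 1.0
    return corrected, uncorrected, p_corr, p_unc


def nemenyi(matrix, labels=None) -> pd.DataFrame:
    """Nemenyi pairwise p-values after a Friedman design.

    Mean-rank differences are referred to the studentized range
    distribution: q = |Rbar_i - Rbar_j| / sqrt(k (k+1) / (12 n)). The
    returned matrix is symmetric with a unit diagonal.
    """
    x = _as_matrix(matrix)
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    q = np.abs(mean_ranks[:, None] - mean_ranks[None, :]) / se
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.clip(np.where(np.eye(k, dtype=bool), 1.0, p), 0.0, 1.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry against numerical noise
    np.fill_diagonal(p, 1.0)
    if labels is None and isinstance(matrix, pd.DataFrame):
        labels = list(matrix.columns)
    if labels is None:
        labels = list(range(k))
    return pd.DataFrame(p, index=labels, columns=labels)


def effect_size(matrix, method: Literal["kendall_w", "anova"] = "kendall_w") -> float:
    """Effect size for a Friedman design.

    ``kendall_w`` (default): Kendall's coefficient of concordance
    W = chi2_F / (n (k - 1)), in [0, 1]; 0 for identical columns, 1 for
    perfect agreement on a strict ordering. ``anova``: partial eta squared
    from the repeated-measures sum-of-squares decomposition of the raw
    scores, SS_cond / (SS_cond + SS_error).
    """
    x = _as_matrix(matrix)
    n, k = x.shape
    if method == "kendall_w":
        stat, _, _, _ = _friedman_full(x)
        return float(stat / (n * (k - 1)))
    if method == "anova":
        grand = x.mean()
        ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
        ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
        ss_total = float(((x - grand) ** 2).sum())
        ss_error = ss_total - ss_cond - ss_subj
        if ss_cond + ss_error <= 0:
            return 0.0
        return float(ss_cond / (ss_cond + ss_error))
    raise ValueError(f"unknown method {method!r}")


def friedman_test(matrix, alpha: float = 0.05) -> TestResult:
    """Full omnibus + conditional post-hoc analysis of one n x k table."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.columns)
        x = _as_matrix(matrix)
    else:
        x = _as_matrix(matrix)
        labels = list(range(x.shape[1]))
    n, k = x.shape
    corrected, uncorrected, p_corr, p_unc = _friedman_full(x)
    result = TestResult(
        statistic=corrected,
        p_value=p_corr,
        effect_size=float(corrected / (n * (k - 1))),
        n=n,
        k=k,
        statistic_uncorrected=uncorrected,
        p_value_uncorrected=p_unc,
        condition_means=pd.Series(x.mean(axis=0), index=labels),
        condition_sds=pd.Series(x.std(axis=0, ddof=1), index=labels),
    )
    if result.p_value < alpha:
        result.posthoc = nemenyi(x, labels=labels)
    return result


def analyze(responses: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full questionnaire analysis on a response table.

    Applies complete-case filtering, then per domain tests scores across
    surgery types (phase-summed) and across phases (type-summed). Post-hoc
    Nemenyi matrices are attached only when the omnibus Friedman test is
    significant at ``alpha``.
    """
    if responses.empty:
        raise ValueError("no responses to analyze")
    complete = complete_cases(responses)
    if complete.empty:
        raise ValueError("no complete responses to analyze")
    by_type: dict[str, TestResult] = {}
    by_phase: dict[str, TestResult] = {}
    for domain in SURGTLX_DOMAINS:
        by_type[domain] = friedman_test(sum_over_phases(complete, domain), alpha)
        by_phase[domain] = friedman_test(sum_over_types(complete, domain), alpha)
    return {
        "n_respondents": complete["respondent_id"].nunique(),
        "n_excluded": responses["respondent_id"].nunique()
        - complete["respondent_id"].nunique(),
        "mean_workload": mean_workload(complete),
        "by_type": by_type,
        "by_phase": by_phase,
    }


def results_table(results: dict, axis: Literal["by_type", "by_phase"] = "by_type") -> pd.DataFrame:
    """Flatten analysis results into a descriptive table (one row per
    domain x condition, with the omnibus p and effect size repeated)."""
    rows = []
    for domain, res in results[axis].items():
        for cond in res.condition_means.index:
            rows.append(
                {
                    "domain": domain,
                    "condition": cond,
                    "mean": res.condition_means[cond],
                    "sd": res.condition_sds[cond],
                    "friedman_chi2": res.statistic,
                    "p_value": res.p_value,
                    "effect_size_w": res.effect_size,
                    "significant": res.p_value < 0.05,
                }
            )
    return pd.DataFrame(rows)


def plot_scores(responses: pd.DataFrame, domain: str, ax=None):
    """Boxplot of phase-summed scores per surgery type for one domain."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    table = sum_over_phases(complete_cases(responses), domain)
    ax.boxplot([table[c].to_numpy() for c in table.columns], tick_labels=list(table.columns))
    ax.set_ylabel(f"{domain} (phase-summed, 0-60)")
    ax.set_xlabel("Surgery type")
    return ax
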