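"""Participant- and group-level gait statistics.

Variability is summarized by the coefficient of variation (sample SD over
mean); stride length and MTC are normalized by participant height, total GRF
by body mass. Groups are compared with unpaired two-sample t-tests (pooled
variance by default, Welch optional) and Cohen's d; estimate-vs-reference
agreement is reported as Pearson r, RMSE and Bland-Altman bias with
+/- 1.96 sigma limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import UsageError


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    group: str
    mean_stride_length: float  # m
    cv_stride_length: float
    mean_mtc: float  # m
    cv_mtc: float
    norm_stride_length: float  # stride / height
    norm_mtc: float  # mtc / height


@dataclass(frozen=True)
class GroupComparison:
    t_stat: float
    df: float
    p_value: float
    cohens_d: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass(frozen=True)
class AgreementReport:
    r: float
    rmse: float
    bias: float
    loa_low: float
    loa_high: float


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError("CV needs at least two values")
    mean = v.mean()
    if abs(mean) < 1e-12 * max(1.0, np.abs(v).max()):
        raise UsageError("CV undefined for (near-)zero mean")
    return float(v.std(ddof=1) / mean)


def normalize_by_height(value: float, height: float) -> float:
    if height <= 0:
        raise UsageError("height must be positive")
    return value / height


def unpaired_t_test(group_a, group_b, welch: bool = False) -> GroupComparison:
    """Two-sample t-test with pooled-SD Cohen's d.

    The default is the Student pooled-variance test; ``welch=True`` switches
    to the Welch unequal-variance form (Cohen's d stays pooled).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UsageError("each group needs n >= 2")
    na, nb = a.size, b.size
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    if pooled_var == 0:
        raise UsageError("zero pooled variance; t-test degenerate")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", na + nb - 2))
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    return GroupComparison(
        t_stat=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        cohens_d=d,
        mean_a=float(a.mean()),
        sd_a=float(np.sqrt(var_a)),
        mean_b=float(b.mean()),
        sd_b=float(np.sqrt(var_b)),
    )


def agreement(estimates, references) -> AgreementReport:
    """Pearson r, RMSE and Bland-Altman statistics of estimate minus reference."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise UsageError("agreement needs equal-length sequences, n >= 3")
    diff = est - ref
    bias = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    sd = float(diff.std(ddof=1))
    if est.std() == 0 or ref.std() == 0:
        raise UsageError("correlation undefined for zero-variance input")
    r = float(sps.pearsonr(est, ref).statistic)
    return AgreementReport(
        r=r,
        rmse=rmse,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
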