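"""Inter-visit repeatability and agreement statistics.

Given paired measurements (two visits per subject) the module computes the
standard repeatability panel: a paired t-test for a systematic inter-visit
shift, the intraclass correlation coefficient ICC(2,1) (two-way random
effects, absolute agreement, single measurement) with its F-based 95% CI,
Bland–Altman limits of agreement, and Pearson's r (with Fisher-z CI) for
comparing metric variants against a reference variant.

ICC bands follow the conventional cutpoints: < 0.50 poor, [0.50, 0.75)
moderate, [0.75, 0.90] good, > 0.90 excellent.

Degenerate inputs (identical visits, zero-variance differences) take
explicit flagged conventions (ICC = 1, p = 1) instead of propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "RepeatabilityReport",
    "paired_t_test",
    "icc_two_way",
    "icc_band",
    "bland_altman",
    "pearson_with_ci",
    "build_report",
]


@dataclass
class PairedMeasurements:
    """Two-visit measurements of one metric across subjects."""

    subject_ids: Sequence
    visit1: np.ndarray
    visit2: np.ndarray
    metric_label: str = ""

    def __post_init__(self) -> None:
        self.visit1 = np.asarray(self.visit1, dtype=np.float64)
        self.visit2 = np.asarray(self.visit2, dtype=np.float64)
        if not (len(self.subject_ids) == len(self.visit1) == len(self.visit2)):
            raise ValueError("subject_ids, visit1, visit2 must have equal length")
        if len(self.visit1) < 3:
            raise ValueError("need at least 3 paired subjects")
        if np.isnan(self.visit1).any() or np.isnan(self.visit2).any():
            raise ValueError("missing values must be dropped upstream")

    @property
    def n(self) -> int:
        return len(self.visit1)

    @property
    def data(self) -> np.ndarray:
        """n x 2 matrix (subjects x visits)."""
        return np.column_stack([self.visit1, self.visit2])


def paired_t_test(pm: PairedMeasurements) -> tuple[float, int, float, bool]:
    """Classical dependent t-test on visit differences.

    Returns ``(t, df, p, degenerate)``. Zero-variance differences are a
    flagged degenerate branch: p = 1 when the mean difference is also zero
    (identical visits), and a degenerate flag with p = 1, t = inf-guarded 0
    otherwise (a systematic shift with no noise, untestable by t).
    """
    d = pm.visit1 - pm.visit2
    if np.allclose(d.std(ddof=1), 0.0):
        return 0.0, pm.n - 1, 1.0, True
    t, p = sps.ttest_rel(pm.visit1, pm.visit2)
    return float(t), pm.n - 1, float(p), False


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x visits) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)


def icc_band(icc: float) -> str:
    """Repeatability band at the 0.50 / 0.75 / 0.90 cutpoints.

    Half-open convention: [0.50, 0.75) moderate, [0.75, 0.90] good;
    excellent requires strictly > 0.90.
    """
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_two_way(
    pm: PairedMeasurements, alpha: float = 0.05, form: str = "ICC2"
) -> tuple[float, tuple[float, float], str, bool]:
    """ICC with F-based confidence interval from the two-way ANOVA.

    ``form="ICC2"`` is ICC(2,1): two-way random effects, absolute
    agreement, single measurement — visits are treated as random and a
    systematic inter-visit shift counts against agreement. ``form="ICC3"``
    (two-way mixed, consistency) is offered as an alternative.

    Returns ``(icc, (lo, hi), band, degenerate)``. A fully degenerate table
    (all values identical) takes the flagged convention ICC = 1, CI (1, 1).
    """
    data = pm.data
    n, k = data.shape
    if np.allclose(data, data.flat[0]):
        return 1.0, (1.0, 1.0), icc_band(1.0), True
    msr, msc, mse = _anova_mean_squares(data)

    if form == "ICC3":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else np.inf
        fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f_obs * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else 1.0
        lo, hi = _icc2_ci(icc, msr, msc, mse, n, k, alpha)
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    icc = float(icc)
    return icc, (min(float(lo), icc), max(float(hi), icc)), icc_band(icc), False


def _icc2_ci(icc: float, msr: float, msc: float, mse: float,
             n: int, k: int, alpha: float) -> tuple[float, float]:
    """F-based CI for ICC(2,1) with Satterthwaite degrees of freedom."""
    if mse == 0:
        return 1.0, 1.0
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f_lo = sps.f.ppf(1 - alpha / 2, n - 1.0, v)
    f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1.0)
    lo = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    return lo, hi


def bland_altman(pm: PairedMeasurements) -> dict:
    """Bland–Altman agreement: mean difference and 1.96-SD limits.

    Differences are oriented visit1 - visit2 (recorded in the output);
    returns per-subject (mean, difference) points for plotting.
    """
    d = pm.visit1 - pm.visit2
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_lo": mean_diff - 1.96 * sd,
        "loa_hi": mean_diff + 1.96 * sd,
        "orientation": "visit1-visit2",
        "points": np.column_stack([(pm.visit1 + pm.visit2) / 2.0, d]),
    }


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z confidence interval and two-sided p.

    Raises ``ValueError`` for constant input (zero variance) or n < 4.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired values")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


@dataclass
class RepeatabilityReport:
    """One repeatability panel row (one metric variant in one region)."""

    n: int
    mean_avg: float
    sd_avg: float
    t_p_value: float
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    bland_altman: tuple[float, float, float]  # (mean_diff, loa_lo, loa_hi)
    pearson_r: Optional[float] = None
    pearson_ci: Optional[tuple[float, float]] = None
    pearson_p: Optional[float] = None
    degenerate: bool = False
    label: dict = field(default_factory=dict)


def analyse_pair(pm: PairedMeasurements, icc_form: str = "ICC2") -> RepeatabilityReport:
    """Full repeatability panel for one paired-measurement set."""
    avg = (pm.visit1 + pm.visit2) / 2.0
    _, _, p, t_degen = paired_t_test(pm)
    icc, ci, band, icc_degen = icc_two_way(pm, form=icc_form)
    ba = bland_altman(pm)
    return RepeatabilityReport(
        n=pm.n,
        mean_avg=float(avg.mean()),
        sd_avg=float(avg.std(ddof=1)),
        t_p_value=p,
        icc=icc,
        icc_ci=ci,
        icc_band=band,
        bland_altman=(ba["mean_diff"], ba["loa_lo"], ba["loa_hi"]),
        degenerate=t_degen or icc_degen,
    )


def build_report(
    long_df: pd.DataFrame,
    reference_variant: dict[str, str] | None = None,
    icc_form: str = "ICC2",
) -> pd.DataFrame:
    """Repeatability report over a long-format measurement table.

    ``long_df`` columns: subject_id, visit, slab, region, variant, metric,
    value — one row per measurement. One report row is produced per
    (slab, metric, region, variant); the Pearson column compares each
    variant's per-subject two-visit averages against the reference variant
    for that metric (e.g. the unfiltered scan, or the k = 1 threshold),
    following the reference-row convention of repeatability tables.

    ``reference_variant`` maps metric name -> reference variant name;
    metrics without an entry get no Pearson column. Raises ``ValueError``
    if a configured reference variant is missing from the table.
    """
    required = {"subject_id", "visit", "slab", "region", "variant", "metric", "value"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    reference_variant = reference_variant or {}

    rows = []
    group_cols = ["slab", "metric", "region"]
    for (slab, metric, region), grp in long_df.groupby(group_cols, sort=True, dropna=False):
        wide = grp.pivot_table(index="subject_id", columns=["variant", "visit"],
                               values="value", aggfunc="first")
        ref_name = reference_variant.get(metric)
        variants = sorted(grp["variant"].unique())
        if ref_name is not None and ref_name not in variants:
            raise ValueError(
                f"reference variant {ref_name!r} missing for metric {metric!r}")
        ref_avg = None
        if ref_name is not None:
            ref_avg = (wide[(ref_name, 1)] + wide[(ref_name, 2)]) / 2.0
        for variant in variants:
            sub = wide[[(variant, 1), (variant, 2)]].dropna()
            pm = PairedMeasurements(
                subject_ids=list(sub.index),
                visit1=sub[(variant, 1)].to_numpy(),
                visit2=sub[(variant, 2)].to_numpy(),
                metric_label=f"{slab}/{metric}/{region}/{variant}",
            )
            rep = analyse_pair(pm, icc_form=icc_form)
            row = {
                "slab": slab, "metric": metric, "region": region, "variant": variant,
                "n": rep.n, "mean_avg": rep.mean_avg, "sd_avg": rep.sd_avg,
                "t_p_value": rep.t_p_value,
                "icc": rep.icc, "icc_lo": rep.icc_ci[0], "icc_hi": rep.icc_ci[1],
                "icc_band": rep.icc_band,
                "ba_mean_diff": rep.bland_altman[0],
                "ba_loa_lo": rep.bland_altman[1],
                "ba_loa_hi": rep.bland_altman[2],
                "degenerate": rep.degenerate,
                "pearson_r": np.nan, "pearson_lo": np.nan, "pearson_hi": np.nan,
                "pearson_p": np.nan, "reference": "",
            }
            if ref_name is not None:
                if variant == ref_name:
                    row["reference"] = "reference"
                else:
                    var_avg = (sub[(variant, 1)] + sub[(variant, 2)]) / 2.0
                    joined = pd.concat([ref_avg.rename("ref"), var_avg.rename("var")],
                                       axis=1).dropna()
                    try:
                        r, (lo, hi), p = pearson_with_ci(joined["ref"], joined["var"])
                        row.update(pearson_r=r, pearson_lo=lo, pearson_hi=hi, pearson_p=p)
                    except ValueError:
                        pass  # constant metric: Pearson undefined, left NaN
            rows.append(row)
    return pd.DataFrame(rows)
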