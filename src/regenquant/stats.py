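"""Regenerative Index and cohort statistics.

The Regenerative Index (RI) of a muscle section is the number of
regenerating (eMHC+) myofibers divided by the number of necrotic (IgG+)
myofibers.  Being a ratio of two counts from the same section, it is
invariant to section size and normalises the large between-biopsy
variability in absolute damage, which is what makes it usable as a
longitudinal readout of regenerative capacity.

This module aggregates per-fiber marker calls (or raw per-section counts)
into per-sample summaries and computes the cohort-level statistics: simple
linear regression of a response against age at biopsy, and Welch's
unequal-variance two-sample t-test between age groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RI",
    "SampleSummary",
    "RegressionResult",
    "GroupComparison",
    "compute_ri",
    "round_half_away",
    "summarize_sample",
    "regress_vs_age",
    "welch_ttest",
    "build_cohort_report",
    "load_reference_cohort",
    "summaries_from_cohort_table",
    "plot_ri_vs_age",
]

YOUNG_GROUP = "7-8"
OLD_GROUP = "9-11"


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (so 10.25 -> 10.3 at 1 dp).

    Python's builtin ``round`` uses banker's rounding, which disagrees with
    the convention used when reporting RI values.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RI:
    """An RI value with its definedness status.

    ``status`` is ``"defined"`` when there is at least one IgG+ fiber,
    ``"undefined"`` when both counts are zero (no damage, no regeneration —
    the ratio carries no information), and ``"infinite"`` when regenerating
    fibers are present without any necrotic ones.
    """

    value: float | None
    status: str  # "defined" | "undefined" | "infinite"

    @property
    def defined(self) -> bool:
        return self.status == "defined"

    @property
    def rounded(self) -> float | None:
        """Value for reporting: one decimal, ties away from zero."""
        if self.value is None:
            return None
        return round_half_away(self.value, 1)

    def __str__(self) -> str:
        if self.status == "defined":
            return f"{self.rounded:.1f}"
        return self.status


def compute_ri(n_emhc: float, n_igg: float) -> RI:
    """Regenerative Index: eMHC+ fiber count over IgG+ fiber count.

    Counts may be fractional (averages over replicate sections).

    Raises
    ------
    ValueError
        If either count is negative.
    """
    if n_emhc < 0 or n_igg < 0:
        raise ValueError(f"fiber counts must be non-negative, got eMHC={n_emhc}, IgG={n_igg}")
    if n_igg > 0:
        return RI(value=n_emhc / n_igg, status="defined")
    if n_emhc == 0:
        return RI(value=None, status="undefined")
    return RI(value=None, status="infinite")


@dataclass
class SampleSummary:
    """Per-biopsy counts, percentages and RI (one row of a cohort table)."""

    sample_id: str
    age: float
    group: str
    n_total: float
    n_igg: float
    n_emhc: float
    pct_igg: float
    pct_emhc: float
    ri: RI
    status: str = "DMD"

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "age": self.age,
            "status": self.status,
            "group": self.group,
            "n_igg": self.n_igg,
            "n_emhc": self.n_emhc,
            "n_total": self.n_total,
            "pct_igg": self.pct_igg,
            "pct_emhc": self.pct_emhc,
            "pct_igg_rounded": round_half_away(self.pct_igg, 2),
            "pct_emhc_rounded": round_half_away(self.pct_emhc, 2),
            "ri": self.ri.value,
            "ri_rounded": self.ri.rounded,
            "ri_status": self.ri.status,
            "ri_display": str(self.ri),
        }


def _age_group(age: float) -> str:
    return YOUNG_GROUP if age <= 8 else OLD_GROUP


def summarize_sample(
    replicates: Sequence[tuple[float, float, float]] | tuple[float, float, float],
    sample_id: str,
    age: float,
    status: str = "DMD",
) -> SampleSummary:
    """Summarise one biopsy from one or more replicate sections.

    Parameters
    ----------
    replicates
        One ``(n_igg, n_emhc, n_total)`` triple per replicate section, or a
        single triple.  Counts are averaged arithmetically across replicates,
        which can yield fractional counts (e.g. 205.5 from sections counting
        205 and 206).
    """
    if isinstance(replicates, tuple) and len(replicates) == 3 and np.isscalar(replicates[0]):
        replicates = [replicates]  # type: ignore[list-item]
    reps = list(replicates)
    if not reps:
        raise ValueError("at least one replicate section is required")
    arr = np.asarray(reps, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("each replicate must be a (n_igg, n_emhc, n_total) triple")
    n_igg, n_emhc, n_total = arr.mean(axis=0)
    if n_total <= 0:
        raise ValueError(f"sample {sample_id!r}: zero total fibers")
    if n_igg > n_total or n_emhc > n_total:
        raise ValueError(f"sample {sample_id!r}: marker count exceeds total fiber count")
    return SampleSummary(
        sample_id=sample_id,
        age=age,
        group=_age_group(age),
        n_total=n_total,
        n_igg=n_igg,
        n_emhc=n_emhc,
        pct_igg=100.0 * n_igg / n_total,
        pct_emhc=100.0 * n_emhc / n_total,
        ri=compute_ri(n_emhc, n_igg),
        status=status,
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression of a response on age."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    response: str = ""
    slope_se: float = float("nan")

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        tcrit = sps.t.ppf(1 - alpha / 2, self.n - 2)
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)

    def summary(self) -> str:
        return (
            f"{self.response or 'response'} ~ age: slope={self.slope:.4g}/yr, "
            f"intercept={self.intercept:.4g}, R²={self.r_squared:.4f}, "
            f"p(slope)={self.p_slope:.4g}, n={self.n}"
        )


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison between two groups."""

    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p: float
    n_a: int = 0
    n_b: int = 0
    label_a: str = ""
    label_b: str = ""

    def summary(self) -> str:
        return (
            f"{self.label_a or 'A'} (mean {self.mean_a:.4g}, n={self.n_a}) vs "
            f"{self.label_b or 'B'} (mean {self.mean_b:.4g}, n={self.n_b}): "
            f"t={self.t_stat:.4g}, df={self.df:.4g}, p={self.p:.4g}"
        )


def _response_values(cohort: Iterable[SampleSummary], response: str, use_rounded_ri: bool) -> tuple[np.ndarray, np.ndarray]:
    ages, values = [], []
    for s in cohort:
        if response == "ri":
            if not s.ri.defined:
                continue
            v = s.ri.rounded if use_rounded_ri else s.ri.value
        else:
            v = getattr(s, response)
        ages.append(s.age)
        values.append(float(v))
    return np.asarray(ages, float), np.asarray(values, float)


def regress_vs_age(
    cohort: Sequence[SampleSummary],
    response: str = "ri",
    *,
    dmd_only: bool = True,
    use_rounded_ri: bool = True,
) -> RegressionResult:
    """Ordinary least squares of a per-sample response on age at biopsy.

    Controls are excluded by default: age trends are a within-disease
    question, and control samples mostly carry undefined RI anyway.

    ``use_rounded_ri`` regresses the reported one-decimal RI column rather
    than the unrounded ratios; this is the convention used when reproducing
    published cohort tables, and makes negligible difference otherwise.
    """
    samples = [s for s in cohort if (s.status == "DMD" or not dmd_only)]
    ages, y = _response_values(samples, response, use_rounded_ri)
    if len(y) < 3:
        raise ValueError(f"need at least 3 samples with defined {response!r}, got {len(y)}")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: all ages identical")
    X = sm.add_constant(ages)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=len(y),
        response=response,
        slope_se=float(fit.bse[1]),
    )


def welch_ttest(a: Sequence[float], b: Sequence[float], label_a: str = "", label_b: str = "") -> GroupComparison:
    """Welch's unpaired two-tailed t-test with Satterthwaite df."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        label_a=label_a,
        label_b=label_b,
    )


def _group_values(cohort: Sequence[SampleSummary], response: str, use_rounded_ri: bool) -> tuple[list[float], list[float]]:
    young, old = [], []
    for s in cohort:
        if s.status != "DMD":
            continue
        if response == "ri":
            if not s.ri.defined:
                continue
            v = s.ri.rounded if use_rounded_ri else s.ri.value
        else:
            v = getattr(s, response)
        (young if s.group == YOUNG_GROUP else old).append(float(v))
    return young, old


@dataclass
class CohortReport:
    """Tables and statistics for a full cohort (per-sample table + stats)."""

    table: pd.DataFrame
    regressions: dict[str, RegressionResult | None]
    comparisons: dict[str, GroupComparison | None]

    def write(self, outdir: str | Path) -> None:
        """Write the report as CSV + JSON, deterministically."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "cohort_table.csv", index=False)
        payload: dict = {"regressions": {}, "comparisons": {}}
        for name, r in self.regressions.items():
            payload["regressions"][name] = None if r is None else {
                "slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_slope": r.p_slope, "n": r.n,
            }
        for name, c in self.comparisons.items():
            payload["comparisons"][name] = None if c is None else {
                "mean_7_8": c.mean_a, "mean_9_11": c.mean_b,
                "t": c.t_stat, "df": c.df, "p": c.p,
            }
        with open(outdir / "cohort_stats.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_cohort_report(cohort: Sequence[SampleSummary], *, use_rounded_ri: bool = True) -> CohortReport:
    """Per-sample table plus the age regressions and group comparisons.

    Regressions (RI, %eMHC, %IgG on age; DMD samples only) and Welch
    comparisons (7-8 vs 9-11 years) are marked not-computable (``None``)
    whenever the cohort is too small rather than raising.
    """
    if not cohort:
        raise ValueError("empty cohort")
    table = pd.DataFrame([s.to_row() for s in cohort])

    regressions: dict[str, RegressionResult | None] = {}
    for response in ("ri", "pct_emhc", "pct_igg"):
        try:
            regressions[response] = regress_vs_age(cohort, response, use_rounded_ri=use_rounded_ri)
        except ValueError:
            regressions[response] = None

    comparisons: dict[str, GroupComparison | None] = {}
    for response in ("ri", "pct_emhc", "pct_igg"):
        young, old = _group_values(cohort, response, use_rounded_ri)
        if len(young) >= 2 and len(old) >= 2:
            comparisons[response] = welch_ttest(young, old, YOUNG_GROUP, OLD_GROUP)
        else:
            comparisons[response] = None
    return CohortReport(table=table, regressions=regressions, comparisons=comparisons)


def summaries_from_cohort_table(df: pd.DataFrame) -> list[SampleSummary]:
    """Build SampleSummary objects from a cohort counts table.

    Expected columns: sample_id, age, status (DMD|CTRL), n_igg, n_emhc,
    n_total.  One row per sample (counts already averaged over replicates).
    """
    out = []
    for _, row in df.iterrows():
        out.append(
            summarize_sample(
                (float(row["n_igg"]), float(row["n_emhc"]), float(row["n_total"])),
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                status=str(row["status"]),
            )
        )
    return out


def load_reference_cohort() -> pd.DataFrame:
    """The packaged 13-sample reference cohort (10 DMD + 3 control).

    Per-section fiber counts for boys 7-11 years old: IgG+ (necrotic),
    eMHC+ (regenerating) and total fiber counts, with age at biopsy.
    Fractional counts are averages of two replicate sections.
    """
    with resources.files("regenquant.data").joinpath("table2.csv").open("r") as fh:
        return pd.read_csv(fh)


def plot_ri_vs_age(cohort: Sequence[SampleSummary], path: str | Path | None = None):
    """Scatter of RI against age for DMD samples with the OLS fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [(s.age, s.ri.rounded) for s in cohort if s.status == "DMD" and s.ri.defined]
    ages = [a for a, _ in pts]
    ris = [r for _, r in pts]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(ages, ris, color="k")
    try:
        reg = regress_vs_age(cohort, "ri")
        xs = np.linspace(min(ages), max(ages), 2)
        ax.plot(xs, reg.intercept + reg.slope * xs, "r-",
                label=f"R²={reg.r_squared:.3f}, p={reg.p_slope:.4f}")
        ax.legend(frameon=False)
    except ValueError:
        pass
    ax.set_xlabel("age at biopsy (years)")
    ax.set_ylabel("Regenerative Index")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
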