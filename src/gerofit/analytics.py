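"""Nonparametric session-progress statistics and distribution summaries.

Session distributions show outliers and unequal variances across sessions,
genders and age ranges, so comparisons use rank-based tests: Mann–Whitney U
between independent groups, the Wilcoxon signed-rank test for paired
session series of the same participants (it does not apply across groups),
and Spearman's rank correlation for monotone association.  Distribution
summaries are five-number boxplot statistics with whiskers at the 10th and
90th percentiles and extreme values reported beyond the whiskers.

Small untied samples are tested exactly (full enumeration of the null
distribution); larger or tied samples use the normal approximation with
midrank tie correction.  Test computations are delegated to
:mod:`scipy.stats` with the method selected explicitly.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assessment import SessionRecord
from .errors import InputError, UndefinedStatisticError

#: Largest total sample size for which the exact null distribution is
#: enumerated (untied data only).
EXACT_N_MAX = 12

#: Age-range bins of the study cohort.
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = ((65, 69), (70, 74), (75, 80))

#: Session contrasts evaluated by default (avoids first-session instability
#: and consecutive-session noise).
DEFAULT_CONTRASTS: tuple[tuple[int, int], ...] = ((2, 4), (4, 6), (2, 6))


def _as_array(sample: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(sample), dtype=float)
    if arr.size == 0:
        raise InputError(f"sample {name!r} is empty")
    return arr


def mann_whitney_u(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Mann–Whitney U test (two-sided).  Returns (U of x, p).

    Ties receive midranks.  The p-value is exact (full enumeration) when
    n_x + n_y ≤ 12 and the pooled data has no ties; otherwise the normal
    approximation with tie correction is used.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    exact = (pooled.size <= EXACT_N_MAX) and (np.unique(pooled).size == pooled.size)
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(paired_diffs: Iterable[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences (two-sided).

    Zero differences are discarded; tied magnitudes receive midranks.  The
    returned statistic W is the sum of the midranks of the positive
    differences; the p-value is exact for n ≤ 12 untied magnitudes, else a
    normal approximation.  Raises :class:`UndefinedStatisticError` when all
    differences are zero.
    """
    d = np.asarray(list(paired_diffs), dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise UndefinedStatisticError("all paired differences are zero")
    mags = np.abs(d)
    ranks = stats.rankdata(mags)  # midranks
    w_plus = float(ranks[d > 0].sum())
    exact = (d.size <= EXACT_N_MAX) and (np.unique(mags).size == mags.size)
    res = stats.wilcoxon(
        d, alternative="two-sided", method="exact" if exact else "approx"
    )
    return w_plus, float(res.pvalue)


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of midranks, p-value
    via the t approximation.  Raises for constant samples (undefined)."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise InputError("samples must have equal length")
    if xa.size < 3:
        raise InputError("need at least 3 paired observations")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise UndefinedStatisticError("correlation undefined for a constant sample")
    res = stats.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BoxplotSummary:
    """Five-number summary with whiskers at the 10th/90th percentiles."""

    q1: float
    median: float
    q3: float
    whisker_low: float  # 10th percentile
    whisker_high: float  # 90th percentile
    outliers: list[float] = field(default_factory=list)

    @classmethod
    def from_sample(cls, values: Iterable[float]) -> "BoxplotSummary":
        arr = _as_array(values, "values")
        w_lo, q1, med, q3, w_hi = np.percentile(arr, [10, 25, 50, 75, 90])
        out = arr[(arr < w_lo) | (arr > w_hi)]
        return cls(float(q1), float(med), float(q3), float(w_lo), float(w_hi),
                   sorted(float(v) for v in out))


# ---------------------------------------------------------------------------
# Progress report
# ---------------------------------------------------------------------------


def _records_frame(records: "Sequence[SessionRecord] | pd.DataFrame") -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "exercise_id": [r.exercise_id for r in records],
            "session": [r.session_index for r in records],
            "average_angle": [r.average_angle for r in records],
        }
    )


def _age_group_label(age: int, bins: Sequence[tuple[int, int]]) -> str:
    for lo, hi in bins:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return "other"


@dataclass
class ProgressReport:
    """Session-progress analytics for one grouping factor.

    ``summaries``: per group × exercise × session boxplot statistics.
    ``within_contrasts``: Mann–Whitney and Wilcoxon results per session
    contrast within each group.  ``cross_group``: same-session Mann–Whitney
    comparisons between consecutive groups (the paired Wilcoxon does not
    apply across groups).  ``notes`` records gaps and degenerate tests
    instead of failing.
    """

    group_by: str
    summaries: pd.DataFrame
    within_contrasts: pd.DataFrame
    cross_group: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def to_csv(self, out_dir: "str | Path") -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (
            ("summaries", self.summaries),
            ("within_contrasts", self.within_contrasts),
            ("cross_group", self.cross_group),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths.append(p)
        return paths

    def plot(self, records: "Sequence[SessionRecord] | pd.DataFrame",
             path: "str | Path", age_bins=DEFAULT_AGE_BINS) -> Path:
        """Boxplots of average angle per session, one panel per
        group × exercise; whiskers at the 10th and 90th percentiles."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = _records_frame(records)
        df["group"] = (
            df["age"].map(lambda a: _age_group_label(a, age_bins))
            if self.group_by == "age"
            else df["gender"]
        )
        groups = sorted(df["group"].unique())
        exercises = sorted(df["exercise_id"].unique())
        fig, axes = plt.subplots(
            len(exercises), len(groups),
            figsize=(3.2 * len(groups), 2.6 * len(exercises)),
            squeeze=False, sharey="row",
        )
        for i, ex in enumerate(exercises):
            for j, g in enumerate(groups):
                sub = df[(df["exercise_id"] == ex) & (df["group"] == g)]
                sessions = sorted(sub["session"].unique())
                data = [sub[sub["session"] == s]["average_angle"] for s in sessions]
                ax = axes[i][j]
                ax.boxplot(data, whis=(10, 90), tick_labels=[str(s) for s in sessions])
                ax.set_title(f"{ex}\n{g}", fontsize=8)
                if j == 0:
                    ax.set_ylabel("average angle (°)")
                ax.set_xlabel("session")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


def progress_report(
    records: "Sequence[SessionRecord] | pd.DataFrame",
    group_by: str = "age",
    contrasts: Sequence[tuple[int, int]] = DEFAULT_CONTRASTS,
    age_bins: Sequence[tuple[int, int]] = DEFAULT_AGE_BINS,
) -> ProgressReport:
    """Full session-progress analysis of a study table.

    Missing sessions are reported as gaps; degenerate Wilcoxon tests
    (identical paired sessions) become notes rather than failures.
    """
    if group_by not in ("age", "gender"):
        raise InputError(f"group_by must be 'age' or 'gender', got {group_by!r}")
    df = _records_frame(records)
    df["group"] = (
        df["age"].map(lambda a: _age_group_label(a, age_bins))
        if group_by == "age"
        else df["gender"]
    )
    notes: list[str] = []
    summary_rows, within_rows, cross_rows = [], [], []
    groups = sorted(df["group"].unique())
    exercises = sorted(df["exercise_id"].unique())

    for g in groups:
        for ex in exercises:
            sub = df[(df["group"] == g) & (df["exercise_id"] == ex)]
            sessions = sorted(sub["session"].unique())
            for s in sessions:
                box = BoxplotSummary.from_sample(
                    sub[sub["session"] == s]["average_angle"]
                )
                summary_rows.append(
                    dict(group=g, exercise_id=ex, session=s,
                         n=int((sub["session"] == s).sum()),
                         whisker_low=box.whisker_low, q1=box.q1,
                         median=box.median, q3=box.q3,
                         whisker_high=box.whisker_high,
                         n_outliers=len(box.outliers))
                )
            for a, b in contrasts:
                if a not in sessions or b not in sessions:
                    notes.append(
                        f"{g}/{ex}: contrast ({a},{b}) skipped, session missing"
                    )
                    continue
                sa = sub[sub["session"] == a].set_index("participant_id")["average_angle"]
                sb = sub[sub["session"] == b].set_index("participant_id")["average_angle"]
                u, p_mw = mann_whitney_u(sa.to_numpy(), sb.to_numpy())
                paired = sb.reindex(sa.index).dropna()
                row = dict(group=g, exercise_id=ex, contrast=f"{a}-{b}",
                           mw_U=u, mw_p=p_mw, wilcoxon_W=np.nan, wilcoxon_p=np.nan)
                try:
                    w, p_w = wilcoxon_signed_rank(
                        (paired - sa.reindex(paired.index)).to_numpy()
                    )
                    row["wilcoxon_W"], row["wilcoxon_p"] = w, p_w
                except UndefinedStatisticError as exc:
                    notes.append(f"{g}/{ex}: Wilcoxon ({a},{b}) degenerate: {exc}")
                within_rows.append(row)

    for ga, gb in zip(groups, groups[1:]):
        for ex in exercises:
            sub = df[df["exercise_id"] == ex]
            for s in sorted(sub["session"].unique()):
                xa = sub[(sub["group"] == ga) & (sub["session"] == s)]["average_angle"]
                xb = sub[(sub["group"] == gb) & (sub["session"] == s)]["average_angle"]
                if xa.empty or xb.empty:
                    notes.append(f"{ga} vs {gb}/{ex}: session {s} missing in a group")
                    continue
                u, p = mann_whitney_u(xa.to_numpy(), xb.to_numpy())
                cross_rows.append(
                    dict(group_a=ga, group_b=gb, exercise_id=ex, session=s,
                         mw_U=u, mw_p=p)
                )

    return ProgressReport(
        group_by=group_by,
        summaries=pd.DataFrame(summary_rows),
        within_contrasts=pd.DataFrame(within_rows),
        cross_group=pd.DataFrame(cross_rows),
        notes=notes,
    )
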