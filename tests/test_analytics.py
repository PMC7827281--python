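"""Nonparametric statistics against brute-force enumeration oracles, and the
session-progress report."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gerofit.analytics import (
    BoxplotSummary,
    mann_whitney_u,
    progress_report,
    spearman_rho,
    wilcoxon_signed_rank,
)
from gerofit.assessment import SessionRecord
from gerofit.errors import InputError, UndefinedStatisticError
from gerofit.simulator import StudyConfig, simulate_study

# ---------------------------------------------------------------------------
# Enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------


def _mw_u_stat(x, y):
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


def mw_exact_p_oracle(x, y):
    """Two-sided exact p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = _mw_u_stat(x, y)
    mean_u = len(x) * len(y) / 2
    dev = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(_mw_u_stat(xs, ys) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p_oracle(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    mags = sorted(abs(d) for d in diffs)
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    n = len(diffs)
    w_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    center = n * (n + 1) / 4
    dev = abs(w_obs - center)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip((ranks[abs(d)] for d in diffs), signs) if s)
        if abs(w - center) >= dev - 1e-12:
            count += 1
    return count / 2**n


def _midranks(values):
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = np.asarray(values)[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)

    def test_identical_multisets_give_central_u(self):
        x = [3.0, 1.0, 4.0, 1.5]
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_x = int(rng.integers(2, 4))
            n_y = int(rng.integers(2, 5))
            pooled = rng.permutation(np.arange(10.0))[: n_x + n_y]
            x, y = pooled[:n_x], pooled[n_x:]
            u, p = mann_whitney_u(x, y)
            assert u == pytest.approx(_mw_u_stat(x, y))
            assert p == pytest.approx(mw_exact_p_oracle(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=9), rng.normal(0.8, 1, size=11)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert w == 15.0
        assert p == pytest.approx(2 / 32, abs=1e-12)

    def test_antisymmetric_diffs_at_null_center(self):
        d = [1.0, -1.5, 1.5, -1.0, 2.0, -2.0]
        w, p = wilcoxon_signed_rank(d)
        assert w == pytest.approx(len(d) * (len(d) + 1) / 4)
        assert p > 0.9

    def test_zeros_discarded(self):
        w_with, p_with = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 0.0])
        w_without, p_without = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert (w_with, p_with) == (w_without, p_without)

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            d = rng.permutation(np.arange(1.0, 12.0))[:n]
            d *= rng.choice([-1, 1], size=n)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(wilcoxon_exact_p_oracle(d), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho, _ = spearman_rho(x, [math.exp(v) for v in x])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, [-v**3 for v in x])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0]
        rho, _ = spearman_rho(x, y)
        rx, ry = _midranks(x), _midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_sample_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            spearman_rho([1, 2, 3], [1, 2])


class TestBoxplotSummary:
    def test_whiskers_at_10th_and_90th_percentiles(self):
        rng = np.random.default_rng(5)
        values = rng.normal(100, 10, size=200)
        box = BoxplotSummary.from_sample(values)
        assert box.whisker_low == pytest.approx(np.percentile(values, 10))
        assert box.whisker_high == pytest.approx(np.percentile(values, 90))
        assert (
            box.whisker_low <= box.q1 <= box.median <= box.q3 <= box.whisker_high
        )
        for v in box.outliers:
            assert v < box.whisker_low or v > box.whisker_high
        assert len(box.outliers) == np.sum(
            (values < box.whisker_low) | (values > box.whisker_high)
        )


class TestProgressReport:
    def test_strong_improvement_everything_significant(self):
        records = simulate_study(StudyConfig(seed=12))
        report = progress_report(records, group_by="age")
        assert (report.within_contrasts["mw_p"] < 0.01).all()
        assert (report.within_contrasts["wilcoxon_p"] < 0.01).all()
        assert (report.cross_group["mw_p"] < 0.001).all()
        # three age groups x two exercises x six sessions of summaries
        assert len(report.summaries) == 3 * 2 * 6

    def test_gender_grouping(self):
        records = simulate_study(StudyConfig(seed=12))
        report = progress_report(records, group_by="gender")
        assert set(report.within_contrasts["group"]) == {"M", "F"}

    def test_single_session_yields_summaries_only(self):
        records = [
            SessionRecord(f"P{i}", 70, "F", "ex", 1, 100.0 + i) for i in range(12)
        ]
        report = progress_report(records)
        assert len(report.summaries) == 1
        assert report.within_contrasts.empty
        assert any("skipped" in n for n in report.notes)

    def test_identical_sessions_surface_degenerate_note(self):
        records = []
        for i in range(12):
            for s in (2, 4):
                records.append(SessionRecord(f"P{i}", 67, "M", "ex", s, 100.0 + i))
        report = progress_report(records, contrasts=[(2, 4)])
        assert any("degenerate" in n for n in report.notes)
        row = report.within_contrasts.iloc[0]
        assert np.isnan(row["wilcoxon_p"]) and row["mw_p"] > 0.9

    def test_csv_and_plot_outputs(self, tmp_path):
        records = simulate_study(StudyConfig(seed=3))
        report = progress_report(records)
        paths = report.to_csv(tmp_path)
        assert all(p.exists() for p in paths)
        assert pd.read_csv(paths[0]).shape[0] == len(report.summaries)
        fig = report.plot(records, tmp_path / "box.png")
        assert fig.exists() and fig.stat().st_size > 0
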