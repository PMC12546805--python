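"""Test-selection decision tree and hypothesis testing for grouped data.

For each measurement the tree works in three layers:

1. Number of conditions: one group means no statistics; every group
   additionally needs at least 3 cilia or no test is run.
2. Normality: Shapiro-Wilk per group at the chosen alpha.
3. Homogeneity of variance: Levene's test across groups.

Chosen tests:

===========================  ==========================  ============================
distributional situation     2 groups                    >2 groups
===========================  ==========================  ============================
normal, homogeneous          Student's t                 one-way ANOVA + Tukey HSD
normal, heterogeneous        Welch's t                   Welch ANOVA + Games-Howell
any group non-normal         Mann-Whitney U              Kruskal-Wallis + Dunn (Holm)
===========================  ==========================  ============================

Significance stars: ``***`` for p <= 0.001, ``**`` for 0.001 < p <= 0.01,
``*`` for 0.01 < p <= 0.05, else ``ns``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Records per group below which the Shapiro test is run on a subsample
#: (the test's p-value is unreliable for very large n).
SHAPIRO_MAX_N = 5000


def stars(p: float) -> str:
    """Map a p-value to the fixed significance-star convention."""
    if np.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class TestDecision:
    """Outcome of the decision tree for one measurement."""

    chosen_test: str
    posthoc: str | None = None
    rationale: list[str] = field(default_factory=list)
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")

    @property
    def runnable(self) -> bool:
        return self.chosen_test not in ("none", "insufficient n")


@dataclass
class StatsResult:
    """Executed test results for one measurement."""

    measurement: str
    decision: TestDecision
    statistic: float = float("nan")
    p_value: float = float("nan")
    stars: str = "ns"
    posthoc_table: pd.DataFrame | None = None


def choose_test(groups: dict[str, np.ndarray], alpha: float = 0.05,
                seed: int = 0) -> TestDecision:
    """Select the statistical test for one measurement.

    ``groups`` maps group label to the measurement values.  The rationale
    trace records every intermediate p-value so the choice is fully
    reproducible from the recorded outcomes.
    """
    labels = list(groups)
    decision = TestDecision(chosen_test="none")
    if len(labels) < 2:
        decision.rationale.append("single condition: no statistical analysis")
        return decision
    sizes = {g: len(np.asarray(v)) for g, v in groups.items()}
    if min(sizes.values()) < 3:
        decision.chosen_test = "insufficient n"
        decision.rationale.append(
            f"at least 3 cilia per condition required, got {sizes}"
        )
        return decision

    all_normal = True
    rng = np.random.default_rng(seed)
    for g in labels:
        vals = np.asarray(groups[g], dtype=float)
        test_vals = vals
        if len(vals) > SHAPIRO_MAX_N:
            test_vals = rng.choice(vals, SHAPIRO_MAX_N, replace=False)
            decision.rationale.append(
                f"{g}: Shapiro on a {SHAPIRO_MAX_N}-record subsample of {len(vals)}"
            )
        if np.ptp(test_vals) == 0:
            p_norm = 0.0  # degenerate constant sample: treat as non-normal
        else:
            _, p_norm = sps.shapiro(test_vals)
        decision.normality_p[g] = float(p_norm)
        decision.rationale.append(f"Shapiro {g}: p={p_norm:.4g}")
        if p_norm < alpha:
            all_normal = False

    two = len(labels) == 2
    if not all_normal:
        decision.chosen_test = "Mann-Whitney U" if two else "Kruskal-Wallis"
        decision.posthoc = None if two else "Dunn (Holm)"
        decision.rationale.append(
            "at least one condition non-normal -> non-parametric branch"
        )
        return decision

    _, p_lev = sps.levene(*[np.asarray(groups[g], dtype=float) for g in labels])
    decision.levene_p = float(p_lev)
    decision.rationale.append(f"Levene: p={p_lev:.4g}")
    if p_lev < alpha:
        decision.chosen_test = "Welch's t" if two else "Welch ANOVA"
        decision.posthoc = None if two else "Games-Howell"
        decision.rationale.append("variances heterogeneous -> Welch branch")
    else:
        decision.chosen_test = "Student's t" if two else "one-way ANOVA"
        decision.posthoc = None if two else "Tukey HSD"
        decision.rationale.append("all normal, variances homogeneous -> parametric branch")
    return decision


def _welch_anova(samples: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F* statistic)."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    variances = np.array([s.var(ddof=1) for s in samples])
    w = ns / variances
    mw = (w * means).sum() / w.sum()
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    b = 1 + (2 * (k - 2) / (k ** 2 - 1)) * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
    f = a / b
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum())
    p = sps.f.sf(f, df1, df2)
    return float(f), float(p)


def _games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances)."""
    rows = []
    for a, b in itertools.combinations(groups, 2):
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        na, nb = len(x), len(y)
        va, vb = x.var(ddof=1) / na, y.var(ddof=1) / nb
        se = np.sqrt(va + vb)
        t = (x.mean() - y.mean()) / se
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
        p = sps.studentized_range.sf(np.abs(t) * np.sqrt(2), len(groups), df)
        rows.append({"group_a": a, "group_b": b, "statistic": float(t),
                     "p_value": float(p), "stars": stars(p)})
    return pd.DataFrame(rows)


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    samples = [np.asarray(v, float) for v in groups.values()]
    res = sps.tukey_hsd(*samples)
    labels = list(groups)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": float(res.statistic[i, j]),
                     "p_value": p, "stars": stars(p)})
    return pd.DataFrame(rows)


def _dunn_holm(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Holm correction.

    Z statistics use the pooled-rank means with a tie correction; the
    raw two-sided p-values are Holm-adjusted across all pairs.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], float) for g in labels]
    all_vals = np.concatenate(samples)
    ranks = sps.rankdata(all_vals)
    n = len(all_vals)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n - 1))
    rank_means, sizes = [], []
    start = 0
    for s in samples:
        rank_means.append(ranks[start:start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    rows = []
    raw_p = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rank_means[i] - rank_means[j]) / se
        p = 2 * sps.norm.sf(abs(z))
        raw_p.append(p)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": float(z)})
    adj = multipletests(raw_p, method="holm")[1]
    for row, p in zip(rows, adj):
        row["p_value"] = float(p)
        row["stars"] = stars(p)
    return pd.DataFrame(rows)


def run_test(groups: dict[str, np.ndarray], decision: TestDecision) -> tuple[float, float, pd.DataFrame | None]:
    """Execute the chosen test; returns (statistic, p, post-hoc table)."""
    samples = [np.asarray(v, float) for v in groups.values()]
    name = decision.chosen_test
    posthoc = None
    if name == "Student's t":
        stat, p = sps.ttest_ind(*samples, equal_var=True)
    elif name == "Welch's t":
        stat, p = sps.ttest_ind(*samples, equal_var=False)
    elif name == "Mann-Whitney U":
        stat, p = sps.mannwhitneyu(*samples, alternative="two-sided")
    elif name == "one-way ANOVA":
        stat, p = sps.f_oneway(*samples)
        posthoc = _tukey(groups)
    elif name == "Welch ANOVA":
        stat, p = _welch_anova(samples)
        posthoc = _games_howell(groups)
    elif name == "Kruskal-Wallis":
        stat, p = sps.kruskal(*samples)
        posthoc = _dunn_holm(groups)
    else:
        raise ValueError(f"test {name!r} is not runnable")
    return float(stat), float(p), posthoc


def run_stats(dataset, measurements: list[str], alpha: float = 0.05,
              seed: int = 0, no_stats: bool = False) -> dict[str, StatsResult]:
    """Run the decision tree and the chosen test per measurement.

    ``dataset`` is a :class:`~ciliametry.explorer.GroupedDataset`.  With
    ``no_stats`` the tree and tests are skipped entirely (summary tables
    are still produced by the output stage).  Integer-valued measurements
    get a warning in the rationale: ordinal variables may need adapted
    tests, so their results should be read with care.
    """
    results: dict[str, StatsResult] = {}
    for meas in measurements:
        groups = {g: dataset.values(meas, g) for g in dataset.group_labels}
        groups = {g: v[~np.isnan(v)] for g, v in groups.items() if v.size}
        if no_stats:
            decision = TestDecision(chosen_test="none",
                                    rationale=["statistics disabled"])
            results[meas] = StatsResult(measurement=meas, decision=decision)
            continue
        decision = choose_test(groups, alpha=alpha, seed=seed)
        if any(np.allclose(v, np.round(v)) for v in groups.values() if v.size):
            decision.rationale.append(
                "integer-valued measurement: ordinal variable, interpret "
                "test results with care"
            )
        result = StatsResult(measurement=meas, decision=decision)
        if decision.runnable:
            stat, p, posthoc = run_test(groups, decision)
            result.statistic = stat
            result.p_value = p
            result.stars = stars(p)
            result.posthoc_table = posthoc
        results[meas] = result
    return results


def statistics_text(results: dict[str, StatsResult]) -> str:
    """Render the statistics summary text file."""
    lines = ["# statistics summary",
             "# stars: *** p<=0.001, ** p<=0.01, * p<=0.05, ns otherwise", ""]
    for meas, res in results.items():
        lines.append(f"measurement: {meas}")
        lines.append(f"  test: {res.decision.chosen_test}")
        if res.decision.runnable:
            lines.append(f"  statistic: {res.statistic:.6g}")
            lines.append(f"  p-value: {res.p_value:.6g}")
            lines.append(f"  significance: {res.stars}")
        for entry in res.decision.rationale:
            lines.append(f"  rationale: {entry}")
        if res.posthoc_table is not None:
            lines.append(f"  post-hoc ({res.decision.posthoc}):")
            for _, row in res.posthoc_table.iterrows():
                lines.append(
                    f"    {row['group_a']} vs {row['group_b']}: "
                    f"p={row['p_value']:.6g} {row['stars']}"
                )
        lines.append("")
    return "\n".join(lines)
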