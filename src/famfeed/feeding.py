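"""Pharyngeal pumping-rate statistics.

Pump counts become per-animal rates (adults: mean of three 30 s counts
× 2 → pumps/min; L1 larvae: mean of two 55 s counts, reported per 55 s).
Groups are compared with the battery used throughout the familiar-food
study:

* two-group comparisons run both the unpaired Welch t-test and the
  Mann–Whitney U test (two-tailed) and report the more conservative
  (larger) p-value;
* multi-group comparisons use one-way ANOVA with a post hoc Tukey HSD
  (Tukey–Kramer for unequal n);
* the headline receptor-effect statistic is a difference of group-mean
  differences, e.g. for the SER-7 effect

  .. math::

     t = \\frac{(\\bar x_{wt,HH} - \\bar x_{ser7,HH})
              - (\\bar x_{wt,DH} - \\bar x_{ser7,DH})}
             {\\sqrt{\\sum_i s_i^2 / n_i}}

  with Welch–Satterthwaite degrees of freedom over the four variance/n
  terms.

Only familiar- and novel-food groups tested on the *same* test food are
ever compared (HH vs DH, DD vs HD), because absolute rates differ between
bacteria; requesting a cross-test-food comparison is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeedingObservation",
    "GroupSummary",
    "TwoSampleResult",
    "ContrastResult",
    "AnovaTukeyResult",
    "pumps_to_rate",
    "rates_from_table",
    "summarize_group",
    "conservative_two_sample_test",
    "anova_tukey",
    "effect_contrast",
    "familiar_vs_novel_tests",
    "check_comparison_policy",
    "FamiliarityContrastModel",
    "FAMILIAR_CODES",
    "NOVEL_CODES",
]

FAMILIAR_CODES = ("HH", "DD")
NOVEL_CODES = ("DH", "HD")

#: exact Mann-Whitney enumeration is used when both groups are at most
#: this large and there are no ties
EXACT_MW_MAX_N = 8


class StatsError(ValueError):
    pass


class ComparisonPolicyError(StatsError):
    """Raised when two groups tested on different foods are compared."""


@dataclass(frozen=True)
class FeedingObservation:
    """Pump counts of one animal.

    Adults carry three 30 s counts, L1 larvae two 55 s counts.
    """

    animal_id: str
    genotype: str
    training_food: str
    test_food: str
    counts: tuple[int, ...]
    window_s: float
    stage: str  # "adult" | "l1"

    def __post_init__(self):
        if self.stage == "adult":
            if len(self.counts) != 3 or self.window_s != 30:
                raise StatsError(
                    f"{self.animal_id}: adult observations need 3 counts of 30 s"
                )
        elif self.stage == "l1":
            if len(self.counts) != 2 or self.window_s != 55:
                raise StatsError(
                    f"{self.animal_id}: L1 observations need 2 counts of 55 s"
                )
        else:
            raise StatsError(f"{self.animal_id}: unknown stage {self.stage!r}")
        if any(c < 0 for c in self.counts):
            raise StatsError(f"{self.animal_id}: counts must be non-negative")

    @property
    def condition(self) -> str:
        return f"{self.training_food}{self.test_food}"


def pumps_to_rate(obs: FeedingObservation) -> float:
    """Per-animal feeding rate.

    Adults: mean of the three 30 s counts × 2 → pumps/min.  L1 larvae:
    mean of the two 55 s counts, left on the pumps-per-55 s scale.
    """
    mean_count = float(np.mean(obs.counts))
    return mean_count * 2.0 if obs.stage == "adult" else mean_count


def rates_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``rate`` column to a tidy pump-count table.

    Expects columns ``animal_id, genotype, training_food, test_food,
    stage, window_s, count1..countK`` (K = 3 for adults, 2 for L1).
    """
    count_cols = sorted(c for c in df.columns if c.startswith("count"))
    rates = []
    for _, row in df.iterrows():
        counts = tuple(int(row[c]) for c in count_cols if pd.notna(row[c]))
        obs = FeedingObservation(
            animal_id=str(row["animal_id"]),
            genotype=str(row["genotype"]),
            training_food=str(row["training_food"]),
            test_food=str(row["test_food"]),
            counts=counts,
            window_s=float(row["window_s"]),
            stage=str(row["stage"]),
        )
        rates.append(pumps_to_rate(obs))
    out = df.copy()
    out["rate"] = rates
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, unbiased variance and SEM of one group's rates."""

    n: int
    mean: float
    variance: float
    sem: float

    @property
    def var_over_n(self) -> float:
        return self.variance / self.n


def summarize_group(rates) -> GroupSummary:
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise StatsError("cannot summarise an empty group")
    n = rates.size
    mean = float(rates.mean())
    var = float(rates.var(ddof=1)) if n >= 2 else float("nan")
    sem = float(np.sqrt(var / n)) if n >= 2 else float("nan")
    return GroupSummary(n=n, mean=mean, variance=var, sem=sem)


# ---------------------------------------------------------------------------
# two-sample battery


@dataclass(frozen=True)
class TwoSampleResult:
    """Welch t and Mann–Whitney U results with the conservative p-value."""

    t_statistic: float
    p_t: float
    u_statistic: float
    p_mw: float
    mw_method: str  # "exact" | "asymptotic"

    @property
    def p_conservative(self) -> float:
        return max(self.p_t, self.p_mw)


def conservative_two_sample_test(a, b, flavor: str = "welch") -> TwoSampleResult:
    """Two-tailed unpaired t-test and Mann–Whitney U test; the larger
    (more conservative) p-value is the headline result.

    ``flavor`` selects the t-test: ``"welch"`` (default, unequal
    variances) or ``"pooled"`` (classic Student).  The Mann–Whitney p is
    exact by enumeration when both groups have at most ``EXACT_MW_MAX_N``
    observations and there are no ties, otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    if flavor not in ("welch", "pooled"):
        raise StatsError(f"unknown t-test flavor {flavor!r}")

    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t_stat, p_t = 0.0, 1.0
    else:
        t_stat, p_t = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))

    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    use_exact = no_ties and a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N
    method = "exact" if use_exact else "asymptotic"
    u_stat, p_mw = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TwoSampleResult(
        t_statistic=float(t_stat),
        p_t=float(min(p_t, 1.0)),
        u_statistic=float(u_stat),
        p_mw=float(min(p_mw, 1.0)),
        mw_method=method,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA with Tukey HSD


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_overall: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, p_adj

    def pairwise_p(self, g1: str, g2: str) -> float:
        for _, row in self.pairwise.iterrows():
            if {row["group1"], row["group2"]} == {g1, g2}:
                return float(row["p_adj"])
        raise KeyError(f"no pairwise comparison {g1} vs {g2}")


def anova_tukey(groups: dict) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA plus all pairwise Tukey HSD contrasts.

    Unequal group sizes use the Tukey–Kramer adjustment.  Requires at
    least two groups with at least two observations each; a dataset whose
    values are all identical has no defined F statistic and is rejected.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise StatsError("need at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise StatsError("each group needs at least 2 observations")
    allvals = np.concatenate(samples)
    if np.all(allvals == allvals[0]):
        raise StatsError("all observations identical: F statistic undefined")

    f_stat, p_overall = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_overall=float(p_overall),
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# difference-of-differences contrast


@dataclass(frozen=True)
class ContrastResult:
    """Difference (or difference-of-differences) of group means.

    ``estimate`` is ``(m1 − m2) − (m3 − m4)`` (or ``m1 − m2`` in the
    two-group variant); ``sem`` is the root of the summed variance/n
    terms; ``p`` is two-tailed.
    """

    estimate: float
    sem: float
    t_statistic: float
    df: float
    p: float
    n_groups: int

    def summary(self) -> str:
        kind = (
            "difference of group-mean differences"
            if self.n_groups == 4
            else "difference of group means"
        )
        return "\n".join(
            [
                f"Contrast ({kind})",
                "=" * 44,
                f"estimate   {self.estimate:.4f}",
                f"sem        {self.sem:.4f}",
                f"t          {self.t_statistic:.4f}",
                f"df         {self.df:.2f}",
                f"p (2-tail) {self.p:.4g}",
            ]
        )


def _welch_satterthwaite_df(summaries) -> float:
    terms = np.array([s.var_over_n for s in summaries])
    dens = np.array([s.var_over_n**2 / (s.n - 1) for s in summaries])
    total = terms.sum()
    if total == 0:
        return float("nan")
    return float(total**2 / dens.sum())


def effect_contrast(
    g1: GroupSummary,
    g2: GroupSummary,
    g3: GroupSummary | None = None,
    g4: GroupSummary | None = None,
    df_policy: str = "welch-satterthwaite",
) -> ContrastResult:
    """Difference-of-differences contrast between four group summaries.

    With four groups the estimate is ``(mean1 − mean2) − (mean3 − mean4)``
    — e.g. the SER-7 effect on familiar food minus the SER-7 effect on
    novel food — with standard error ``sqrt(Σ var_i/n_i)``.  With ``g3``
    and ``g4`` omitted it reduces to the plain two-group difference with
    ``sqrt(v1/n1 + v2/n2)``.

    ``df_policy`` is ``"welch-satterthwaite"`` (default) or ``"normal"``
    (standard-normal reference for the statistic).
    """
    if (g3 is None) != (g4 is None):
        raise StatsError("provide both g3 and g4 or neither")
    summaries = [g1, g2] if g3 is None else [g1, g2, g3, g4]
    for s in summaries:
        if s.n < 2:
            raise StatsError("every group needs n >= 2 for the contrast")
        if not np.isfinite(s.variance):
            raise StatsError("every group needs a finite variance")
    if df_policy not in ("welch-satterthwaite", "normal"):
        raise StatsError(f"unknown df_policy {df_policy!r}")

    if g3 is None:
        estimate = g1.mean - g2.mean
    else:
        estimate = (g1.mean - g2.mean) - (g3.mean - g4.mean)
    sem = float(np.sqrt(sum(s.var_over_n for s in summaries)))

    if sem == 0.0:
        t = 0.0 if estimate == 0.0 else np.inf * np.sign(estimate)
    else:
        t = estimate / sem

    if df_policy == "normal":
        df = float("inf")
        p = 2.0 * stats.norm.sf(abs(t)) if np.isfinite(t) else 0.0
    else:
        df = _welch_satterthwaite_df(summaries)
        if not np.isfinite(t):
            p = 0.0
        elif t == 0.0:
            p = 1.0
        else:
            p = 2.0 * stats.t.sf(abs(t), df)
    return ContrastResult(
        estimate=float(estimate),
        sem=sem,
        t_statistic=float(t),
        df=df,
        p=float(min(p, 1.0)),
        n_groups=len(summaries),
    )


# ---------------------------------------------------------------------------
# comparison policy and table-level analysis


def check_comparison_policy(condition_a: str, condition_b: str) -> None:
    """Allow only familiar-vs-novel pairs sharing a test food.

    Valid pairs: HH vs DH (test food H) and DD vs HD (test food D).
    Absolute rates differ between bacteria, so groups tested on different
    foods are never compared.
    """
    pair = {condition_a, condition_b}
    if pair not in ({"HH", "DH"}, {"DD", "HD"}):
        raise ComparisonPolicyError(
            f"comparison {condition_a} vs {condition_b} crosses test foods; "
            "only familiar-vs-novel pairs on the same test food are allowed "
            "(HH vs DH, DD vs HD)"
        )


def familiar_vs_novel_tests(df: pd.DataFrame) -> pd.DataFrame:
    """Conservative two-sample tests of familiar vs novel groups, per
    genotype and test food, from a tidy pump-count table.
    """
    df = rates_from_table(df)
    df["condition"] = df["training_food"].astype(str) + df["test_food"].astype(str)
    rows = []
    for (genotype, test_food), sub in df.groupby(["genotype", "test_food"]):
        familiar = sub[sub["training_food"] == sub["test_food"]]
        novel = sub[sub["training_food"] != sub["test_food"]]
        if len(familiar) < 2 or len(novel) < 2:
            continue
        cond_f = familiar["condition"].iloc[0]
        cond_n = novel["condition"].iloc[0]
        check_comparison_policy(cond_f, cond_n)
        res = conservative_two_sample_test(familiar["rate"], novel["rate"])
        rows.append(
            {
                "genotype": genotype,
                "comparison": f"{cond_f} vs {cond_n}",
                "mean_familiar": familiar["rate"].mean(),
                "mean_novel": novel["rate"].mean(),
                "t": res.t_statistic,
                "p_t": res.p_t,
                "U": res.u_statistic,
                "p_mw": res.p_mw,
                "p_conservative": res.p_conservative,
            }
        )
    return pd.DataFrame(rows)


class FamiliarityContrastModel:
    """Receptor-effect contrast fitted from a tidy pump-count table.

    Compares the effect of a mutation (e.g. *ser-7*) on the feeding rate
    between a familiar-food condition and the novel-food condition sharing
    its test food — a difference of differences over four groups:

    (reference, familiar) − (mutant, familiar)
    minus (reference, novel) − (mutant, novel).
    """

    def __init__(
        self,
        summaries: tuple[GroupSummary, GroupSummary, GroupSummary, GroupSummary],
        labels: tuple[str, ...],
        df_policy: str = "welch-satterthwaite",
    ):
        self.summaries = summaries
        self.labels = labels
        self.df_policy = df_policy

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        reference_genotype: str,
        mutant_genotype: str,
        familiar_condition: str = "HH",
        novel_condition: str = "DH",
        df_policy: str = "welch-satterthwaite",
    ) -> "FamiliarityContrastModel":
        check_comparison_policy(familiar_condition, novel_condition)
        if familiar_condition not in FAMILIAR_CODES:
            raise ComparisonPolicyError(
                f"{familiar_condition!r} is not a familiar-food condition"
            )
        df = rates_from_table(df)
        df["condition"] = df["training_food"].astype(str) + df["test_food"].astype(str)
        cells = [
            (reference_genotype, familiar_condition),
            (mutant_genotype, familiar_condition),
            (reference_genotype, novel_condition),
            (mutant_genotype, novel_condition),
        ]
        summaries = []
        for genotype, cond in cells:
            sel = df[(df["genotype"] == genotype) & (df["condition"] == cond)]
            if len(sel) < 2:
                raise StatsError(
                    f"group ({genotype}, {cond}) has fewer than 2 animals"
                )
            summaries.append(summarize_group(sel["rate"]))
        labels = tuple(f"{g}:{c}" for g, c in cells)
        return cls(tuple(summaries), labels, df_policy)

    def fit(self) -> ContrastResult:
        return effect_contrast(*self.summaries, df_policy=self.df_policy)
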