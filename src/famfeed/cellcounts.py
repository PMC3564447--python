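"""Serotonin-positive cell-count analysis.

Each animal contributes a count in {0..3}: the number of serotonin-positive
cells among the two AIM neurons and RIH (ADF, NSM and HSN are excluded by
the scoring protocol).  Per experiment, the post-starvation baseline mean
is subtracted from each refed group's mean (HH/HD against the H baseline,
DD/DH against the D baseline), familiar and novel increases are compared
with a difference-of-differences t statistic over the four underlying
groups, and the per-experiment p-values are combined across k independent
experiments by Fisher's method:

.. math::

   \\chi^2 = -2 \\sum_{i=1}^{k} \\ln p_i \\sim \\chi^2_{2k}
   \\quad \\text{under the joint null.}
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feeding import ContrastResult, GroupSummary, StatsError, effect_contrast, summarize_group

__all__ = [
    "CountObservation",
    "BaselineAdjustedSummary",
    "FisherResult",
    "baseline_subtract",
    "per_experiment_contrast",
    "fisher_combine",
    "CellCountFamiliarityModel",
    "FisherCombinedResults",
    "CONDITIONS",
    "BASELINE_OF",
]

CONDITIONS = ("H", "D", "HH", "DH", "DD", "HD")

#: starvation baseline matching each refed condition's training food
BASELINE_OF = {"HH": "H", "HD": "H", "DD": "D", "DH": "D"}

#: the two familiarity comparisons: (familiar refed, novel refed)
COMPARISON_PAIRS = {"HHvsDH": ("HH", "DH"), "DDvsHD": ("DD", "HD")}


@dataclass(frozen=True)
class CountObservation:
    """One animal's serotonin-positive AIM/RIH count."""

    animal_id: str
    condition: str
    experiment: int
    count: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise StatsError(
                f"{self.animal_id}: unknown condition {self.condition!r}"
            )
        if not 0 <= self.count <= 3:
            raise StatsError(
                f"{self.animal_id}: count {self.count} outside 0..3"
            )
        if self.experiment < 1:
            raise StatsError(f"{self.animal_id}: experiment index must be >= 1")


@dataclass(frozen=True)
class BaselineAdjustedSummary:
    """Refed-group mean minus starvation-baseline mean, one experiment."""

    refed_condition: str
    baseline_condition: str
    experiment: int
    delta_mean: float
    sem: float
    refed: GroupSummary
    baseline: GroupSummary


def baseline_subtract(refed_counts, baseline_counts, refed_condition: str,
                      baseline_condition: str, experiment: int) -> BaselineAdjustedSummary:
    """Baseline-subtracted mean increase in serotonin-positive cells.

    ``delta = mean(refed) − mean(baseline)`` with
    ``sem = sqrt(var_refed/n_refed + var_baseline/n_baseline)``.  The
    baseline must match the refed group's training food (HH/HD ↔ H,
    DD/DH ↔ D).
    """
    if BASELINE_OF.get(refed_condition) != baseline_condition:
        raise StatsError(
            f"baseline {baseline_condition!r} does not match the training food "
            f"of refed condition {refed_condition!r}"
        )
    refed = summarize_group(refed_counts)
    base = summarize_group(baseline_counts)
    delta = refed.mean - base.mean
    sem = float(np.sqrt(refed.var_over_n + base.var_over_n))
    return BaselineAdjustedSummary(
        refed_condition=refed_condition,
        baseline_condition=baseline_condition,
        experiment=experiment,
        delta_mean=float(delta),
        sem=sem,
        refed=refed,
        baseline=base,
    )


def per_experiment_contrast(
    familiar: BaselineAdjustedSummary,
    novel: BaselineAdjustedSummary,
    df_policy: str = "welch-satterthwaite",
) -> ContrastResult:
    """Familiar-vs-novel contrast of baseline-subtracted increases within
    one experiment.

    ``t = [(mean_fam − mean_base,f) − (mean_nov − mean_base,n)] /
    sqrt(Σ var_i/n_i)`` over the four underlying groups; two-tailed p.
    """
    if familiar.experiment != novel.experiment:
        raise StatsError("summaries come from different experiments")
    valid = {("HH", "DH"), ("DD", "HD")}
    if (familiar.refed_condition, novel.refed_condition) not in valid:
        raise StatsError(
            f"invalid condition pair {familiar.refed_condition} vs "
            f"{novel.refed_condition}; use HH vs DH or DD vs HD"
        )
    return effect_contrast(
        familiar.refed, familiar.baseline, novel.refed, novel.baseline,
        df_policy=df_policy,
    )


@dataclass(frozen=True)
class FisherResult:
    """Fisher-combined evidence across k independent tests."""

    chi2: float
    df: int
    p_combined: float
    per_experiment_p: tuple[float, ...]


def fisher_combine(p_values, floor: float | None = None) -> FisherResult:
    """Combine independent p-values: ``χ² = −2 Σ ln p_i`` on 2k degrees
    of freedom; the combined p is the upper-tail χ² probability.

    Independence of the inputs is the caller's responsibility.  Values
    outside (0, 1] are rejected; ``floor`` (off by default) clips tiny
    p-values up to the given positive value before combining, for
    pipeline robustness only.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise StatsError("need at least one p-value")
    if floor is not None:
        if floor <= 0 or floor >= 1:
            raise StatsError("floor must lie in (0, 1)")
        p = np.maximum(p, floor)
    if np.any(p <= 0) or np.any(p > 1):
        raise StatsError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return FisherResult(
        chi2=chi2,
        df=df,
        p_combined=float(stats.chi2.sf(chi2, df)),
        per_experiment_p=tuple(float(x) for x in p),
    )


# ---------------------------------------------------------------------------
# model / results surface


class CellCountFamiliarityModel:
    """Familiarity analysis of a tidy cell-count table.

    For the requested comparison (``"HHvsDH"`` or ``"DDvsHD"``), each
    experiment yields a baseline-subtracted familiar-vs-novel contrast;
    the per-experiment two-tailed p-values are then combined by Fisher's
    method.
    """

    def __init__(self, df: pd.DataFrame, comparison: str = "HHvsDH",
                 df_policy: str = "welch-satterthwaite"):
        if comparison not in COMPARISON_PAIRS:
            raise StatsError(
                f"unknown comparison {comparison!r}; use one of "
                f"{sorted(COMPARISON_PAIRS)}"
            )
        required = {"animal_id", "condition", "experiment", "count"}
        missing = required - set(df.columns)
        if missing:
            raise StatsError(f"cell-count table missing columns {sorted(missing)}")
        # vectorised row validation, mirroring the CountObservation invariants
        bad = ~df["condition"].astype(str).isin(CONDITIONS)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise StatsError(
                f"row {i}: unknown condition {df['condition'].iloc[i]!r}"
            )
        counts = df["count"].to_numpy()
        bad = (counts < 0) | (counts > 3)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise StatsError(f"row {i}: count {counts[i]} outside 0..3")
        if (df["experiment"].to_numpy() < 1).any():
            raise StatsError("experiment indices must be >= 1")
        self.df = df
        self.comparison = comparison
        self.df_policy = df_policy

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, comparison: str = "HHvsDH",
                       df_policy: str = "welch-satterthwaite"):
        return cls(df, comparison=comparison, df_policy=df_policy)

    def fit(self) -> "FisherCombinedResults":
        fam_cond, nov_cond = COMPARISON_PAIRS[self.comparison]
        rows = []
        p_values = []
        for exp, sub in self.df.groupby("experiment"):
            def counts(cond):
                vals = sub.loc[sub["condition"] == cond, "count"].to_numpy()
                if vals.size < 2:
                    raise StatsError(
                        f"experiment {exp}: condition {cond} has fewer than "
                        "2 animals"
                    )
                return vals

            fam = baseline_subtract(
                counts(fam_cond), counts(BASELINE_OF[fam_cond]),
                fam_cond, BASELINE_OF[fam_cond], int(exp),
            )
            nov = baseline_subtract(
                counts(nov_cond), counts(BASELINE_OF[nov_cond]),
                nov_cond, BASELINE_OF[nov_cond], int(exp),
            )
            contrast = per_experiment_contrast(fam, nov, df_policy=self.df_policy)
            p_values.append(contrast.p)
            rows.append(
                {
                    "experiment": int(exp),
                    "delta_familiar": fam.delta_mean,
                    "sem_familiar": fam.sem,
                    "delta_novel": nov.delta_mean,
                    "sem_novel": nov.sem,
                    "estimate": contrast.estimate,
                    "sem": contrast.sem,
                    "t": contrast.t_statistic,
                    "df": contrast.df,
                    "p": contrast.p,
                }
            )
        fisher = fisher_combine(p_values)
        return FisherCombinedResults(
            model=self,
            per_experiment=pd.DataFrame(rows),
            fisher=fisher,
        )


@dataclass(frozen=True)
class FisherCombinedResults:
    """Per-experiment contrasts plus the Fisher-combined verdict."""

    model: CellCountFamiliarityModel
    per_experiment: pd.DataFrame
    fisher: FisherResult

    @property
    def p_combined(self) -> float:
        return self.fisher.p_combined

    def summary(self) -> str:
        lines = [
            f"Serotonin-positive cell-count familiarity analysis "
            f"({self.model.comparison})",
            "=" * 60,
            "per-experiment contrasts (baseline-subtracted, familiar - novel):",
        ]
        for _, r in self.per_experiment.iterrows():
            lines.append(
                f"  experiment {int(r['experiment'])}: estimate "
                f"{r['estimate']:+.3f} ± {r['sem']:.3f} cells, "
                f"t = {r['t']:.2f}, p = {r['p']:.3f}"
            )
        lines += [
            f"Fisher combination: chi2 = {self.fisher.chi2:.2f}, "
            f"df = {self.fisher.df}, combined p = {self.fisher.p_combined:.3f}",
        ]
        return "\n".join(lines)
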