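"""Statistical reporting on morphometric and fluorescence tables.

Mirrors the reporting conventions used for meristem timecourses:

* two-sided Mann-Whitney-Wilcoxon tests between genotypes within each
  timepoint (exact p for small samples, normal approximation with tie
  correction otherwise; no correction across timepoints);
* one-way ANOVA across timepoints within a genotype, followed by Tukey HSD
  pairwise comparisons summarised as a compact letter display (groups
  sharing a letter do not differ at α);
* per-experiment normalization of each measurement by the median of the
  reference genotype in that experiment;
* fold-change summaries as ratios of medians between timepoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "LetterDisplay",
    "rank_sum_test",
    "compare_genotypes",
    "compare_timepoints",
    "compact_letters",
    "normalize_by_reference",
    "fold_change",
]

#: largest per-group n for which the exact rank-sum null is enumerated
EXACT_N_MAX = 8


@dataclass
class ComparisonResult:
    """One two-group comparison."""

    grouping: str
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError("p-value out of range")


@dataclass
class LetterDisplay:
    """Compact letter display over groups with the underlying Tukey p matrix."""

    groups: list
    letters: dict  # group -> letter string, e.g. "ab"
    p_matrix: pd.DataFrame
    anova_F: float
    anova_p: float
    alpha: float = 0.05
    n_per_group: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Assert the display invariants against the p matrix."""
        for g1, g2 in itertools.combinations(self.groups, 2):
            shared = set(self.letters[g1]) & set(self.letters[g2])
            p = self.p_matrix.loc[g1, g2]
            if shared and p < self.alpha:
                raise AssertionError(
                    f"{g1} and {g2} share a letter but differ (p={p:.4g})")
            if not shared and p >= self.alpha:
                raise AssertionError(
                    f"{g1} and {g2} share no letter but do not differ (p={p:.4g})")


def rank_sum_test(x, y, alpha: float = 0.05, grouping: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact null distribution when both groups have ≤ 8 observations and the
    data are tie-free; otherwise the normal approximation with mid-ranks
    and tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(grouping, f"mann-whitney ({method})",
                            float(res.statistic), float(min(res.pvalue, 1.0)),
                            len(x), len(y), alpha)


def compare_genotypes(records: pd.DataFrame, measure: str, timepoint,
                      genotype1: str, genotype2: str,
                      alpha: float = 0.05) -> ComparisonResult:
    """Mann-Whitney comparison of two genotypes within one timepoint."""
    sel = records[records["timepoint_d"] == timepoint]
    x = sel.loc[sel["genotype"] == genotype1, measure].dropna()
    y = sel.loc[sel["genotype"] == genotype2, measure].dropna()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(
            f"empty group for {genotype1!r}/{genotype2!r} at timepoint {timepoint}")
    return rank_sum_test(x, y, alpha, grouping=f"timepoint {timepoint}")


def compact_letters(groups, p_matrix: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Insert-and-absorb compact letter display from a pairwise p matrix.

    Starts with all groups in one letter column; for every significant pair
    the columns containing both are split, then columns that are subsets of
    others are absorbed.  Guarantees: significant pairs never share a
    letter; non-significant pairs always share at least one.
    """
    groups = list(groups)
    columns: list[set] = [set(groups)]
    for g1, g2 in itertools.combinations(groups, 2):
        if p_matrix.loc[g1, g2] >= alpha:
            continue
        new_columns = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = [
            c for i, c in enumerate(new_columns)
            if c and not any(c < other or (c == other and i > j)
                             for j, other in enumerate(new_columns))
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def compare_timepoints(records: pd.DataFrame, measure: str, genotype: str,
                       alpha: float = 0.05) -> LetterDisplay:
    """One-way ANOVA across timepoints plus Tukey HSD with letters."""
    df = records[records["genotype"] == genotype][["timepoint_d", measure]].dropna()
    groups = sorted(df["timepoint_d"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 timepoints")
    samples = [df.loc[df["timepoint_d"] == g, measure].to_numpy() for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"timepoint {g} has fewer than 2 observations")
    F, p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(df[measure].to_numpy(),
                              df["timepoint_d"].to_numpy(), alpha=alpha)
    pmat = pd.DataFrame(np.ones((len(groups), len(groups))),
                        index=groups, columns=groups)
    tukey_groups = list(tukey.groupsunique)
    for (i, j), pv in zip(itertools.combinations(range(len(tukey_groups)), 2),
                          tukey.pvalues):
        gi, gj = tukey_groups[i], tukey_groups[j]
        pmat.loc[gi, gj] = pmat.loc[gj, gi] = pv
    letters = compact_letters(groups, pmat, alpha)
    disp = LetterDisplay(groups, letters, pmat, float(F), float(p), alpha,
                         {g: len(s) for g, s in zip(groups, samples)})
    disp.validate()
    return disp


def normalize_by_reference(records: pd.DataFrame, reference_genotype: str,
                           measure: str) -> pd.DataFrame:
    """Normalize a measure by the reference genotype's median per experiment.

    Returns a copy of the records with ``reference_median`` and
    ``normalized`` columns; the reference genotype therefore normalizes to
    median exactly 1 in every experiment.
    """
    out = []
    for exp, grp in records.groupby("experiment_id"):
        ref = grp.loc[grp["genotype"] == reference_genotype, measure].dropna()
        if len(ref) == 0:
            raise ValueError(f"experiment {exp!r} lacks reference genotype records")
        ref_median = float(ref.median())
        if ref_median <= 0:
            raise ValueError(f"non-positive reference median in experiment {exp!r}")
        g = grp.copy()
        g["reference_median"] = ref_median
        g["normalized"] = g[measure] / ref_median
        out.append(g)
    return pd.concat(out, ignore_index=True)


def fold_change(records: pd.DataFrame, measure: str, t0, t1,
                genotype: str | None = None) -> float:
    """Ratio of the measure's median at t1 over its median at t0."""
    df = records if genotype is None else records[records["genotype"] == genotype]
    m0 = df.loc[df["timepoint_d"] == t0, measure].dropna()
    m1 = df.loc[df["timepoint_d"] == t1, measure].dropna()
    if len(m0) == 0 or len(m1) == 0:
        raise ValueError("both timepoints must be populated")
    med0 = float(m0.median())
    if med0 == 0:
        raise ValueError("zero median at the baseline timepoint")
    return float(m1.median()) / med0
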