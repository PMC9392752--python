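"""Group-level statistical comparisons between simulated samples.

Three analyses, matching how fitted model groups are compared:

* within-group PE vs NPE contrasts (Welch t, Bonferroni over the 8 groups);
* one-way ANOVA on one index across the four age groups of a condition,
  with all six pairwise post-hoc Welch t-tests (Bonferroni family 6) when
  the ANOVA is significant;
* control vs ASC contrasts per age and index (Bonferroni over the 4
  indices within an age).

All tests are two-sided Welch (unequal variances) unless both samples are
degenerate (zero variance), in which case an exact equality check is
reported: p = 1 if the constant samples agree, p = 0 otherwise, flagged as
degenerate. Family sizes are explicit arguments so alternative correction
choices stay a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "welch_test",
    "bonferroni",
    "pe_vs_npe",
    "anova_across_ages",
    "control_vs_asc",
    "results_to_frame",
]


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def band(self) -> str:
        """The p-band convention used when reporting: ns, <0.05, <0.01, <0.001."""
        p = self.p_adjusted
        if p < 0.001:
            return "<0.001"
        if p < 0.01:
            return "<0.01"
        if p < 0.05:
            return "<0.05"
        return "ns"


def bonferroni(p_raw: float, family: int) -> float:
    return min(1.0, p_raw * family)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Welch t-test; returns (statistic, p, degenerate_flag).

    Zero variance in both samples makes the t statistic undefined; fall
    back to an exact equality check on the means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0:
        equal = a.mean() == b.mean()
        return 0.0, 1.0 if equal else 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def _result(contrast, stat, p_raw, family, alpha, degenerate) -> ComparisonResult:
    p_adj = bonferroni(p_raw, family)
    return ComparisonResult(
        contrast=contrast,
        statistic=stat,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=bool(p_adj < alpha),
        alpha=alpha,
        degenerate=degenerate,
    )


def pe_vs_npe(
    profiles: np.ndarray, label: str = "pe_vs_npe", family: int = 8, alpha: float = 0.05
) -> ComparisonResult:
    """PE vs NPE contrast within one group of per-session profiles.

    ``profiles`` is an ``(n, 4)`` array (cc, pe, npe, fms). The Bonferroni
    family defaults to the 8 simulated groups.
    """
    profiles = np.asarray(profiles, dtype=float)
    t, p, degen = welch_test(profiles[:, 1], profiles[:, 2])
    return _result(label, t, p, family, alpha, degen)


def anova_across_ages(
    groups: dict[str, np.ndarray],
    index: int,
    alpha: float = 0.05,
    posthoc_family: int = 6,
):
    """One-way ANOVA on one index across four age groups, plus post-hocs.

    Returns ``(anova_result, posthoc_list)``; post-hocs (all pairwise
    Welch t-tests, Bonferroni family 6) are run only when the ANOVA is
    significant at ``alpha``.
    """
    if len(groups) != 4:
        raise ValueError("expected exactly 4 age groups")
    samples = {k: np.asarray(v, dtype=float)[:, index] for k, v in groups.items()}
    for k, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {k} needs at least 2 sessions")
    values = list(samples.values())
    if all(v.std() == 0.0 for v in values):
        means = [v.mean() for v in values]
        equal = len(set(means)) == 1
        anova = _result("anova", 0.0, 1.0 if equal else 0.0, 1, alpha, True)
    else:
        f, p = stats.f_oneway(*values)
        anova = _result("anova", float(f), float(p), 1, alpha, False)

    posthocs: list[ComparisonResult] = []
    if anova.significant:
        names = list(samples)
        for i in range(4):
            for j in range(i + 1, 4):
                t, p, degen = welch_test(samples[names[i]], samples[names[j]])
                posthocs.append(
                    _result(f"{names[i]}_vs_{names[j]}", t, p, posthoc_family, alpha, degen)
                )
    return anova, posthocs


def control_vs_asc(
    control: np.ndarray,
    asc: np.ndarray,
    age: str,
    index: int,
    family: int = 4,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Control vs ASC contrast for one age group and one index."""
    control = np.asarray(control, dtype=float)
    asc = np.asarray(asc, dtype=float)
    t, p, degen = welch_test(control[:, index], asc[:, index])
    name = ("cc", "pe", "npe", "fms")[index]
    return _result(f"{age}_{name}_control_vs_asc", t, p, family, alpha, degen)


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Report table mirroring the banding convention (ns, <0.05, <0.01, <0.001)."""
    return pd.DataFrame(
        {
            "contrast": [r.contrast for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "band": [r.band for r in results],
        }
    )
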