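"""Group-wise trait association tests.

Two-group contrasts run the Wilcoxon rank-sum test (exact for small
samples, normal approximation with continuity correction otherwise)
alongside Student's and Welch's t-tests; multi-group contrasts use Tukey's
honest significant difference with a compact letter display.  Differences
at p <= 0.05 are flagged significant; no multiple-testing correction is
applied by default (an optional Benjamini-Hochberg column is available),
matching the per-trait alpha convention of agronomic association scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "pairwise_tests", "tukey_hsd",
           "association_report", "compact_letters"]

EXACT_WILCOXON_MAX_N = 50


@dataclass
class AssociationResult:
    trait: str
    grouping: str
    test: str
    statistic: float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)
    direction: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0,1]")


def _clean_two(values: Sequence[float], groups: Sequence[str],
               min_n: int = 3) -> tuple[np.ndarray, np.ndarray, list[str]]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise ValueError("pairwise tests need exactly two groups")
    x, y = v[g == labels[0]], v[g == labels[1]]
    if min(x.size, y.size) < min_n:
        raise ValueError(f"each group needs >= {min_n} observations")
    return x, y, labels


def pairwise_tests(values: Sequence[float], groups: Sequence[str],
                   trait: str = "trait", grouping: str = "group",
                   ) -> list[AssociationResult]:
    """Wilcoxon rank-sum, Student's t and Welch's t for a two-group contrast.

    The Wilcoxon test is exact when the combined sample size is at most 50,
    otherwise the normal approximation with continuity correction is used.
    Degenerate data (both groups constant and identical) returns p = 1 with
    a flag rather than NaN.
    """
    x, y, labels = _clean_two(values, groups)
    means = {labels[0]: float(np.mean(x)), labels[1]: float(np.mean(y))}
    direction = f"{labels[0]}>{labels[1]}" if means[labels[0]] > \
        means[labels[1]] else f"{labels[1]}>{labels[0]}"
    degenerate = np.ptp(np.concatenate([x, y])) == 0
    out = []
    if degenerate:
        for test in ("wilcoxon", "student_t", "welch_t"):
            out.append(AssociationResult(trait, grouping, test, 0.0, 1.0,
                                         means, direction="none",
                                         flags=("degenerate",)))
        return out
    method = "exact" if x.size + y.size <= EXACT_WILCOXON_MAX_N \
        else "asymptotic"
    w = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    out.append(AssociationResult(trait, grouping, "wilcoxon",
                                 float(w.statistic), float(w.pvalue), means,
                                 direction=direction))
    for name, equal_var in (("student_t", True), ("welch_t", False)):
        t = stats.ttest_ind(x, y, equal_var=equal_var)
        p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
        out.append(AssociationResult(trait, grouping, name,
                                     float(t.statistic), p, means,
                                     direction=direction,
                                     flags=("degenerate",) if
                                     np.isnan(t.pvalue) else ()))
    return out


def compact_letters(labels: Sequence[str],
                    significant: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not
    significantly different (insert-and-absorb algorithm)."""
    letters: list[set[str]] = [set(labels)]
    for a, b in significant:
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
    letters.sort(key=lambda s: sorted(list(labels).index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in labels}
    for i, s in enumerate(letters):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def tukey_hsd(values: Sequence[float], groups: Sequence[str],
              trait: str = "trait", grouping: str = "group",
              alpha: float = 0.05) -> AssociationResult:
    """Tukey HSD over k groups with a compact letter display.

    Pairwise p-values come from the studentized-range distribution; the
    letter display assigns shared letters to groups whose difference is not
    significant at ``alpha``.  Groups with zero within-group variance
    everywhere are flagged.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    labels = sorted(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    samples = [v[g == lab] for lab in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs >= 2 observations")
    flags: tuple[str, ...] = ()
    if all(np.ptp(s) == 0 for s in samples):
        flags = ("singular_variance",)
        letters = {lab: "a" for lab in labels}
        means = {lab: float(np.mean(s)) for lab, s in zip(labels, samples)}
        return AssociationResult(trait, grouping, "tukey_hsd", 0.0, 1.0,
                                 means, letters, flags=flags)
    res = stats.tukey_hsd(*samples)
    sig = set()
    min_p = 1.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            min_p = min(min_p, p)
            if p <= alpha:
                sig.add((labels[i], labels[j]))
    order = np.argsort([-np.mean(s) for s in samples])
    ordered = [labels[i] for i in order]
    letters = compact_letters(ordered, sig)
    means = {lab: float(np.mean(s)) for lab, s in zip(labels, samples)}
    return AssociationResult(trait, grouping, "tukey_hsd",
                             float(res.statistic[0, -1]), min_p, means,
                             letters, flags=flags)


def association_report(trait_table: pd.DataFrame,
                       groupings: Sequence[str],
                       alpha: float = 0.05,
                       min_group_n: int = 3,
                       bh_correct: bool = False) -> pd.DataFrame:
    """Test every numeric trait against every grouping column.

    Two-level groupings run all three pairwise tests; multi-level groupings
    run Tukey HSD.  Groups smaller than ``min_group_n`` are dropped from
    the contrast.  Returns one row per trait x grouping x test with the
    direction of effect and a significance flag at ``alpha``; with
    ``bh_correct`` a Benjamini-Hochberg adjusted p-value column is added
    (off by default).
    """
    import warnings

    if not groupings:
        raise ValueError("need at least one grouping column")
    rows = []
    traits = [c for c in trait_table.columns
              if c not in groupings and
              pd.api.types.is_numeric_dtype(trait_table[c])]
    for grouping in groupings:
        g = trait_table[grouping].astype(str)
        sizes = g.value_counts()
        keep_groups = sizes[sizes >= min_group_n].index
        mask = g.isin(keep_groups)
        if len(keep_groups) < 2:
            warnings.warn(f"grouping {grouping!r} has a single usable group;"
                          " skipped")
            continue
        for trait in traits:
            v = trait_table.loc[mask, trait]
            gg = g[mask]
            try:
                if len(keep_groups) == 2:
                    results = pairwise_tests(v, gg, trait, grouping)
                else:
                    results = [tukey_hsd(v, gg, trait, grouping, alpha)]
            except ValueError:
                continue
            for r in results:
                rows.append({
                    "trait": r.trait, "grouping": r.grouping, "test": r.test,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "significant": r.p_value <= alpha,
                    "direction": r.direction,
                    "group_means": ";".join(f"{k}={v:.4g}"
                                            for k, v in r.group_means.items()),
                    "letters": ";".join(f"{k}={v}"
                                        for k, v in r.letters.items()),
                    "flags": ",".join(r.flags),
                })
    report = pd.DataFrame(rows)
    if bh_correct and not report.empty:
        from statsmodels.stats.multitest import multipletests
        report["p_bh"] = multipletests(report["p_value"],
                                       method="fdr_bh")[1]
        report["significant_bh"] = report["p_bh"] <= alpha
    return report
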