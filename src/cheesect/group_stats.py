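"""Group comparison of wheel summaries: one-way ANOVA with Tukey post hoc.

Wheels are grouped (typically young vs mature by age, or by batch) and each
report metric is compared across groups by classical one-way ANOVA
(F = MSB/MSW against the F distribution) followed by Tukey's HSD for
pairwise contrasts at a fixed α (default 0.05).  Groups that do not differ
significantly share a superscript letter in the compact letter display, as
in the usual "mean ± sd^a" report tables.  No correction is applied across
metrics; each metric is tested on its own.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .morphometry import WheelSummary

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "GroupComparison",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "compare_stages",
    "format_comparison_table",
    "COMPARISON_METRICS",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: WheelSummary fields compared between groups, in report order.
COMPARISON_METRICS = [
    "n_eyes",
    "mean_eye_volume_cm3",
    "eye_volume_p10_cm3",
    "eye_volume_p90_cm3",
    "total_eye_volume_cm3",
    "wheel_volume_cm3",
    "ratio",
    "eye_percent",
    "mean_roundness",
    "roundness_p10",
    "roundness_p90",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float  # mean(a) − mean(b)
    p_adjusted: float
    significant: bool


@dataclass
class GroupComparison:
    metric: str
    group_labels: list[str]
    group_means: list[float]
    group_sds: list[float]
    group_ns: list[int]
    anova: AnovaResult
    tukey: list[PairwiseComparison]
    letters: dict[str, str]
    alpha: float = DEFAULT_ALPHA


def _validate_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    return arrays


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = (SSB/df1) / (SSW/df2) with df1 = k−1, df2 = N−k; the p value comes
    from the upper tail of the F distribution.  All-identical data make F
    undefined (0/0); a degenerate result with F = nan, p = nan and a warning
    is returned rather than an exception.
    """
    arrays = _validate_groups(groups)
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df1, df2 = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            warnings.warn(
                "all data identical: F is undefined (0/0)", RuntimeWarning
            )
            return AnovaResult(np.nan, df1, df2, np.nan, degenerate=True)
        return AnovaResult(np.inf, df1, df2, 0.0, degenerate=True)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult(float(f), df1, df2, p)


def tukey_hsd(
    groups, alpha: float = DEFAULT_ALPHA, names: list[str] | None = None
) -> tuple[list[PairwiseComparison], dict[str, str]]:
    """Tukey HSD pairwise comparisons plus a compact letter display.

    Adjusted p values come from the studentized-range distribution with the
    pooled within-group variance.  With two groups the studentized range
    satisfies q = √2·|t|, so the adjusted p equals the pooled two-sided
    t-test p.
    """
    arrays = _validate_groups(groups)
    names = names or [str(i) for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names length must match number of groups")

    res = sps.tukey_hsd(*arrays)
    pairs: list[PairwiseComparison] = []
    sig_pairs: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(len(arrays)), 2):
        p_adj = float(res.pvalue[i, j])
        diff = float(arrays[i].mean() - arrays[j].mean())
        significant = p_adj < alpha
        pairs.append(PairwiseComparison(names[i], names[j], diff, p_adj, significant))
        if significant:
            sig_pairs.add((names[i], names[j]))
    letters = compact_letter_display(names, sig_pairs)
    return pairs, letters


def compact_letter_display(
    names: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign shared letters to groups that are *not* significantly different.

    Letter columns are the maximal cliques of the non-difference graph
    (nodes = groups, edges = pairs not significantly different), found by
    Bron–Kerbosch.  Every non-different pair then shares at least one letter
    and no significant pair shares any; group counts here are small (a
    handful of ages or batches), so clique enumeration is trivial.
    """
    sig = {frozenset(p) for p in significant_pairs}
    adj = {
        g: {h for h in names if h != g and frozenset((g, h)) not in sig}
        for g in names
    }

    cliques: list[set[str]] = []

    def bron_kerbosch(r: set, p: set, x: set):
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(names), set())
    # order columns by first appearance of their groups for stable lettering
    unique = sorted(cliques, key=lambda c: sorted(names.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, col in zip(alphabet, unique):
        for g in names:
            if g in col:
                out[g] += letter
    return out


def _group_key(summary: WheelSummary, group_by: str):
    return getattr(summary, group_by)


def compare_stages(
    summaries: list[WheelSummary],
    group_by: str = "age_days",
    alpha: float = DEFAULT_ALPHA,
    metrics: list[str] | None = None,
) -> list[GroupComparison]:
    """Compare wheel summaries between groups for every report metric.

    Wheels with an absent (None) value for a metric are dropped from that
    metric's comparison; if a whole group has no values the metric is
    skipped with a warning.
    """
    metrics = metrics or COMPARISON_METRICS
    keys = sorted({_group_key(s, group_by) for s in summaries})
    if len(keys) < 2:
        raise ValueError(
            f"grouping by {group_by!r} yields {len(keys)} group(s); need >= 2"
        )
    grouped = {k: [s for s in summaries if _group_key(s, group_by) == k] for k in keys}
    names = [str(k) for k in keys]

    results: list[GroupComparison] = []
    for metric in metrics:
        values = []
        ok = True
        for k in keys:
            vals = [
                float(getattr(s, metric))
                for s in grouped[k]
                if getattr(s, metric) is not None
            ]
            if len(vals) < 2:
                logger.warning(
                    "metric %s: group %s has %d usable value(s); metric skipped",
                    metric, k, len(vals),
                )
                ok = False
                break
            values.append(np.asarray(vals))
        if not ok:
            continue
        anova = one_way_anova(values)
        if anova.degenerate:
            # zero within-group variance: pairs differ iff their means do
            pairs, sig = [], set()
            for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
                diff = float(values[i].mean() - values[j].mean())
                significant = diff != 0.0
                pairs.append(
                    PairwiseComparison(a, b, diff, 0.0 if significant else 1.0,
                                       significant)
                )
                if significant:
                    sig.add((a, b))
            letters = compact_letter_display(names, sig)
        else:
            pairs, letters = tukey_hsd(values, alpha=alpha, names=names)
        results.append(
            GroupComparison(
                metric=metric,
                group_labels=names,
                group_means=[float(v.mean()) for v in values],
                group_sds=[float(v.std(ddof=1)) for v in values],
                group_ns=[int(v.size) for v in values],
                anova=anova,
                tukey=pairs,
                letters=letters,
                alpha=alpha,
            )
        )
    return results


def format_comparison_table(comparisons: list[GroupComparison]) -> str:
    """Render comparisons as a text table with 'mean ± sd^letter' cells."""
    if not comparisons:
        return "(no metrics compared)"
    names = comparisons[0].group_labels
    header = ["Characteristic"] + list(names)
    rows = [header]
    for comp in comparisons:
        row = [comp.metric]
        for name, mean, sd in zip(comp.group_labels, comp.group_means, comp.group_sds):
            row.append(f"{mean:.3f} ± {sd:.3f}^{comp.letters[name]}")
        rows.append(row)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    ]
    lines.insert(1, "-" * len(lines[0]))
    lines.append(
        f"Groups sharing a letter do not differ at alpha = {comparisons[0].alpha}; "
        "no correction across metrics."
    )
    return "\n".join(lines)
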