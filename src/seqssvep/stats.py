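"""Population statistics: paired exact Wilcoxon tests and two-way repeated
measures ANOVA with Bonferroni-corrected pairwise post-hocs.

Mice are the unit of inference: neuron- or channel-level quantities are pooled
(averaged) within each mouse before any test.  With n = 6 mice the smallest
attainable two-sided exact signed-rank p is 2/2^6 = 0.03125, so exact null
distributions (not the normal approximation) are used throughout small
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonTable",
    "WilcoxonResult",
    "make_comparison_table",
    "paired_wilcoxon",
    "bonferroni",
    "rm_anova_two_way",
]


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_pairs: int
    n_zero_dropped: int
    all_zero: bool = False


class ComparisonTable:
    """Tidy (mouse, condition, metric, value) table for paired comparisons.

    ``moving_bar_mean`` averages the 12 bar orientations and
    ``sequential_mean`` the 12 sequential stimuli, so each mouse contributes
    one value per condition and metric.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"mouse_id", "condition", "metric", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"comparison table missing columns {sorted(missing)}")
        dup = frame.duplicated(["mouse_id", "condition", "metric"])
        if dup.any():
            raise ValueError("multiple values for one (mouse, condition, metric)")
        self.frame = frame.reset_index(drop=True)

    def paired(self, cond_a: str, cond_b: str, metric: str):
        sub = self.frame[self.frame["metric"] == metric]
        wide = sub.pivot(index="mouse_id", columns="condition", values="value")
        for c in (cond_a, cond_b):
            if c not in wide.columns:
                raise ValueError(f"condition {c!r} absent for metric {metric!r}")
        wide = wide[[cond_a, cond_b]].dropna()
        return wide[cond_a].to_numpy(), wide[cond_b].to_numpy()


def make_comparison_table(rows: list[dict]) -> ComparisonTable:
    return ComparisonTable(pd.DataFrame(rows))


def paired_wilcoxon(
    table: ComparisonTable,
    cond_a: str,
    cond_b: str,
    metric: str,
    min_pairs: int = 5,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test, exact for n <= 25.

    Zero differences are dropped before ranking (Wilcoxon's original
    prescription); with every difference zero the test is undefined and the
    result is flagged.  For n = 6 pairs all of one sign the exact two-sided p
    is 2/64 = 0.03125.
    """
    a, b = table.paired(cond_a, cond_b, metric)
    if a.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} paired observations, got {a.size}")
    d = a - b
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    if not nonzero.any():
        return WilcoxonResult(np.nan, np.nan, 0, n_dropped, all_zero=True)
    n = int(nonzero.sum())
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d[nonzero], zero_method="wilcox", alternative="two-sided",
                       method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n, n_dropped)


def bonferroni(p: float | np.ndarray, n_comparisons: int):
    """Bonferroni correction: multiply by the comparison count, cap at 1."""
    return np.minimum(np.asarray(p, dtype=float) * n_comparisons, 1.0)


def rm_anova_two_way(
    table: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("waveform_class", "repeat_frequency"),
    subject: str = "mouse_id",
    posthoc_factor: str | None = None,
):
    """Two-way repeated measures ANOVA with Bonferroni pairwise post-hocs.

    Expects a balanced long table with one aggregate per subject per cell of
    the two within factors.  Returns ``(anova, posthoc)`` DataFrames; the
    post-hoc compares levels of ``posthoc_factor`` (default: the second
    within factor) with Bonferroni-adjusted p values.  The degenerate
    all-cells-equal design (zero effect and error sums of squares) is reported
    as F = 0, p = 1.
    """
    import pingouin as pg  # deferred: pingouin import is slow

    cells = table.groupby([subject, *within], observed=True).size()
    expected = set(
        (s, a, b)
        for s in table[subject].unique()
        for a in table[within[0]].unique()
        for b in table[within[1]].unique()
    )
    missing = expected - set(cells.index)
    if missing or (cells != 1).any():
        bad = sorted(missing)[:3] if missing else cells[cells != 1].index[:3].tolist()
        raise ValueError(f"design not balanced; offending (subject, cell): {bad}")

    anova = pg.rm_anova(data=table, dv=dv, within=list(within), subject=subject,
                        detailed=True)
    anova = anova.rename(columns={"p_unc": "p-unc"})
    # degenerate zero-variance designs: define F = 0, p = 1
    if "SS" in anova.columns:
        degen = (anova["SS"].fillna(0) == 0) & anova["F"].isna()
        anova.loc[degen, "F"] = 0.0
        anova.loc[degen, "p-unc"] = 1.0

    factor = posthoc_factor or within[1]
    posthoc = pg.pairwise_tests(data=table, dv=dv, within=list(within),
                                subject=subject, padjust="bonf")
    posthoc = posthoc.rename(columns={"p_unc": "p-unc", "p_corr": "p-corr"})
    posthoc = posthoc[posthoc["Contrast"].str.contains(factor)]
    return anova, posthoc
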