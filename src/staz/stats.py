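"""Group summaries and vs-control hypothesis tests.

The assay reports per-treatment mean ± SEM (larva = statistical unit,
batch count reported alongside) and compares treatments to the vehicle
control with either

* Kruskal–Wallis followed by Dunn's post-test (rank-based, the default
  for the steatosis score), or
* one-way ANOVA followed by Dunnett's many-to-one comparisons, or
* two-way ANOVA with Bonferroni-adjusted cell contrasts (factorial
  designs, e.g. treatment x inhibitor).

Dunn's z statistics are computed from the pooled tie-corrected ranks and
Bonferroni-adjusted over the control comparisons (the "compare to
control" convention used by common stats packages); an all-pairs mode is
available. Dunnett adjustment uses the multivariate-t distribution via
scipy. Adjusted p-values are clipped to be no smaller than the raw ones.

Significance stars: ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001, else
``ns``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, MissingControlError, UnbalancedDesignError


@dataclass(frozen=True)
class GroupSummary:
    treatment: str
    concentration: str | None
    n_larvae: int
    n_batches: int
    mean: float
    sem: float  # NaN when n_larvae == 1


@dataclass(frozen=True)
class Comparison:
    group: str
    statistic: float
    p_raw: float
    p_adj: float
    stars: str


@dataclass(frozen=True)
class TestResult:
    method: str
    global_stat: float
    global_p: float
    comparisons: tuple[Comparison, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "comparison": "global",
                "statistic": self.global_stat,
                "raw_p": self.global_p,
                "adj_p": np.nan,
                "stars": "",
            }
        ]
        for c in self.comparisons:
            rows.append(
                {
                    "method": self.method,
                    "comparison": c.group,
                    "statistic": c.statistic,
                    "raw_p": c.p_raw,
                    "adj_p": c.p_adj,
                    "stars": c.stars,
                }
            )
        return pd.DataFrame(rows)


def star_code(p: float) -> str:
    """Map an adjusted p-value to the assay's significance stars."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(
    values_by_group: Mapping[str, Sequence[tuple[float, str]]],
    concentrations: Mapping[str, str | None] | None = None,
) -> list[GroupSummary]:
    """Per-group mean ± SEM with larva and distinct-batch counts.

    ``values_by_group`` maps treatment -> [(larva value, batch_id), ...].
    SEM is the sample standard deviation over sqrt(n); it is NaN for
    singleton groups.
    """
    out = []
    for treatment in values_by_group:
        pairs = list(values_by_group[treatment])
        if not pairs:
            raise ValueError(f"group {treatment!r} is empty")
        vals = np.array([v for v, _ in pairs], dtype=float)
        batches = {b for _, b in pairs}
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        out.append(
            GroupSummary(
                treatment=treatment,
                concentration=(concentrations or {}).get(treatment),
                n_larvae=len(vals),
                n_batches=len(batches),
                mean=float(vals.mean()),
                sem=sem,
            )
        )
    return out


def _check_groups(values_by_group: Mapping[str, Sequence[float]], control_label: str):
    if control_label not in values_by_group:
        raise MissingControlError(f"control group {control_label!r} absent")
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")


def kruskal_dunn(
    values_by_group: Mapping[str, Sequence[float]],
    control_label: str = "DMSO",
    all_pairs: bool = False,
) -> TestResult:
    """Kruskal–Wallis H followed by Dunn's z tests vs the control group.

    H uses the tie correction; Dunn's z is computed on the pooled
    mid-ranks with the same tie term, Bonferroni-adjusted over the
    comparisons performed (treated-vs-control by default).
    """
    _check_groups(values_by_group, control_label)
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        comps = _degenerate_comparisons(groups, control_label, all_pairs)
        return TestResult("kruskal_dunn", 0.0, 1.0, comps)
    h_stat, h_p = sps.kruskal(*groups.values())

    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_rank = {}
    start = 0
    for g, vals in groups.items():
        mean_rank[g] = float(ranks[start : start + len(vals)].mean())
        start += len(vals)

    if all_pairs:
        pairs = list(combinations(groups, 2))
    else:
        pairs = [(g, control_label) for g in groups if g != control_label]
    k = len(pairs)
    comps = []
    for a, b in pairs:
        denom = np.sqrt(var_factor * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / denom if denom > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * k)
        label = a if b == control_label else f"{a} vs {b}"
        comps.append(Comparison(label, float(z), p_raw, max(p_adj, p_raw), star_code(p_adj)))
    return TestResult("kruskal_dunn", float(h_stat), float(h_p), tuple(comps))


def _degenerate_comparisons(groups, control_label, all_pairs):
    if all_pairs:
        pairs = list(combinations(groups, 2))
    else:
        pairs = [(g, control_label) for g in groups if g != control_label]
    return tuple(
        Comparison(a if b == control_label else f"{a} vs {b}", 0.0, 1.0, 1.0, "ns")
        for a, b in pairs
    )


def anova_dunnett(
    values_by_group: Mapping[str, Sequence[float]],
    control_label: str = "DMSO",
) -> TestResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    Dunnett-adjusted p-values come from the multivariate-t distribution
    (scipy implementation, deterministic quadrature seed); raw p-values
    are the unadjusted two-sided t probabilities at the pooled residual
    degrees of freedom.
    """
    _check_groups(values_by_group, control_label)
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    within_ss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    if within_ss == 0.0:
        raise DegenerateVarianceError("zero within-group variance in every group")

    grand = np.concatenate(list(groups.values())).mean()
    between_ss = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    if between_ss == 0.0:
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = sps.f_oneway(*groups.values())

    control = groups[control_label]
    treated_labels = [g for g in groups if g != control_label]
    res = sps.dunnett(
        *[groups[g] for g in treated_labels],
        control=control,
        rng=np.random.default_rng(0),
    )
    df_resid = sum(len(v) for v in groups.values()) - len(groups)
    comps = []
    for i, g in enumerate(treated_labels):
        t = float(res.statistic[i])
        p_raw = float(2.0 * sps.t.sf(abs(t), df_resid))
        p_adj = max(float(res.pvalue[i]), p_raw)
        comps.append(Comparison(g, t, p_raw, min(p_adj, 1.0), star_code(p_adj)))
    return TestResult("anova_dunnett", float(f_stat), float(f_p), tuple(comps))


def two_way_anova_bonferroni(
    values: Sequence[tuple[float, str, str]],
    comparisons: Sequence[tuple[tuple[str, str], tuple[str, str]]] = (),
) -> TestResult:
    """Two-factor ANOVA with Bonferroni-adjusted cell contrasts.

    ``values`` are (value, factor A level, factor B level) triples over a
    full two-factor layout (every A x B cell populated). Main effects and
    the interaction are tested with the standard two-way linear model
    (type-II sums of squares); the listed cell-pair contrasts are t tests
    on the pooled residual variance, Bonferroni-adjusted over the list.
    The reported global statistic/p is the interaction term.
    """
    df = pd.DataFrame(values, columns=["value", "A", "B"])
    levels_a = sorted(df["A"].unique())
    levels_b = sorted(df["B"].unique())
    cell_groups = df.groupby(["A", "B"])["value"]
    cells = {k: v.to_numpy(dtype=float) for k, v in cell_groups}
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in cells:
                raise UnbalancedDesignError(f"empty cell ({a}, {b})")

    n = len(df)
    n_cells = len(cells)
    resid_ss = sum(float(((v - v.mean()) ** 2).sum()) for v in cells.values())
    df_resid = n - n_cells
    cell_means_ss = sum(
        len(v) * (v.mean() - df["value"].mean()) ** 2 for v in cells.values()
    )

    if cell_means_ss == 0.0 and resid_ss == 0.0:
        # constant response: every effect is exactly null
        rows = {t: (0.0, 1.0) for t in ("A", "B", "A:B")}
    elif resid_ss == 0.0:
        raise DegenerateVarianceError("zero residual variance with non-constant cells")
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        rows = {
            "A": (float(table.loc["C(A)", "F"]), float(table.loc["C(A)", "PR(>F)"])),
            "B": (float(table.loc["C(B)", "F"]), float(table.loc["C(B)", "PR(>F)"])),
            "A:B": (
                float(table.loc["C(A):C(B)", "F"]),
                float(table.loc["C(A):C(B)", "PR(>F)"]),
            ),
        }
        # an exactly-null effect can come out as a tiny negative/NaN F
        rows = {
            k: ((0.0, 1.0) if not np.isfinite(f) else (max(f, 0.0), p))
            for k, (f, p) in rows.items()
        }

    mse = resid_ss / df_resid if df_resid > 0 else float("nan")
    comps = []
    k = len(comparisons)
    for (a1, b1), (a2, b2) in comparisons:
        for cell in ((a1, b1), (a2, b2)):
            if cell not in cells:
                raise UnbalancedDesignError(f"comparison references empty cell {cell}")
        v1, v2 = cells[(a1, b1)], cells[(a2, b2)]
        diff = v1.mean() - v2.mean()
        if mse > 0:
            se = np.sqrt(mse * (1.0 / len(v1) + 1.0 / len(v2)))
            t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df_resid))
        else:  # no residual noise: identical means are null, distinct are certain
            t = 0.0 if diff == 0 else float("inf")
            p_raw = 1.0 if diff == 0 else 0.0
        p_adj = min(1.0, p_raw * k)
        comps.append(
            Comparison(
                f"({a1},{b1}) vs ({a2},{b2})",
                float(t),
                p_raw,
                max(p_adj, p_raw),
                star_code(p_adj),
            )
        )
    stat, p = rows["A:B"]
    result = TestResult("two_way_anova_bonferroni", stat, p, tuple(comps))
    # stash the full effect table for callers that want it
    object.__setattr__(result, "effects", rows)
    return result
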