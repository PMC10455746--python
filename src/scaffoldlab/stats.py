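"""Group statistics and normalization arithmetic for scaffold experiments.

Implements the comparisons used across the study: unpaired (Welch) t-tests,
one-way ANOVA with Tukey–Kramer honestly-significant-difference pairwise
tests (unequal group sizes supported), two-way ANOVA with Šídák-adjusted
pairwise contrasts, qPCR housekeeping-gene normalization with fold
induction, and fluorescence normalization to nuclear staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "QpcrRecord",
    "FluorescenceRecord",
    "TTestResult",
    "AnovaResult",
    "welch_t_test",
    "one_way_anova_tukey",
    "two_way_anova_sidak",
    "sidak_adjust",
    "qpcr_normalize",
    "normalize_fluorescence",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupTable:
    """Measurements with a primary grouping factor and an optional second factor."""

    values: np.ndarray
    group: np.ndarray
    factor2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        group = np.asarray(self.group)
        if values.size != group.size:
            raise ValueError("values and group labels must have equal lengths")
        if self.factor2 is not None:
            factor2 = np.asarray(self.factor2)
            if factor2.size != values.size:
                raise ValueError("factor2 must match values length")
            object.__setattr__(self, "factor2", factor2)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group", group)

    def groups(self) -> dict[str, np.ndarray]:
        return {str(g): self.values[self.group == g] for g in pd.unique(self.group)}


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: transcript copies plus the GAPDH reference."""

    gene: str
    copies: float
    gapdh_copies: float
    condition: str  # "CO" (control) or "OB" (osteogenic)
    donor: str

    def __post_init__(self) -> None:
        if not self.gapdh_copies > 0:
            raise ValueError("gapdh_copies must be > 0")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass(frozen=True)
class FluorescenceRecord:
    signal_intensity: float  # a.u.
    nuclear_intensity: float  # a.u.
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.nuclear_intensity > 0:
            raise ValueError("nuclear_intensity must be > 0")
        if self.signal_intensity < 0:
            raise ValueError("signal_intensity must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False  # zero variance in both groups

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: float
    df_within: float
    p: float
    degenerate: bool = False


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float], pooled: bool = False
) -> TTestResult:
    """Two-sided unpaired t-test, Welch by default (pooled variance by flag).

    Degenerate case (zero variance in both groups): equal means report
    t = 0, p = 1 with a flag; unequal means with zero variance report
    t = ±inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(
            t=float(np.sign(a.mean() - b.mean()) * np.inf), df=df, p=0.0, degenerate=True
        )
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def one_way_anova_tukey(table: GroupTable) -> tuple[AnovaResult, pd.DataFrame]:
    """One-way ANOVA with Tukey–Kramer HSD pairwise adjusted p-values.

    The Kramer generalization supports unequal group sizes.  Returns the
    ANOVA record and a tidy pairwise table (group_a, group_b, difference,
    p_adj, stars).
    """
    groups = table.groups()
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    arrays = list(groups.values())
    names = list(groups.keys())
    n_total = sum(a.size for a in arrays)
    df_between = float(len(arrays) - 1)
    df_within = float(n_total - len(arrays))

    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        if ss_between == 0:
            anova = AnovaResult(F=0.0, df_between=df_between, df_within=df_within,
                                p=1.0, degenerate=True)
        else:
            anova = AnovaResult(F=float("inf"), df_between=df_between,
                                df_within=df_within, p=0.0, degenerate=True)
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(F, df_between, df_within))
        anova = AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)

    if ss_within == 0:
        # HSD undefined without within-group variance; report trivial p's
        p_pair = {
            (i, j): 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
            for i in range(len(arrays)) for j in range(i + 1, len(arrays))
        }
    else:
        hsd = sps.tukey_hsd(*arrays)
        p_pair = {
            (i, j): float(hsd.pvalue[i, j])
            for i in range(len(arrays)) for j in range(i + 1, len(arrays))
        }
    rows = [
        {
            "group_a": names[i],
            "group_b": names[j],
            "difference": float(arrays[i].mean() - arrays[j].mean()),
            "p_adj": p_pair[(i, j)],
            "stars": significance_stars(p_pair[(i, j)]),
        }
        for i, j in sorted(p_pair)
    ]
    return anova, pd.DataFrame(rows)


def sidak_adjust(p: float, m: int) -> float:
    """Šídák correction for m planned contrasts: p_adj = 1 − (1 − p)^m."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def two_way_anova_sidak(table: GroupTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (main effects + interaction) with Šídák pairwise contrasts.

    Requires a complete two-factor layout with every cell n >= 2 (no
    imputation).  The planned contrasts compare the two (or more) levels of
    the primary factor within each level of the second factor, by Welch
    t-tests, Šídák-adjusted over the number of contrasts.

    Returns ``(anova_table, pairwise_table)``.
    """
    if table.factor2 is None:
        raise ValueError("two-way ANOVA requires factor2")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"value": table.values, "g1": table.group.astype(str), "g2": table.factor2.astype(str)}
    )
    cells = df.groupby(["g1", "g2"], sort=True).size()
    levels1 = sorted(df["g1"].unique())
    levels2 = sorted(df["g2"].unique())
    for l1 in levels1:
        for l2 in levels2:
            n = cells.get((l1, l2), 0)
            if n == 0:
                raise ValueError(f"empty cell ({l1}, {l2}); complete layout required")
            if n < 2:
                raise ValueError(f"cell ({l1}, {l2}) has n < 2")

    model = smf.ols("value ~ C(g1) * C(g2)", data=df).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)

    contrasts = []
    for l2 in levels2:
        for i in range(len(levels1)):
            for j in range(i + 1, len(levels1)):
                a = df.loc[(df.g1 == levels1[i]) & (df.g2 == l2), "value"].to_numpy()
                b = df.loc[(df.g1 == levels1[j]) & (df.g2 == l2), "value"].to_numpy()
                res = welch_t_test(a, b)
                contrasts.append(
                    {"factor2_level": l2, "group_a": levels1[i], "group_b": levels1[j],
                     "t": res.t, "p_raw": res.p}
                )
    m = len(contrasts)
    for c in contrasts:
        c["p_adj"] = sidak_adjust(c["p_raw"], m)
        c["stars"] = significance_stars(c["p_adj"])
    return anova_table, pd.DataFrame(contrasts)


def qpcr_normalize(records: Sequence[QpcrRecord], mean_wise: bool = False) -> pd.DataFrame:
    """GAPDH-normalized expression and fold induction vs. matched controls.

    ``normalized = copies / gapdh_copies``; fold induction is
    ``normalized_OB / normalized_CO`` per (gene, donor).  With
    ``mean_wise=True`` the OB values are instead related to the mean
    normalized CO value per gene.  A missing or zero control raises,
    naming the (gene, donor) pair.
    """
    rows = [
        {"gene": r.gene, "donor": r.donor, "condition": r.condition,
         "normalized": r.copies / r.gapdh_copies}
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(fold=[])
    out = []
    co = df[df.condition == "CO"]
    for (gene, donor), grp in df[df.condition == "OB"].groupby(["gene", "donor"]):
        if mean_wise:
            ref = co.loc[co.gene == gene, "normalized"]
            key = f"gene {gene!r}"
        else:
            ref = co.loc[(co.gene == gene) & (co.donor == donor), "normalized"]
            key = f"(gene {gene!r}, donor {donor!r})"
        if ref.empty:
            raise ValueError(f"no matched CO control for {key}")
        ref_val = float(ref.mean())
        if ref_val == 0:
            raise ZeroDivisionError(f"zero CO control for {key}; fold undefined")
        for _, r in grp.iterrows():
            out.append(
                {"gene": gene, "donor": donor, "normalized": r["normalized"],
                 "fold": r["normalized"] / ref_val}
            )
    return pd.DataFrame(out)


def normalize_fluorescence(record: FluorescenceRecord) -> float:
    """Signal intensity normalized to the nuclear-staining intensity."""
    return record.signal_intensity / record.nuclear_intensity


def significance_stars(p: float) -> str:
    """Figure-caption star convention: p < 0.05 / 0.01 / 0.001 / 0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
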