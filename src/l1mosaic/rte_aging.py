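"""Temporal ("aging") categorization of retrotransposable elements and
set-overlap enrichment.

The input is a set of differential-expression tables, one per age
comparison, for non-transgenic animals: 15 months versus each earlier
age (1.5, 3, 6, 10 months). Every comparison is expressed with the
15-month time point in the numerator, so a positive log2 fold-change
(``UP``) means higher expression in old animals. Each RTE's four
significance calls form a pattern that is mapped onto one of five
mutually exclusive temporal categories:

``STRONG_AGE``
    up-regulated with age in at least 3 of the 4 comparisons, and not
    down at 1.5 months.
``MILD_AGE``
    up in at least one comparison and never down.
``PEAK_1P5``
    down at 1.5 months (i.e. higher in the youngest animals) but not at
    3 months.
``EARLY_EXPR``
    down at both 1.5 and 3 months, recovered by 6 months.
``STRONG_ANTI_AGE``
    down at 1.5, 3 and 6 months.

The rules overlap as stated, so they are evaluated most-specific-first
— (i) STRONG_AGE, (v) STRONG_ANTI_AGE, (iv) EARLY_EXPR, (iii) PEAK_1P5,
(ii) MILD_AGE — which makes the categories a partition.

A separate table (transgenic hTDP-43-WT at 15 months versus
non-transgenic) defines the "RTEs associated with neurodegeneration"
set: significantly up-regulated RTEs in that comparison. Overlap
between that set and each temporal category is scored with Fisher's
exact test and the sample odds ratio, BH-adjusted across the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "Call",
    "Category",
    "AGE_COMPARISONS",
    "DE_COLUMNS",
    "SignificancePattern",
    "derive_pattern",
    "classify_category",
    "classify_features",
    "neurodegeneration_set",
    "count_significant",
    "fisher_enrichment",
    "enrich_categories",
    "EnrichmentResult",
    "bh_adjust",
    "read_de_table",
    "write_de_table",
    "heatmap_matrix",
]

#: Earlier ages (months) each compared against the 15-month reference,
#: in fixed anamnestic order.
AGE_COMPARISONS: tuple[float, ...] = (1.5, 3.0, 6.0, 10.0)

#: Required columns of a differential-expression table.
DE_COLUMNS = ("feature_id", "feature_class", "log2fc", "pvalue", "padj")


class Call(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"


class Category(str, Enum):
    STRONG_AGE = "strongly_age_dependent"
    MILD_AGE = "mildly_age_dependent"
    PEAK_1P5 = "peak_1p5_month"
    EARLY_EXPR = "early_expressors"
    STRONG_ANTI_AGE = "strongly_anti_age_dependent"
    NONE = "none"


@dataclass(frozen=True)
class SignificancePattern:
    """Four significance calls, ordered by comparison age (1.5, 3, 6, 10
    months vs the 15-month reference), plus the alpha used."""

    calls: tuple[Call, Call, Call, Call]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.calls) != len(AGE_COMPARISONS):
            raise ValueError(f"expected {len(AGE_COMPARISONS)} calls, got {len(self.calls)}")


def significance_call(log2fc: float, padj: float, alpha: float) -> Call:
    if padj < alpha:
        if log2fc > 0:
            return Call.UP
        if log2fc < 0:
            return Call.DOWN
    return Call.NS


def derive_pattern(
    rows: Mapping[float, tuple[float, float]],
    alpha: float = 0.05,
    feature_id: str = "?",
) -> SignificancePattern:
    """Build a feature's significance pattern from its four comparisons.

    ``rows`` maps comparison age -> (log2fc, padj). A missing comparison
    is an error naming the feature and the comparison.
    """
    calls = []
    for age in AGE_COMPARISONS:
        if age not in rows:
            raise KeyError(
                f"feature {feature_id!r}: missing comparison for age {age} vs 15 months"
            )
        log2fc, padj = rows[age]
        calls.append(significance_call(log2fc, padj, alpha))
    return SignificancePattern(tuple(calls), alpha)


def classify_category(pattern: SignificancePattern | Sequence[Call]) -> Category:
    """Map a 4-call significance pattern onto one of the five temporal
    categories (or NONE), most-specific rule first."""
    calls = pattern.calls if isinstance(pattern, SignificancePattern) else tuple(pattern)
    p15, p3, p6, p10 = calls
    n_up = sum(c is Call.UP for c in calls)
    any_down = any(c is Call.DOWN for c in calls)
    if n_up >= 3 and p15 is not Call.DOWN:
        return Category.STRONG_AGE
    if p15 is Call.DOWN and p3 is Call.DOWN and p6 is Call.DOWN:
        return Category.STRONG_ANTI_AGE
    if p15 is Call.DOWN and p3 is Call.DOWN and p6 is not Call.DOWN and p10 is not Call.DOWN:
        return Category.EARLY_EXPR
    if p15 is Call.DOWN and p3 is not Call.DOWN:
        return Category.PEAK_1P5
    if n_up >= 1 and not any_down:
        return Category.MILD_AGE
    return Category.NONE


def classify_features(
    tables: Mapping[float, pd.DataFrame],
    alpha: float = 0.05,
    feature_class: str | None = "RTE",
) -> pd.Series:
    """Classify every feature found in the four aging-comparison tables.

    ``tables`` maps comparison age -> DE table (columns ``DE_COLUMNS``).
    Returns a Series feature_id -> Category. Only rows of
    ``feature_class`` are used unless it is None.
    """
    missing = [a for a in AGE_COMPARISONS if a not in tables]
    if missing:
        raise KeyError(f"missing aging comparisons for ages {missing}")
    frames = {}
    for age in AGE_COMPARISONS:
        t = _validated(tables[age])
        if feature_class is not None:
            t = t[t["feature_class"] == feature_class]
        frames[age] = t.set_index("feature_id")[["log2fc", "padj"]]
    ids = frames[AGE_COMPARISONS[0]].index
    for age in AGE_COMPARISONS[1:]:
        if not ids.equals(frames[age].index):
            extra = set(ids).symmetric_difference(frames[age].index)
            sample = sorted(extra)[:5]
            raise ValueError(
                f"feature sets differ between comparisons (e.g. {sample}); "
                "every feature must appear in all four aging tables"
            )
    # vectorized call derivation: one (features x ages) matrix per statistic
    lfc = np.column_stack([frames[a]["log2fc"].to_numpy() for a in AGE_COMPARISONS])
    padj = np.column_stack([frames[a]["padj"].to_numpy() for a in AGE_COMPARISONS])
    up = (padj < alpha) & (lfc > 0)
    down = (padj < alpha) & (lfc < 0)
    cats = np.empty(len(ids), dtype=object)
    n_up = up.sum(axis=1)
    any_down = down.any(axis=1)
    strong = (n_up >= 3) & ~down[:, 0]
    anti = down[:, 0] & down[:, 1] & down[:, 2]
    early = down[:, 0] & down[:, 1] & ~down[:, 2] & ~down[:, 3]
    peak = down[:, 0] & ~down[:, 1]
    mild = (n_up >= 1) & ~any_down
    cats[:] = Category.NONE
    cats[mild] = Category.MILD_AGE
    cats[peak & ~strong] = Category.PEAK_1P5
    cats[early] = Category.EARLY_EXPR
    cats[anti] = Category.STRONG_ANTI_AGE
    cats[strong] = Category.STRONG_AGE
    return pd.Series(cats, index=ids, name="category")


def neurodegeneration_set(
    table: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "up",
    use_padj: bool = True,
) -> set[str]:
    """Features significantly regulated in the given direction.

    With the hTDP-43-WT 15-month vs non-transgenic RTE table and
    defaults, this is the "RTEs associated with neurodegeneration" set:
    adjusted p below alpha with a positive log2 fold-change. A
    ``use_padj=False`` switch applies the threshold to the nominal
    p-value instead.
    """
    t = _validated(table)
    if t.empty:
        warnings.warn("neurodegeneration_set: empty table, returning empty set")
        return set()
    pcol = "padj" if use_padj else "pvalue"
    sig = t[pcol] < alpha
    if direction == "up":
        sig &= t["log2fc"] > 0
    elif direction == "down":
        sig &= t["log2fc"] < 0
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return set(t.loc[sig, "feature_id"])


def count_significant(table: pd.DataFrame, alpha: float = 0.05, direction: str = "up") -> int:
    """Number of rows with padj < alpha and the signed fold-change direction."""
    if len(table) == 0:
        return 0
    return len(neurodegeneration_set(table, alpha=alpha, direction=direction))


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 overlap test between two feature sets within a universe.

    a = |A ∩ B|, b = |A \\ B|, c = |B \\ A|, d = |universe \\ (A ∪ B)|.
    ``odds_ratio`` is the sample odds ratio (a*d)/(b*c), +inf when
    b*c = 0 with a*d > 0. ``padj`` is filled in by batch routines.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    pvalue: float
    padj: float = float("nan")


def fisher_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher exact overlap test of two sets within a universe."""
    sa, sb, uni = set(set_a), set(set_b), set(universe)
    if not uni:
        raise ValueError("universe must be nonempty")
    if not sa <= uni:
        raise ValueError(f"set A contains {len(sa - uni)} features outside the universe")
    if not sb <= uni:
        raise ValueError(f"set B contains {len(sb - uni)} features outside the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    res = stats.fisher_exact(a, b, c, d, alternative=alternative)
    return EnrichmentResult(a, b, c, d, res.odds_ratio, res.pvalue)


def enrich_categories(
    target_set: Iterable[str],
    categories: pd.Series,
    universe: Iterable[str] | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Test a feature set against every temporal category, BH-adjusted
    across the batch.

    ``categories`` is the feature_id -> Category series from
    :func:`classify_features`. The universe defaults to the classified
    features (all features present in every aging table).
    """
    cats = categories
    uni = set(cats.index) if universe is None else set(universe)
    target = set(target_set) & uni
    rows = []
    tested = [c for c in Category if c is not Category.NONE]
    for cat in tested:
        # elementwise 'is': numpy/pandas '==' mishandles str-subclass enums
        members = {f for f, c in cats.items() if c is cat} & uni
        r = fisher_enrichment(target, members, uni, alternative=alternative)
        rows.append(
            {
                "category": cat.value,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "pvalue": r.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = stats.bh_adjust(out["pvalue"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjustment (delegates to the stats kernel)."""
    return stats.bh_adjust(pvalues)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def _validated(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing required columns {missing}")
    bad = table[(table["pvalue"] < 0) | (table["pvalue"] > 1) | (table["padj"] < 0) | (table["padj"] > 1)]
    if len(bad):
        raise ValueError(f"DE table has {len(bad)} rows with p-values outside [0, 1]")
    return table


def read_de_table(path) -> pd.DataFrame:
    """Read a tab-separated DE table (feature_id, feature_class, log2fc,
    pvalue, padj; a ``comparison`` column is carried through if present)."""
    return _validated(pd.read_csv(path, sep="\t"))


def write_de_table(table: pd.DataFrame, path) -> None:
    _validated(table).to_csv(path, sep="\t", index=False)


def heatmap_matrix(
    tables: Mapping[float, pd.DataFrame],
    categories: pd.Series,
    feature_class: str | None = "RTE",
) -> pd.DataFrame:
    """Features x comparisons matrix of log2 fold-changes, sorted by
    category then feature id — the substrate for a category heatmap."""
    cols = {}
    for age in AGE_COMPARISONS:
        t = _validated(tables[age])
        if feature_class is not None:
            t = t[t["feature_class"] == feature_class]
        cols[f"15v{age:g}m"] = t.set_index("feature_id")["log2fc"]
    mat = pd.DataFrame(cols)
    mat["category"] = categories.reindex(mat.index).map(
        lambda c: c.value if isinstance(c, Category) else Category.NONE.value
    )
    order = {c.value: i for i, c in enumerate(Category)}
    mat = mat.sort_values(["category", "feature_id"], key=lambda s: s.map(order) if s.name == "category" else s)
    return mat
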