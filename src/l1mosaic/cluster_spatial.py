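"""Cluster calling of reporter-positive cells across serial brain sections.

Counts of GFP-positive cells are tallied per animal, per section (14
sections at fixed bregma coordinates, anterior to posterior) and per
pseudo-hemisphere. Reporter-only control animals define the thresholds:

* a *global* threshold — control mean of per-animal totals plus
  ``k_sd`` (default 3) sample standard deviations — decides whether an
  animal carries a cluster at all;
* *per-section* thresholds — control mean plus ``k_sd`` SD of the
  per-animal totals at that bregma coordinate — decide which sections
  of a cluster-positive animal are involved and on which hemisphere.

Thresholds are exceeded strictly (a tie is not a cluster). Control
per-section statistics are computed on hemisphere-summed totals; each
hemisphere is then compared against the section threshold scaled by the
control hemisphere share (0.5 by default, configurable; a hemisphere
rule of ``"full"`` compares each hemisphere against the unscaled
threshold instead).

The per-animal, per-section calls assemble into a lateralization map
(animals x sections of NONE/LEFT/RIGHT/BILATERAL with cluster sizes),
summarized by run-length contiguity statistics that distinguish a
single large unilateral cluster from multiple small bilateral ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "PSEUDO_LEFT",
    "PSEUDO_RIGHT",
    "CALL_NONE",
    "CALL_LEFT",
    "CALL_RIGHT",
    "CALL_BILATERAL",
    "COUNT_COLUMNS",
    "ThresholdSet",
    "AnimalCall",
    "LateralizationMap",
    "validate_counts",
    "compute_thresholds",
    "call_animal",
    "call_sections",
    "build_map",
    "summarize_contiguity",
    "compare_counts",
]

PSEUDO_LEFT = "pseudo_left"
PSEUDO_RIGHT = "pseudo_right"

CALL_NONE = "none"
CALL_LEFT = "left"
CALL_RIGHT = "right"
CALL_BILATERAL = "bilateral"

COUNT_COLUMNS = (
    "animal_id",
    "genotype",
    "age_months",
    "section_index",
    "bregma_mm",
    "hemisphere",
    "gfp_count",
)


def validate_counts(df: pd.DataFrame, n_sections: int | None = None) -> pd.DataFrame:
    """Validate a section-count table; returns it sorted by animal,
    section, hemisphere."""
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (df["gfp_count"] < 0).any() or not np.issubdtype(df["gfp_count"].dtype, np.integer):
        if not np.allclose(df["gfp_count"], df["gfp_count"].astype(int)) or (df["gfp_count"] < 0).any():
            raise ValueError("gfp_count must be nonnegative integers")
    bad_hemi = set(df["hemisphere"]) - {PSEUDO_LEFT, PSEUDO_RIGHT}
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels {sorted(bad_hemi)}")
    dup = df.duplicated(["animal_id", "section_index", "hemisphere"])
    if dup.any():
        rows = df.loc[dup, ["animal_id", "section_index", "hemisphere"]].iloc[:5]
        raise ValueError(f"duplicate (animal, section, hemisphere) rows, e.g.\n{rows}")
    if n_sections is not None:
        for animal, grp in df.groupby("animal_id"):
            present = set(grp["section_index"])
            want = set(range(n_sections))
            if present != want:
                raise ValueError(
                    f"animal {animal!r} missing sections {sorted(want - present)}"
                )
    return df.sort_values(["animal_id", "section_index", "hemisphere"]).reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdSet:
    """Control-derived cluster thresholds (mean + k_sd * sample SD)."""

    global_threshold: float
    per_section_threshold: dict[int, float]
    k_sd: float
    control_n: int
    global_mean: float
    global_sd: float
    bregma_mm: dict[int, float] = field(default_factory=dict)


def compute_thresholds(controls: pd.DataFrame, k_sd: float = 3.0) -> ThresholdSet:
    """Thresholds from reporter-only control animals.

    Global: mean + k_sd*SD of per-animal totals over all sections and
    both hemispheres. Per-section: mean + k_sd*SD of per-animal
    hemisphere-summed totals at that section. Sample SD (n-1).
    """
    df = validate_counts(controls)
    animals = df["animal_id"].unique()
    if len(animals) < 2:
        raise ValueError(f"need >= 2 control animals for an SD, got {len(animals)}")
    sections = sorted(df["section_index"].unique())
    per_animal_sections = df.groupby("animal_id")["section_index"].apply(set)
    for animal, present in per_animal_sections.items():
        missing = set(sections) - present
        if missing:
            raise ValueError(f"control {animal!r} missing sections {sorted(missing)}")
    totals = df.groupby("animal_id")["gfp_count"].sum()
    mean, sd = float(totals.mean()), float(totals.std(ddof=1))
    section_totals = (
        df.groupby(["animal_id", "section_index"])["gfp_count"].sum().unstack("section_index")
    )
    per_section = {
        int(s): float(section_totals[s].mean() + k_sd * section_totals[s].std(ddof=1))
        for s in sections
    }
    bregma = {
        int(s): float(df.loc[df["section_index"] == s, "bregma_mm"].iloc[0]) for s in sections
    }
    return ThresholdSet(
        global_threshold=mean + k_sd * sd,
        per_section_threshold=per_section,
        k_sd=k_sd,
        control_n=len(animals),
        global_mean=mean,
        global_sd=sd,
        bregma_mm=bregma,
    )


@dataclass(frozen=True)
class AnimalCall:
    animal_id: str
    has_cluster: bool
    total: int


def call_animal(animal: pd.DataFrame, thresholds: ThresholdSet) -> AnimalCall:
    """Animal-level call: cluster iff the total count over all sections
    and hemispheres strictly exceeds the global threshold."""
    df = validate_counts(animal)
    ids = df["animal_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one animal, got {list(ids)}")
    total = int(df["gfp_count"].sum())
    return AnimalCall(str(ids[0]), total > thresholds.global_threshold, total)


def call_sections(
    animal: pd.DataFrame,
    thresholds: ThresholdSet,
    hemisphere_share: float = 0.5,
    hemisphere_rule: str = "share",
) -> pd.DataFrame:
    """Per-section laterality calls for one animal.

    Each hemisphere count is compared (strictly) against the section
    threshold scaled by ``hemisphere_share`` (rule ``"share"``, default
    0.5) or against the full threshold (rule ``"full"``). Exactly one
    qualifying hemisphere gives LEFT/RIGHT, both give BILATERAL,
    neither NONE. ``size`` sums the counts of qualifying hemispheres.
    """
    if hemisphere_rule not in ("share", "full"):
        raise ValueError("hemisphere_rule must be 'share' or 'full'")
    scale = hemisphere_share if hemisphere_rule == "share" else 1.0
    df = validate_counts(animal)
    wide = df.pivot_table(
        index="section_index", columns="hemisphere", values="gfp_count", aggfunc="sum"
    ).reindex(columns=[PSEUDO_LEFT, PSEUDO_RIGHT], fill_value=0)
    rows = []
    for s in wide.index:
        if int(s) not in thresholds.per_section_threshold:
            raise KeyError(f"no control threshold for section {s}")
        thr = thresholds.per_section_threshold[int(s)] * scale
        left = int(wide.at[s, PSEUDO_LEFT])
        right = int(wide.at[s, PSEUDO_RIGHT])
        l_pass, r_pass = left > thr, right > thr
        if l_pass and r_pass:
            call, size = CALL_BILATERAL, left + right
        elif l_pass:
            call, size = CALL_LEFT, left
        elif r_pass:
            call, size = CALL_RIGHT, right
        else:
            call, size = CALL_NONE, 0
        rows.append(
            {
                "section_index": int(s),
                "bregma_mm": thresholds.bregma_mm.get(int(s), float("nan")),
                "call": call,
                "size": size,
            }
        )
    return pd.DataFrame(rows).sort_values("section_index").reset_index(drop=True)


@dataclass
class LateralizationMap:
    """Animals x sections matrix of laterality calls with sizes."""

    calls: pd.DataFrame  # animals x section_index, values in CALL_*
    sizes: pd.DataFrame  # animals x section_index, summed supra-threshold counts
    bregma_mm: dict[int, float]

    @property
    def animals(self) -> list[str]:
        return list(self.calls.index)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (animal, section, bregma, call, size) table."""
        long_calls = self.calls.stack().rename("call")
        long_sizes = self.sizes.stack().rename("size")
        out = pd.concat([long_calls, long_sizes], axis=1).reset_index()
        out.columns = ["animal_id", "section_index", "call", "size"]
        out["bregma_mm"] = out["section_index"].map(self.bregma_mm)
        return out


def build_map(
    dataset: pd.DataFrame,
    thresholds: ThresholdSet,
    hemisphere_share: float = 0.5,
    hemisphere_rule: str = "share",
) -> LateralizationMap:
    """Assemble the lateralization map over animals that pass the
    animal-level call; animals that do not are omitted (the map shows
    only cluster-positive animals)."""
    df = validate_counts(dataset)
    call_rows: dict[str, pd.Series] = {}
    size_rows: dict[str, pd.Series] = {}
    for animal_id, grp in df.groupby("animal_id", sort=True):
        if not call_animal(grp, thresholds).has_cluster:
            continue
        sec = call_sections(grp, thresholds, hemisphere_share, hemisphere_rule)
        call_rows[str(animal_id)] = sec.set_index("section_index")["call"]
        size_rows[str(animal_id)] = sec.set_index("section_index")["size"]
    if not call_rows:
        empty = pd.DataFrame()
        return LateralizationMap(empty, empty, dict(thresholds.bregma_mm))
    calls = pd.DataFrame(call_rows).T.sort_index()
    sizes = pd.DataFrame(size_rows).T.sort_index()
    return LateralizationMap(calls, sizes, dict(thresholds.bregma_mm))


def summarize_contiguity(m: LateralizationMap) -> pd.DataFrame:
    """Run-length contiguity summary per animal.

    ``n_runs``: maximal contiguous runs of non-NONE sections;
    ``max_run_length``: longest such run; ``unilateral_fraction``:
    fraction of cluster-positive sections whose call equals the modal
    unilateral hemisphere (0 when no unilateral call exists);
    ``total_size``: summed supra-threshold counts.
    """
    rows = []
    for animal in m.animals:
        seq = [str(c) for c in m.calls.loc[animal]]
        positive = [c for c in seq if c != CALL_NONE]
        runs = _run_lengths(seq)
        lateral = [c for c in positive if c in (CALL_LEFT, CALL_RIGHT)]
        if lateral:
            n_left = lateral.count(CALL_LEFT)
            modal = CALL_LEFT if n_left * 2 >= len(lateral) else CALL_RIGHT
            frac = sum(c == modal for c in positive) / len(positive)
        else:
            frac = 0.0
        rows.append(
            {
                "animal_id": animal,
                "n_runs": len(runs),
                "max_run_length": max(runs) if runs else 0,
                "unilateral_fraction": frac,
                "total_size": int(m.sizes.loc[animal].sum()),
            }
        )
    return pd.DataFrame(rows)


def _run_lengths(calls: Sequence[str]) -> list[int]:
    runs, current = [], 0
    for c in calls:
        if c != CALL_NONE:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def compare_counts(
    groups: Mapping[str, Sequence[float]],
    lambda_bc: float = 0.041,
    offset: float = 1.0,
    comparisons: Sequence[tuple[str, str]] | None = None,
    welch: bool = False,
) -> dict:
    """Box-Cox-normalize per-animal counts and test group differences.

    One-way ANOVA across all groups, then two-sample t-tests for the
    planned pairwise comparisons (all pairs by default). Counts may
    contain zeros; the offset keeps them in the Box-Cox domain.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    params = stats.BoxCoxParams(lambda_=lambda_bc, offset=offset)
    transformed = {name: stats.boxcox(np.asarray(v, dtype=float), params) for name, v in groups.items()}
    names = list(transformed)
    anova = stats.anova_oneway([transformed[n] for n in names])
    if comparisons is None:
        comparisons = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    posthoc = []
    for g1, g2 in comparisons:
        r = stats.t_two_sample(transformed[g1], transformed[g2], welch=welch)
        posthoc.append({"group_a": g1, "group_b": g2, "t": r.t, "df": r.df, "pvalue": r.pvalue})
    return {
        "lambda": lambda_bc,
        "offset": offset,
        "anova": {
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "pvalue": anova.pvalue,
        },
        "posthoc": posthoc,
    }
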