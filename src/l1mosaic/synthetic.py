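"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the structure of the study's data:

* :func:`simulate_de_tables` — per-comparison differential-expression
  summary tables (genes and RTEs) with temporal categories planted into
  the four aging comparisons (15 months vs 1.5/3/6/10) and a planted
  "neurodegeneration" RTE set, overlapping a designated category at a
  target odds ratio, driving the transgenic 15-month comparison.
  Summary statistics are simulated directly: an observed log2
  fold-change is the planted effect plus Gaussian noise of known scale,
  its p-value comes from the corresponding z-statistic, and adjusted
  p-values are Benjamini-Hochberg within each table.
* :func:`simulate_section_counts` — per-animal, per-section,
  per-hemisphere GFP-positive cell counts over 14 bregma-ordered
  sections: Poisson baseline everywhere, plus a planted cluster that is
  either one contiguous unilateral span or several scattered small
  foci on both hemispheres.
* :func:`simulate_nuclei` / :func:`simulate_tissue_stack` — a 900 µm
  (plus cluster margin) x 300 µm field of nuclei with a GFP-positive
  cluster band at one end; each nucleus dies with probability
  ``p(d) = p_far + (p_near - p_far) * exp(-d / l)`` of its distance
  from the cluster edge, and dying nuclei carry >= 3 TUNEL puncta.
  The stack renderer draws every channel as additive Gaussian blobs
  plus background and noise, with puncta snapped to pixel positions
  whose pairwise separation exceeds the detector's merge radius, so a
  noise-free stack is exactly recoverable.

All generators are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _spstats

from . import cluster_spatial as cs
from . import imagequant as iq
from .rte_aging import AGE_COMPARISONS, Category
from .stats import bh_adjust

__all__ = [
    "DeSimConfig",
    "DeSimResult",
    "simulate_de_tables",
    "SpatialSimConfig",
    "SpatialSimResult",
    "simulate_section_counts",
    "StackSimConfig",
    "StackSimResult",
    "simulate_nuclei",
    "simulate_tissue_stack",
    "CATEGORY_SIGNS",
    "puncta_offsets",
]

# Planted per-comparison effect signs for each temporal category, in the
# (1.5, 3, 6, 10 months vs 15) comparison order; +1 means higher at 15
# months. Each canonical pattern classifies into its own category.
CATEGORY_SIGNS: dict[Category, tuple[int, int, int, int]] = {
    Category.STRONG_AGE: (1, 1, 1, 1),
    Category.MILD_AGE: (0, 0, 1, 0),
    Category.PEAK_1P5: (-1, 0, 0, 0),
    Category.EARLY_EXPR: (-1, -1, 0, 0),
    Category.STRONG_ANTI_AGE: (-1, -1, -1, 0),
}

_DEFAULT_FRACTIONS = {
    Category.STRONG_AGE: 0.04,
    Category.MILD_AGE: 0.06,
    Category.PEAK_1P5: 0.04,
    Category.EARLY_EXPR: 0.03,
    Category.STRONG_ANTI_AGE: 0.03,
}


@dataclass(frozen=True)
class DeSimConfig:
    """Differential-expression simulation settings.

    ``effect_size_log2fc`` over ``null_sd`` sets the planted z-scale
    (default 5, a clearly detectable effect); ``overlap_odds`` is the
    target odds ratio between the planted neurodegeneration set and
    ``neuro_target_category`` over the RTE universe, with
    ``neuro_baseline_rate`` membership outside that category.
    """

    n_genes: int = 2000
    n_rtes: int = 5000
    category_fractions: Mapping[Category, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    effect_size_log2fc: float = 2.0
    null_sd: float = 0.4
    alpha: float = 0.05
    overlap_odds: float = 10.0
    neuro_baseline_rate: float = 0.05
    neuro_target_category: Category = Category.STRONG_AGE
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_rtes < 1:
            raise ValueError("n_genes and n_rtes must be >= 1")
        fracs = dict(self.category_fractions)
        if any(f < 0 for f in fracs.values()):
            raise ValueError("category fractions must be nonnegative")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ValueError(f"category fractions sum to {sum(fracs.values()):.3f} > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_size_log2fc <= 0 or self.null_sd <= 0:
            raise ValueError("effect_size_log2fc and null_sd must be positive")
        if self.overlap_odds <= 0:
            raise ValueError("overlap_odds must be positive")
        if not 0 <= self.neuro_baseline_rate < 1:
            raise ValueError("neuro_baseline_rate must be in [0, 1)")


@dataclass
class DeSimResult:
    """Simulated DE tables plus planted truth."""

    tables: dict[str, pd.DataFrame]
    aging_labels: dict[float, str]
    neuro_label: str
    true_categories: pd.Series  # RTE feature_id -> Category
    true_neuro_set: set[str]
    planted_odds_ratio: float

    def aging_tables(self) -> dict[float, pd.DataFrame]:
        return {age: self.tables[label] for age, label in self.aging_labels.items()}


def simulate_de_tables(cfg: DeSimConfig) -> DeSimResult:
    """Generate the four aging-comparison tables and the transgenic
    15-month table with planted categories and set overlap."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    rte_ids = [f"rte_{i:05d}" for i in range(cfg.n_rtes)]

    # assign categories to RTEs in a fixed block layout, then shuffle ids
    fracs = {Category(k): float(v) for k, v in dict(cfg.category_fractions).items()}
    shuffled = list(rng.permutation(rte_ids))
    categories = pd.Series(Category.NONE, index=pd.Index(rte_ids, name="feature_id"), dtype=object)
    cursor = 0
    for cat in (c for c in Category if c is not Category.NONE):
        k = int(round(fracs.get(cat, 0.0) * cfg.n_rtes))
        categories.loc[shuffled[cursor : cursor + k]] = cat
        cursor += k

    # planted neurodegeneration set: exact member counts inside/outside
    # the designated category at the rates implied by the target odds
    p0 = cfg.neuro_baseline_rate
    odds1 = cfg.overlap_odds * p0 / (1 - p0) if p0 > 0 else 0.0
    p1 = odds1 / (1 + odds1)
    in_cat = [f for f in shuffled if categories[f] is cfg.neuro_target_category]
    out_cat = [f for f in shuffled if categories[f] is not cfg.neuro_target_category]
    k_in = int(round(p1 * len(in_cat)))
    k_out = int(round(p0 * len(out_cat)))
    neuro = set(list(rng.permutation(in_cat))[:k_in]) | set(list(rng.permutation(out_cat))[:k_out])
    a = k_in
    b = k_out
    c = len(in_cat) - k_in
    d = len(out_cat) - k_out
    planted_or = float("nan") if min(b, c) == 0 else (a * d) / (b * c)

    # NB: numpy '==' against a str-subclass Enum stringifies the scalar
    # and never matches, so membership is built per element
    sign_matrix = np.zeros((cfg.n_rtes, len(AGE_COMPARISONS)), dtype=float)
    cat_arr = categories.to_numpy()
    for cat, signs in CATEGORY_SIGNS.items():
        sel = np.fromiter((c is cat for c in cat_arr), dtype=bool, count=len(cat_arr))
        sign_matrix[sel] = signs

    tables: dict[str, pd.DataFrame] = {}
    aging_labels: dict[float, str] = {}
    for j, age in enumerate(AGE_COMPARISONS):
        label = f"NonTg_15v{age:g}"
        aging_labels[age] = label
        planted = np.concatenate(
            [np.zeros(cfg.n_genes), sign_matrix[:, j] * cfg.effect_size_log2fc]
        )
        tables[label] = _make_table(rng, gene_ids, rte_ids, planted, cfg, label)

    neuro_label = "TDP43-WT_15vNonTg"
    member = np.array([f in neuro for f in rte_ids])
    planted = np.concatenate(
        [np.zeros(cfg.n_genes), member * cfg.effect_size_log2fc]
    )
    tables[neuro_label] = _make_table(rng, gene_ids, rte_ids, planted, cfg, neuro_label)

    return DeSimResult(tables, aging_labels, neuro_label, categories, neuro, planted_or)


def _make_table(rng, gene_ids, rte_ids, planted_log2fc, cfg, label) -> pd.DataFrame:
    n = len(gene_ids) + len(rte_ids)
    log2fc = planted_log2fc + rng.normal(0.0, cfg.null_sd, size=n)
    z = log2fc / cfg.null_sd
    pvalue = 2 * _spstats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "feature_id": gene_ids + rte_ids,
            "feature_class": ["gene"] * len(gene_ids) + ["RTE"] * len(rte_ids),
            "comparison": label,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        }
    )


# ---------------------------------------------------------------------------
# Section counts
# ---------------------------------------------------------------------------

LAYOUT_UNILATERAL = "unilateral_contiguous"
LAYOUT_BILATERAL = "bilateral_small"


@dataclass(frozen=True)
class SpatialSimConfig:
    """Section-count simulation: Poisson baseline per hemisphere per
    section, with a planted cluster in affected animals.

    14 sections, 50 µm thick at a 150 µm interval (bregma labels are
    spaced accordingly). ``layout`` is either one contiguous unilateral
    span of ``cluster_span_sections`` sections or the same number of
    scattered single-section foci with independently random hemispheres.
    """

    n_control: int = 10
    n_affected: int = 10
    n_sections: int = 14
    section_thickness_um: float = 50.0
    section_interval_um: float = 150.0
    control_rate: float = 1.0
    cluster_amplitude: float = 20.0
    cluster_span_sections: int = 5
    layout: str = LAYOUT_UNILATERAL
    control_genotype: str = "L1-EGFP"
    affected_genotype: str = "TDP43"
    age_months: float = 6.0
    bregma_start_mm: float = 2.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.control_rate < 0 or self.cluster_amplitude < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.cluster_span_sections <= self.n_sections:
            raise ValueError("cluster_span_sections must be <= n_sections")
        if self.layout not in (LAYOUT_UNILATERAL, LAYOUT_BILATERAL):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_control < 0 or self.n_affected < 0:
            raise ValueError("animal counts must be >= 0")

    @property
    def bregma_mm(self) -> np.ndarray:
        step = (self.section_thickness_um + self.section_interval_um) / 1000.0
        return self.bregma_start_mm - step * np.arange(self.n_sections)


@dataclass
class SpatialSimResult:
    counts: pd.DataFrame  # cluster_spatial.COUNT_COLUMNS schema
    truth: pd.DataFrame  # animal_id, section_index, hemisphere (planted cluster sections)


def simulate_section_counts(cfg: SpatialSimConfig) -> SpatialSimResult:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bregma = cfg.bregma_mm
    rows = []
    truth_rows = []

    def baseline_rows(animal_id: str, genotype: str):
        for s in range(cfg.n_sections):
            for hemi in (cs.PSEUDO_LEFT, cs.PSEUDO_RIGHT):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "genotype": genotype,
                        "age_months": cfg.age_months,
                        "section_index": s,
                        "bregma_mm": float(bregma[s]),
                        "hemisphere": hemi,
                        "gfp_count": int(rng.poisson(cfg.control_rate)),
                    }
                )

    for i in range(cfg.n_control):
        baseline_rows(f"ctrl_{i:02d}", cfg.control_genotype)

    hemis = (cs.PSEUDO_LEFT, cs.PSEUDO_RIGHT)
    for i in range(cfg.n_affected):
        animal = f"aff_{i:02d}"
        baseline_rows(animal, cfg.affected_genotype)
        if cfg.cluster_span_sections == 0:
            continue
        if cfg.layout == LAYOUT_UNILATERAL:
            start = int(rng.integers(0, cfg.n_sections - cfg.cluster_span_sections + 1))
            hemi = hemis[int(rng.integers(2))]
            planted = [(s, hemi) for s in range(start, start + cfg.cluster_span_sections)]
        else:
            secs = rng.choice(cfg.n_sections, size=cfg.cluster_span_sections, replace=False)
            planted = [(int(s), hemis[int(rng.integers(2))]) for s in sorted(secs)]
        for s, hemi in planted:
            extra = int(rng.poisson(cfg.cluster_amplitude))
            for r in rows:
                if r["animal_id"] == animal and r["section_index"] == s and r["hemisphere"] == hemi:
                    r["gfp_count"] += extra
                    break
            truth_rows.append({"animal_id": animal, "section_index": s, "hemisphere": hemi})

    counts = pd.DataFrame(rows, columns=list(cs.COUNT_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=["animal_id", "section_index", "hemisphere"])
    return SpatialSimResult(counts, truth)


# ---------------------------------------------------------------------------
# Tissue stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSimConfig:
    """Tissue-stack simulation around a GFP-positive cluster.

    The field spans ``shape_xyz[0]`` x ``shape_xyz[1]`` pixels (x, y) at
    ``pixel_size_um`` with ``shape_xyz[2]`` optical planes. The cluster
    occupies the band x < ``gfp_cluster_edge_x_um``; nuclei inside it
    are GFP-positive and sit at distance 0. The per-nucleus death
    probability decays exponentially with distance from the edge.
    TUNEL-positive nuclei carry 3-5 puncta, negative ones 0-2.
    """

    shape_xyz: tuple[int, int, int] = (1000, 300, 5)
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    n_nuclei: int = 3000
    nucleus_radius_um: float = 3.5
    min_separation_um: float = 7.5
    gfp_cluster_edge_x_um: float = 100.0
    p_near: float = 0.6
    p_far: float = 0.05
    decay_length_um: float = 200.0
    puncta_per_positive: float = 4.0
    puncta_per_negative: float = 0.5
    nucleus_amp: float = 120.0
    gfp_amp: float = 180.0
    puncta_amp: float = 150.0
    background_level: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        nx, ny, nz = self.shape_xyz
        if min(nx, ny, nz) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 <= self.p_far <= self.p_near <= 1:
            raise ValueError("need 0 <= p_far <= p_near <= 1")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be positive")
        if self.puncta_per_positive < 3:
            raise ValueError("puncta_per_positive mean must be >= 3")
        if not 0 <= self.puncta_per_negative < 3:
            raise ValueError("puncta_per_negative mean must be < 3")
        width_um = nx * self.pixel_size_um
        if not 0 <= self.gfp_cluster_edge_x_um < width_um:
            raise ValueError(
                f"cluster edge at {self.gfp_cluster_edge_x_um} um exceeds the "
                f"{width_um} um stack width"
            )
        if self.min_separation_um < 2 * self.nucleus_radius_um:
            raise ValueError("min_separation_um must be >= nucleus diameter")
        margin = self._margin_px * self.pixel_size_um
        if nx * self.pixel_size_um <= 2 * margin or ny * self.pixel_size_um <= 2 * margin:
            raise ValueError("stack too small for the nucleus geometry")

    @property
    def _margin_px(self) -> int:
        return int(np.ceil(self.nucleus_radius_um / self.pixel_size_um)) + 4


# integer-pixel puncta offset templates: pairwise separation > 3 px,
# all within the nucleus mask; chosen so the 3-px merge radius of the
# detector never fuses distinct planted puncta
_PUNCTA_RING = ((1, 3), (3, -1), (-1, -3), (-3, 1))


def puncta_offsets(count: int, rot: int) -> list[tuple[int, int]]:
    """Integer (dx, dy) offsets for ``count`` puncta (0..5), rotated by
    ``rot`` quarter-turns for variety."""
    if not 0 <= count <= 5:
        raise ValueError("puncta count must be in 0..5")
    if count == 0:
        return []
    ring = [_PUNCTA_RING[(i + rot) % 4] for i in range(4)]
    pts = ring[:count] if count <= 4 else ring + [(0, 0)]
    if count < 4 and count % 2 == 1:
        pts = [(0, 0)] + ring[: count - 1]
    return pts


@dataclass
class StackSimResult:
    stack: iq.ImageStack
    truth: pd.DataFrame


def simulate_nuclei(cfg: StackSimConfig) -> pd.DataFrame:
    """Place nuclei and draw their death status and puncta counts.

    Returns the truth table (nucleus_id, x_um, y_um, z_um,
    gfp_positive, distance_um, p_death, tunel_positive, puncta_count,
    template_rot). Placement is random sequential with a minimum
    center distance, on the pixel grid.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.shape_xyz
    margin = cfg._margin_px
    min_sep_px = cfg.min_separation_um / cfg.pixel_size_um
    cell = max(min_sep_px, 1.0)
    grid: dict[tuple[int, int], list[tuple[int, int]]] = {}
    placed: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 400 * cfg.n_nuclei
    while len(placed) < cfg.n_nuclei:
        if attempts >= max_attempts:
            raise ValueError(
                f"could only place {len(placed)}/{cfg.n_nuclei} nuclei at "
                f"min separation {cfg.min_separation_um} um; reduce density"
            )
        attempts += 1
        x = int(rng.integers(margin, nx - margin))
        y = int(rng.integers(margin, ny - margin))
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for ix in range(gx - 1, gx + 2):
            for iy in range(gy - 1, gy + 2):
                for (px, py) in grid.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < min_sep_px**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((x, y))
            grid.setdefault((gx, gy), []).append((x, y))

    xs = np.array([p[0] for p in placed], dtype=float) * cfg.pixel_size_um
    ys = np.array([p[1] for p in placed], dtype=float) * cfg.pixel_size_um
    zs = rng.integers(0, nz, size=cfg.n_nuclei)
    dist = np.maximum(xs - cfg.gfp_cluster_edge_x_um, 0.0)
    p_death = cfg.p_far + (cfg.p_near - cfg.p_far) * np.exp(-dist / cfg.decay_length_um)
    dead = rng.random(cfg.n_nuclei) < p_death
    pos_counts = 3 + np.minimum(rng.poisson(cfg.puncta_per_positive - 3, cfg.n_nuclei), 2)
    neg_counts = np.minimum(rng.poisson(cfg.puncta_per_negative, cfg.n_nuclei), 2)
    counts = np.where(dead, pos_counts, neg_counts)
    rots = rng.integers(0, 4, size=cfg.n_nuclei)
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(1, cfg.n_nuclei + 1),
            "x_um": xs,
            "y_um": ys,
            "z_um": zs * cfg.z_step_um,
            "gfp_positive": xs < cfg.gfp_cluster_edge_x_um,
            "distance_um": dist,
            "p_death": p_death,
            "tunel_positive": dead,
            "puncta_count": counts.astype(int),
            "template_rot": rots.astype(int),
        }
    )


def simulate_tissue_stack(cfg: StackSimConfig) -> StackSimResult:
    """Render the full multi-channel stack for a simulated field.

    Channels: nuclear counterstain (all nuclei), GFP (nuclei inside the
    cluster band), an empty background-red channel, a far-red channel
    (background only), and TUNEL (puncta). Blobs are additive
    Gaussians; every channel gets ``background_level`` plus
    ``noise_sd`` Gaussian noise, clipped at zero.
    """
    truth = simulate_nuclei(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    nx, ny, nz = cfg.shape_xyz
    vox = np.zeros((5, nz, ny, nx), dtype=np.float32)
    roles = {r: i for i, r in enumerate(iq.CHANNEL_ROLES)}
    r_px = cfg.nucleus_radius_um / cfg.pixel_size_um
    sigma_nuc = r_px / 2
    z_centers = (truth["z_um"].to_numpy() / cfg.z_step_um).astype(int)
    xs_px = (truth["x_um"].to_numpy() / cfg.pixel_size_um).astype(int)
    ys_px = (truth["y_um"].to_numpy() / cfg.pixel_size_um).astype(int)

    for i in range(len(truth)):
        x, y, zc = xs_px[i], ys_px[i], int(z_centers[i])
        _stamp(vox[roles["nuclei_405"]], x, y, zc, cfg.nucleus_amp, sigma_nuc, 1.2)
        if truth["gfp_positive"].iat[i]:
            _stamp(vox[roles["gfp_488"]], x, y, zc, cfg.gfp_amp, sigma_nuc, 1.2)
        n_puncta = int(truth["puncta_count"].iat[i])
        for dx, dy in puncta_offsets(n_puncta, int(truth["template_rot"].iat[i])):
            _stamp(vox[roles["tunel"]], x + dx, y + dy, zc, cfg.puncta_amp, 1.0, 0.8)

    vox += cfg.background_level
    if cfg.noise_sd > 0:
        vox += rng.normal(0.0, cfg.noise_sd, size=vox.shape).astype(np.float32)
    np.maximum(vox, 0, out=vox)
    stack = iq.ImageStack(
        voxels=vox,
        channel_roles=roles,
        pixel_size_um=cfg.pixel_size_um,
        z_step_um=cfg.z_step_um,
    )
    return StackSimResult(stack, truth)


def _stamp(channel: np.ndarray, x: int, y: int, zc: int, amp: float, sigma_xy: float, sigma_z: float) -> None:
    """Add a separable Gaussian blob at (x, y, zc) into a (z, y, x) array."""
    nz, ny, nx = channel.shape
    half = int(np.ceil(3 * sigma_xy))
    x0, x1 = max(x - half, 0), min(x + half + 1, nx)
    y0, y1 = max(y - half, 0), min(y + half + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return
    gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * sigma_xy**2))
    gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * sigma_xy**2))
    gz = np.exp(-((np.arange(nz) - zc) ** 2) / (2 * sigma_z**2))
    channel[:, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
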