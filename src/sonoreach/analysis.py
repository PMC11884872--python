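"""Offline kinematic analysis: reach segmentation, clustering, cohort stats.

Pipeline: segment reaches from the displacement traces (the offline
counterpart of the real-time trial machine), time-normalize each reach to a
fixed number of samples, embed with PCA, cluster PCA scores with a Gaussian
mixture whose component count is selected by BIC (t-SNE is kept strictly for
2-D visualization), then summarize learning as the normalized reach ratio -
left-paw reaches over right-paw reaches, normalized to each animal's Day-1
value - and test it with per-day Welch t-tests, a two-way repeated-measures
ANOVA (group between, day within, Greenhouse-Geisser corrected) and Cohen's
d effect sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

from .engine import SessionRecord, TrialConfig

__all__ = [
    "ReachSegment",
    "TrajectoryMatrix",
    "PCAResult",
    "ClusterResult",
    "CohortResult",
    "StatsResult",
    "detect_reaches",
    "segments_from_record",
    "align_and_resample",
    "pca_embed",
    "choose_n_components",
    "tsne_embed",
    "gmm_cluster",
    "count_table",
    "reach_ratio",
    "cohens_d",
    "group_stats",
]


@dataclass
class ReachSegment:
    """One reach: a maximal excursion above the start tolerance."""

    onset: float
    offset: float
    apex: float
    samples: np.ndarray
    mouse: str = ""
    day: int = 0
    group: str = ""
    paw: str = "left"


@dataclass
class TrajectoryMatrix:
    """Reach-aligned, length-normalized trajectories (n_reaches x T)."""

    matrix: np.ndarray
    meta: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError("metadata rows must match trajectory rows")


def detect_reaches(
    timestamps: Sequence[float],
    displacement: Sequence[float],
    start_tolerance: float = 2.0,
    mouse: str = "",
    day: int = 0,
    group: str = "",
    paw: str = "left",
) -> list[ReachSegment]:
    """Segment maximal excursions where displacement exceeds the tolerance.

    The onset is the first above-tolerance sample and the offset the last one
    of each excursion - the same excursion rule the real-time machine uses to
    start and reset trials, applied per paw so the right paw can serve as the
    reach-ratio denominator. Empty input yields an empty list.
    """
    t = np.asarray(timestamps, dtype=float)
    d = np.asarray(displacement, dtype=float)
    if t.size == 0:
        return []
    above = d > start_tolerance
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]]) if edges.size else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [d.size - 1]
    out = []
    for i0, i1 in zip(starts, ends):
        seg = d[i0 : i1 + 1]
        out.append(
            ReachSegment(
                onset=float(t[i0]),
                offset=float(t[i1]),
                apex=float(seg.max()),
                samples=seg,
                mouse=mouse,
                day=day,
                group=group,
                paw=paw,
            )
        )
    return out


def segments_from_record(
    record: SessionRecord, cfg: TrialConfig | None = None, paw: str = "left"
) -> list[ReachSegment]:
    """Reach segments of one session's logged kinematics."""
    cfg = cfg or record.trial_config
    t = [s.timestamp for s in record.kinematics]
    d = [s.disp_left if paw == "left" else s.disp_right for s in record.kinematics]
    return detect_reaches(
        t, d, cfg.start_tolerance, mouse=record.mouse, day=record.day,
        group=record.group, paw=paw,
    )


def align_and_resample(segments: Sequence[ReachSegment], T: int = 100) -> TrajectoryMatrix:
    """Linearly time-warp each reach to ``T`` samples (endpoints preserved).

    Single-sample segments cannot be interpolated and are excluded
    (counted in ``n_excluded``). Zero segments yield an empty matrix.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rows = []
    meta = []
    excluded = 0
    for seg in segments:
        m = len(seg.samples)
        if m < 2:
            excluded += 1
            continue
        xi = np.linspace(0.0, m - 1.0, T)
        rows.append(np.interp(xi, np.arange(m), seg.samples))
        meta.append({"mouse": seg.mouse, "day": seg.day, "group": seg.group, "paw": seg.paw,
                     "onset": seg.onset, "apex": seg.apex})
    matrix = np.vstack(rows) if rows else np.empty((0, T))
    return TrajectoryMatrix(matrix=matrix, meta=pd.DataFrame(meta), n_excluded=excluded)


# ----------------------------------------------------------------------
# Embeddings and clustering
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    mean: np.ndarray


def pca_embed(matrix: np.ndarray, k: int) -> PCAResult:
    """Mean-centered PCA of the trajectory matrix (k leading components)."""
    X = np.asarray(matrix, dtype=float)
    n, T = X.shape
    if not (1 <= k <= min(n, T)):
        raise ValueError(f"k must be in [1, {min(n, T)}], got {k}")
    p = PCA(n_components=k, svd_solver="full")
    scores = p.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=p.components_,
        variance_explained=p.explained_variance_ratio_,
        mean=p.mean_,
    )


def choose_n_components(matrix: np.ndarray, threshold: float = 0.9, cap: int = 10) -> int:
    """Smallest component count explaining ``threshold`` of the variance."""
    X = np.asarray(matrix, dtype=float)
    kmax = min(min(X.shape), cap)
    full = pca_embed(X, kmax)
    cum = np.cumsum(full.variance_explained)
    return int(np.searchsorted(cum, threshold) + 1) if cum[-1] >= threshold else kmax


def tsne_embed(features: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE for visualization only; deterministic given the seed.

    Requires ``n >= 3 * perplexity`` (the usual rule of thumb baked into the
    perplexity parameter).
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(f"t-SNE needs n >= 3*perplexity; got n={n}, perplexity={perplexity}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    bic: dict[int, float]
    responsibilities: np.ndarray


def gmm_cluster(
    features: np.ndarray,
    k_range: Sequence[int] = tuple(range(1, 7)),
    seed: int = 0,
    n_init: int = 10,
    covariance_type: str = "full",
) -> ClusterResult:
    """Gaussian-mixture clustering with BIC model selection.

    Fits one mixture per candidate component count (each with ``n_init``
    seeded restarts) and keeps the count minimizing BIC; rows are labelled by
    maximum responsibility.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    if n < max(ks):
        raise ValueError(f"need at least max(k_range)={max(ks)} rows, got {n}")
    bic: dict[int, float] = {}
    best = None
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        )
        gm.fit(X)
        bic[k] = float(gm.bic(X))
        if best is None or bic[k] < bic[best[0]]:
            best = (k, gm)
    assert best is not None
    k_sel, gm = best
    return ClusterResult(
        labels=gm.predict(X),
        k=k_sel,
        bic=bic,
        responsibilities=gm.predict_proba(X),
    )


# ----------------------------------------------------------------------
# Reach ratio and cohort statistics
# ----------------------------------------------------------------------

@dataclass
class CohortResult:
    """Per-mouse per-day normalized reach ratios with group labels."""

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def count_table(records: Sequence[SessionRecord], cfg: TrialConfig | None = None) -> pd.DataFrame:
    """Tidy per-session reach counts (both paws) from session records."""
    rows = []
    for rec in records:
        left = segments_from_record(rec, cfg, paw="left")
        right = segments_from_record(rec, cfg, paw="right")
        rows.append(
            {
                "mouse": rec.mouse,
                "group": rec.group,
                "day": rec.day,
                "left_reaches": len(left),
                "right_reaches": len(right),
            }
        )
    return pd.DataFrame(rows)


def reach_ratio(counts: pd.DataFrame) -> CohortResult:
    """Normalized reach ratio per mouse per day.

    ``ratio = left_reaches / right_reaches``; ``normalized`` divides by the
    same animal's Day-1 ratio, so Day 1 is identically 1. Mice with a zero
    denominator on any day, or a zero Day-1 ratio, cannot be normalized and
    are excluded (reported in ``excluded``).
    """
    required = {"mouse", "group", "day", "left_reaches", "right_reaches"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns {sorted(missing)}")
    excluded = []
    frames = []
    for mouse, sub in counts.groupby("mouse", sort=True):
        sub = sub.sort_values("day").copy()
        if (sub["right_reaches"] <= 0).any():
            excluded.append(str(mouse))
            continue
        sub["ratio"] = sub["left_reaches"] / sub["right_reaches"]
        day1 = sub.loc[sub["day"] == sub["day"].min(), "ratio"].iloc[0]
        if day1 <= 0:
            excluded.append(str(mouse))
            continue
        sub["normalized"] = sub["ratio"] / day1
        frames.append(sub)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(counts.columns) + ["ratio", "normalized"])
    )
    return CohortResult(table=table, excluded=excluded)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD; 0 when means are equal."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a.mean() - b.mean()
    if diff == 0:
        return 0.0
    n1, n2 = a.size, b.size
    pooled = math.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        return math.inf if diff > 0 else -math.inf
    return float(diff / pooled)


@dataclass
class StatsResult:
    """Per-day tests, mixed ANOVA table and effect sizes."""

    per_day: pd.DataFrame
    anova: pd.DataFrame
    groups: tuple[str, str]
    welch: bool

    def anova_p(self, source: str, corrected: bool = False) -> float:
        row = self.anova[self.anova["Source"].str.lower() == source.lower()]
        if row.empty:
            raise KeyError(f"no ANOVA source {source!r}")
        if corrected and "p_GG_corr" in row and not np.isnan(row["p_GG_corr"].iloc[0]):
            return float(row["p_GG_corr"].iloc[0])
        return float(row["p_unc"].iloc[0])

    def to_json(self, path) -> None:
        payload = {
            "groups": list(self.groups),
            "welch": self.welch,
            "per_day": self.per_day.to_dict(orient="records"),
            "anova": json.loads(self.anova.to_json(orient="records")),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")


def group_stats(
    cohort: pd.DataFrame | CohortResult,
    value: str = "normalized",
    welch: bool = True,
    correction: bool = True,
) -> StatsResult:
    """Between-group statistics of the normalized reach ratio.

    Per day: unpaired two-sample t-test (Welch by default) plus Cohen's d.
    Overall: two-way repeated-measures ANOVA with day as the within-subject
    factor and group between subjects (Greenhouse-Geisser correction applied
    to the within-subject terms), via pingouin. Days on which both groups are
    constant and equal (e.g. the Day-1 normalization anchor) get p = 1, d = 0.
    """
    df = cohort.table if isinstance(cohort, CohortResult) else cohort
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    g1, g2 = groups
    for g in groups:
        if df[df["group"] == g]["mouse"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 mice")
    rows = []
    for day in sorted(df["day"].unique()):
        a = df[(df["day"] == day) & (df["group"] == g1)][value].to_numpy(float)
        b = df[(df["day"] == day) & (df["group"] == g2)][value].to_numpy(float)
        if a.std(ddof=0) == 0 and b.std(ddof=0) == 0 and a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "day": int(day),
                "t": float(t_stat),
                "p": float(p),
                "cohens_d": cohens_d(a, b),
                f"mean_{g1}": float(a.mean()),
                f"mean_{g2}": float(b.mean()),
                "n1": int(a.size),
                "n2": int(b.size),
            }
        )
    per_day = pd.DataFrame(rows)

    import pingouin as pg

    aov = pg.mixed_anova(
        data=df, dv=value, within="day", subject="mouse", between="group",
        correction=correction,
    )
    return StatsResult(per_day=per_day, anova=aov, groups=(g1, g2), welch=welch)
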