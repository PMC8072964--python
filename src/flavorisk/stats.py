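"""Descriptive summaries and the nonparametric comparison battery.

Contents are strongly right-skewed and heavily censored, so group
comparisons use rank-based tests: Kruskal–Wallis across the three cigarette
parts with Dunn's post hoc z-tests under a Bonferroni correction, and the
Mann–Whitney U test between capsule and non-capsule cigarettes. A
Shapiro–Wilk gateway is exposed for the normality check that motivates the
nonparametric route. PCA on the cigarette × compound content matrix gives
the chemometric fingerprint view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats as _sps
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import ContentRecord, Part, Status

#: switch point between the exact and normal-approximation Mann-Whitney p
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics of detected contents for one compound × group.

    Statistics cover quantified records only (the published summary-table
    semantics); a group with no detection renders as "ND" with all
    statistics absent.
    """

    compound: str
    group: str
    n_detected: int
    mean: Optional[float] = None
    median: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self):
        if self.n_detected == 0:
            if any(v is not None for v in (self.mean, self.median, self.sd)):
                raise ValueError("ND row must have absent statistics")
        elif not (self.min <= self.median <= self.max):
            raise ValueError("need min ≤ median ≤ max")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_rank_difference: float
    z: float
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class TestResult:
    test: Literal["kruskal_wallis", "mann_whitney", "shapiro_wilk"]
    statistic: float
    p_value: float
    df: Optional[int] = None
    pairwise: tuple[PairwiseComparison, ...] = ()


GroupBy = Literal["part", "cigarette_class"]


def _group_key(record: ContentRecord, group_by: GroupBy) -> str:
    if group_by == "part":
        return record.part.value
    if group_by == "cigarette_class":
        return "capsule" if record.has_capsule else "non_capsule"
    raise ValueError(f"unknown group_by {group_by!r}")


def summarize(
    records: Iterable[ContentRecord],
    group_by: GroupBy = "part",
    sd_for_singleton: bool = True,
) -> list[SummaryRow]:
    """Per compound × group descriptive statistics over detected values.

    Only quantified records enter the statistics; the sample (n−1) SD is
    used, reported as 0 for single-observation groups when
    ``sd_for_singleton`` is set (absent otherwise).
    """
    buckets: dict[tuple[str, str], list[float]] = {}
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.compound, _group_key(r, group_by))
        seen.add(key)
        if r.status is Status.QUANTIFIED:
            buckets.setdefault(key, []).append(r.content_ug_per_cigarette)
    rows = []
    for compound, group in sorted(seen):
        vals = np.asarray(buckets.get((compound, group), []), dtype=float)
        if vals.size == 0:
            rows.append(SummaryRow(compound, group, 0))
            continue
        if vals.size == 1:
            sd = 0.0 if sd_for_singleton else None
        else:
            sd = float(vals.std(ddof=1))
        rows.append(
            SummaryRow(
                compound=compound,
                group=group,
                n_detected=int(vals.size),
                mean=float(vals.mean()),
                median=float(np.median(vals)),
                sd=sd,
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return rows


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for i, g in enumerate(gs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return gs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test with tie correction and chi-square p-value.

    With no rank variance at all (every observation equal) H is 0 by
    convention and p is 1.
    """
    gs = _check_groups(groups, 2)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, df=len(gs) - 1)
    h, p = _sps.kruskal(*gs)
    return TestResult("kruskal_wallis", float(h), float(p), df=len(gs) - 1)


def dunn_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> list[PairwiseComparison]:
    """Dunn's post hoc z-tests on mean ranks with Bonferroni adjustment.

    The pooled ranking (average ranks on ties) gives mean rank differences;
    the z variance carries the tie correction Σ(t³−t)/(12(N−1)); two-sided
    p-values are multiplied by the number of pairs k(k−1)/2 and capped at 1.
    """
    gs = _check_groups(groups, 3)
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels must match groups")
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = _sps.rankdata(pooled)
    sizes = [g.size for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(gs))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    n_pairs = len(gs) * (len(gs) - 1) // 2
    out = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            diff = mean_ranks[i] - mean_ranks[j]
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = diff / se if se > 0 else 0.0
            p = 2.0 * _sps.norm.sf(abs(z))
            out.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_rank_difference=float(diff),
                    z=float(z),
                    p_value=float(p),
                    adjusted_p=float(min(1.0, p * n_pairs)),
                )
            )
    return out


def kruskal_wallis_with_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> TestResult:
    """Kruskal–Wallis plus Dunn–Bonferroni pairwise comparisons."""
    kw = kruskal_wallis(groups)
    pairwise = tuple(dunn_bonferroni(groups, labels)) if len(groups) >= 3 else ()
    return TestResult(
        "kruskal_wallis", kw.statistic, kw.p_value, df=kw.df, pairwise=pairwise
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    The exact null distribution is used for min(n, m) ≤ 8 without ties;
    otherwise the normal approximation with tie and continuity correction.
    The reported U is for the first sample.
    """
    xa, ya = _check_groups([x, y], 2)
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(xa.size, ya.size) <= EXACT_MWU_MAX_N and not has_ties
    res = _sps.mannwhitneyu(
        xa, ya,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality gateway (delegated pass-through)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    stat, p = _sps.shapiro(v)
    return TestResult("shapiro_wilk", float(stat), float(p))


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray        # observations × components
    loadings: np.ndarray      # variables × components
    explained_variance_ratio: np.ndarray
    row_ids: tuple[str, ...] = ()
    columns: tuple[str, ...] = ()


def pca_scores(
    matrix: np.ndarray,
    n_components: int = 2,
    row_ids: Sequence[str] = (),
    columns: Sequence[str] = (),
) -> PCAResult:
    """PCA on a cigarettes × compounds content matrix.

    Missing/ND entries must already be encoded as 0 (no defined content);
    columns are centered and scaled to unit variance before decomposition,
    with constant columns left centered only.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("encode ND entries as 0 before PCA")
    n_components = min(n_components, min(X.shape))
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xs)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        row_ids=tuple(row_ids),
        columns=tuple(columns),
    )


def content_matrix(
    records: Iterable[ContentRecord],
) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Cigarette × compound matrix of total contents plus class labels.

    ND cells are 0. Returns (matrix, cigarette_ids, compound_names,
    has_capsule flags).
    """
    totals: dict[str, dict[str, float]] = {}
    classes: dict[str, bool] = {}
    compounds: set[str] = set()
    for r in records:
        row = totals.setdefault(r.cigarette_id, {})
        row[r.compound] = row.get(r.compound, 0.0) + r.content_ug_per_cigarette
        classes[r.cigarette_id] = r.has_capsule
        compounds.add(r.compound)
    ids = sorted(totals)
    names = sorted(compounds)
    X = np.array(
        [[totals[c].get(n, 0.0) for n in names] for c in ids], dtype=float
    )
    flags = np.array([classes[c] for c in ids])
    return X, ids, names, flags
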