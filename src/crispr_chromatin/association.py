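"""Statistical association of gene features with mutagenesis efficiency.

The reported statistic throughout is the Spearman rank correlation between
a per-gene feature (stage-wise RPKM, ATAC coefficient, methylation
coefficient, promoter score) and the per-gene mean mutagenesis efficiency,
with a two-sided p-value from the t approximation
``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom.  Expression
categories (low vs expressed across the early-development window; RPKM
increase across the maternal-to-zygotic transition) feed 2x2 Fisher exact
tests, and guide GC content is compared between functional and
non-functional guides with a Mann-Whitney U test.

The heavy lifting is delegated to scipy.stats; this module owns the
complete-case bookkeeping, tie and degenerate-input policy, and the result
container.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import STAGES, EfficiencyRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_LOW_RPKM = 0.5

#: stage window of the low-expression classification (oblong-sphere..15-somite)
LOW_EXPRESSION_WINDOW = ("oblong-sphere", "50%-epiboly", "15-somite")


class InsufficientDataError(ValueError):
    """Too few complete pairs for the requested statistic."""


class UndefinedCorrelationError(ValueError):
    """A constant input vector makes the rank correlation undefined."""


@dataclass(frozen=True)
class AssociationResult:
    feature_name: str
    stage_or_timepoint: str
    statistic_name: str  # spearman_rho | mann_whitney_U | odds_ratio
    statistic: float
    n: int
    p_value: float
    significant: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (group A / group B) x (category 1 / category 2)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def aggregate_efficiency(
    records: Iterable[EfficiencyRecord], method: str = "mean"
) -> dict[str, float]:
    """Per-gene efficiency aggregated over guides (mean by default)."""
    by_gene: dict[str, list[float]] = {}
    for r in records:
        if r.efficiency is None:
            continue
        by_gene.setdefault(r.gene_id, []).append(r.efficiency)
    agg = np.mean if method == "mean" else np.median
    if method not in {"mean", "median"}:
        raise ValueError(f"unknown aggregation {method!r}")
    return {g: float(agg(v)) for g, v in by_gene.items()}


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    feature_name: str = "",
    stage: str = "",
    alpha: float = DEFAULT_ALPHA,
    exact: bool = False,
) -> AssociationResult:
    """Spearman rank correlation with two-sided p-value.

    Pairs with a missing value are dropped first; the complete-case n is
    recorded in the result.  The p-value uses the t approximation; with
    ``exact=True`` and n <= 10 it is replaced by full permutation
    enumeration.  rho = ±1 returns p = 0.
    """
    xv, yv = _complete_pairs(x, y)
    n = len(xv)
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("zero variance in an input vector")
    if n < 10 and not exact:
        logger.info("Spearman t-approximation used at small n=%d", n)
    rho, p = stats.spearmanr(xv, yv)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-14:  # perfect ranking up to float round-off
        rho = 1.0 if rho > 0 else -1.0
        p = 0.0
    elif exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        p = _spearman_exact_p(xv, yv, rho)
    return AssociationResult(
        feature_name, stage, "spearman_rho", rho, n, float(p),
        significant=float(p) < alpha,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of y-permutations with |rho| >= |obs|."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c ** 2).sum())
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk_perms: list[tuple[int, ...]]) -> int:
        perms = np.array(chunk_perms)
        ry_p = ry[perms]
        ry_c = ry_p - ry_p.mean(axis=1, keepdims=True)
        denom_y = np.sqrt((ry_c ** 2).sum(axis=1))
        rhos = (ry_c * rx_c).sum(axis=1) / (denom_x * denom_y)
        return int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    feature_name: str = "",
    stage: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> AssociationResult:
    """Two-sided Mann-Whitney U test.

    The statistic is U for the first group (``a`` entirely below ``b``
    gives U = 0).  For min(n_a, n_b) <= 8 without ties the p-value is exact
    by enumeration; otherwise the tie-corrected normal approximation is
    used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return AssociationResult(
        feature_name, stage, "mann_whitney_U", float(res.statistic),
        int(a.size + b.size), float(res.pvalue),
        significant=float(res.pvalue) < alpha,
    )


def fisher_exact(
    table: ContingencyTable2x2,
    feature_name: str = "",
    stage: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p is the sum of hypergeometric probabilities of all margin-consistent
    tables at most as probable as the observed one.  The statistic is the
    sample odds ratio a*d / (b*c); infinity for a zero in b or c with
    non-zero numerator, NaN for 0/0.
    """
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    num = table.a * table.d
    den = table.b * table.c
    if den > 0:
        oratio = num / den
    elif num > 0:
        oratio = float("inf")
        logger.warning("odds ratio infinite (zero cell in denominator)")
    else:
        oratio = float("nan")
        logger.warning("odds ratio undefined (0/0)")
    n = int(arr.sum())
    return AssociationResult(
        feature_name, stage, "odds_ratio", oratio, n, float(p),
        significant=float(p) < alpha,
    )


def classify_expression(
    rpkm_by_stage: Mapping[str, float],
    low_threshold: float = DEFAULT_LOW_RPKM,
    window: Sequence[str] = LOW_EXPRESSION_WINDOW,
) -> str:
    """'low' iff RPKM < threshold at every window stage, else 'expressed'.

    A value exactly at the threshold counts as expressed (strict <).
    Missing window stages raise KeyError so callers can exclude the gene.
    """
    for stage in window:
        if stage not in rpkm_by_stage:
            raise KeyError(f"stage {stage!r} missing from expression profile")
    return "low" if all(rpkm_by_stage[s] < low_threshold for s in window) else "expressed"


def mzt_change(rpkm_oblong: float, rpkm_epiboly: float) -> str:
    """'increased' iff RPKM strictly rises from oblong-sphere to 50%-epiboly."""
    if np.isnan(rpkm_oblong) or np.isnan(rpkm_epiboly):
        raise ValueError("missing RPKM value")
    return "increased" if rpkm_epiboly - rpkm_oblong > 0 else "not_increased"


RPKM_PREFIX = "rpkm_"

#: chromatin feature columns correlated against efficiency, with the
#: timepoint label each is reported under
CHROMATIN_FEATURES = {
    "atac_coefficient": "4hpf",
    "methylation_coefficient": "1-cell",
    "promoter_score": "75-80%-epiboly",
}


def correlate_all(
    features: pd.DataFrame,
    stages: Sequence[str] = STAGES,
    alpha: float = DEFAULT_ALPHA,
    exact: bool = False,
) -> list[AssociationResult]:
    """Spearman correlation of every requested feature against efficiency.

    ``features`` is the joined per-gene table with an ``efficiency`` column,
    ``rpkm_<stage>`` expression columns and the chromatin feature columns.
    One result per (feature, stage) pair, each with its own complete-case n.
    """
    if "efficiency" not in features.columns:
        raise ValueError("feature table lacks an 'efficiency' column")
    eff = features["efficiency"].to_numpy(dtype=float)
    results: list[AssociationResult] = []

    def _try(vals, name, label):
        try:
            results.append(
                spearman(vals, eff, feature_name=name, stage=label,
                         alpha=alpha, exact=exact)
            )
        except (InsufficientDataError, UndefinedCorrelationError) as exc:
            logger.warning("correlation %s/%s skipped: %s", name, label, exc)

    for stage in stages:
        col = RPKM_PREFIX + stage
        if col not in features.columns:
            logger.warning("no expression column for stage %s; skipped", stage)
            continue
        _try(features[col].to_numpy(dtype=float), "expression", stage)
    for col, label in CHROMATIN_FEATURES.items():
        if col not in features.columns:
            continue
        _try(features[col].to_numpy(dtype=float), col, label)
    return results
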