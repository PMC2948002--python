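"""Between-group divergence: rank-sum tests with Dunn-Sidak family-wise
control, and between-habitat F_ST aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecocline import morphometrics

__all__ = [
    "RankSumResult",
    "DivergenceResult",
    "FstSummary",
    "wilcoxon_rank_sum",
    "dunn_sidak",
    "habitat_divergence",
    "era_divergence",
    "fst_between_habitat_summary",
    "results_frame",
]

LOWLAND_HABITATS = frozenset({"forest", "ecotone"})


@dataclass
class RankSumResult:
    W: float  # rank-sum statistic of the first sample
    p_two_sided: float
    method: str  # exact | approx


def wilcoxon_rank_sum(x, y, method: str = "auto") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    ``method='auto'`` uses the exact null distribution when the smaller
    group has <= 10 observations and there are no ties, and otherwise the
    normal approximation with tie and continuity corrections.  W is the
    rank sum of ``x`` in the pooled ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if min(len(x), len(y)) <= 10 and not has_ties else "approx"
    if method == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif method == "approx":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankSumResult(W=w, p_two_sided=float(res.pvalue), method=method)


def dunn_sidak(alpha: float, m: int) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/m) for m tests in a family."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


@dataclass
class DivergenceResult:
    trait: str
    scope: str  # region (habitat comparisons) or era (region comparisons)
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    ses: tuple[float, float]
    W: float
    p_two_sided: float
    alpha_corrected: float
    significant: bool


def results_frame(results: list[DivergenceResult]) -> pd.DataFrame:
    """Flatten a list of divergence results into a tidy frame."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "scope": [r.scope for r in results],
            "group_a": [r.groups[0] for r in results],
            "group_b": [r.groups[1] for r in results],
            "n_a": [r.n[0] for r in results],
            "n_b": [r.n[1] for r in results],
            "mean_a": [r.means[0] for r in results],
            "mean_b": [r.means[1] for r in results],
            "se_a": [r.ses[0] for r in results],
            "se_b": [r.ses[1] for r in results],
            "W": [r.W for r in results],
            "p": [r.p_two_sided for r in results],
            "alpha_corrected": [r.alpha_corrected for r in results],
            "significant": [r.significant for r in results],
        }
    )


def _group_stats(v: np.ndarray) -> tuple[int, float, float]:
    n = len(v)
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return n, float(np.mean(v)), se


def _compare(
    trait: str,
    scope: str,
    labels: tuple[str, str],
    va: np.ndarray,
    vb: np.ndarray,
    alpha_corrected: float,
    method: str,
) -> DivergenceResult:
    na, ma, sa = _group_stats(va)
    nb, mb, sb = _group_stats(vb)
    rs = wilcoxon_rank_sum(va, vb, method=method)
    return DivergenceResult(
        trait=trait,
        scope=scope,
        groups=labels,
        n=(na, nb),
        means=(ma, mb),
        ses=(sa, sb),
        W=rs.W,
        p_two_sided=rs.p_two_sided,
        alpha_corrected=alpha_corrected,
        significant=rs.p_two_sided <= alpha_corrected,
    )


def habitat_divergence(
    table: pd.DataFrame,
    region: str,
    traits: list[str],
    alpha: float = 0.05,
    method: str = "auto",
) -> list[DivergenceResult]:
    """Forest-vs-ecotone rank-sum tests for each trait column, within a region.

    The family-wise threshold is Dunn-Sidak corrected for the number of
    traits tested.  Only continental lowland forest and ecotone rows are
    accepted; montane or island rows must be removed by the caller first.
    """
    sub = table[table["region"] == region]
    bad = set(sub["habitat"].unique()) - LOWLAND_HABITATS
    if bad:
        raise ValueError(
            f"only forest/ecotone rows are allowed, found {sorted(bad)}; "
            "restrict to lowland sites first"
        )
    forest = sub[sub["habitat"] == "forest"]
    ecotone = sub[sub["habitat"] == "ecotone"]
    if len(forest) == 0 or len(ecotone) == 0:
        raise ValueError(f"both habitats must be present in region {region!r}")
    alpha_c = dunn_sidak(alpha, len(traits))
    results = []
    for trait in traits:
        va = forest[trait].dropna().to_numpy(dtype=float)
        vb = ecotone[trait].dropna().to_numpy(dtype=float)
        results.append(
            _compare(trait, region, ("forest", "ecotone"), va, vb, alpha_c, method)
        )
    return results


def era_divergence(
    contemp: pd.DataFrame,
    historical: pd.DataFrame,
    traits: list[str],
    alpha: float = 0.05,
    correct: bool = False,
    sc_gate: bool = True,
    method: str = "auto",
) -> list[DivergenceResult]:
    """Between-region rank-sum tests within each era, on rainforest rows only.

    For the historical era, size-corrected traits (``<base>_sc``) are
    omitted when the underlying log-log size-correction regression is not
    significant on the historical sample (``sc_gate``).  Tests are
    uncorrected by default (``correct=False``); pass ``correct=True`` for a
    Dunn-Sidak family threshold.
    """
    results = []
    for era, tbl in (("contemporary", contemp), ("historical", historical)):
        if len(tbl) == 0:
            raise ValueError(f"{era} table is empty")
        sub = tbl[tbl["habitat"] == "forest"]
        regions = sorted(sub["region"].unique())
        if len(regions) < 2:
            raise ValueError(f"{era} era has a single region; two required")
        if len(regions) > 2:
            raise ValueError(f"{era} era has more than two regions")
        era_traits = list(traits)
        if era == "historical" and sc_gate:
            for trait in traits:
                if trait.endswith("_sc"):
                    base = trait[: -len("_sc")]
                    if morphometrics.size_correct(sub, base).p_value >= 0.05:
                        era_traits.remove(trait)
        alpha_c = dunn_sidak(alpha, len(era_traits)) if correct else alpha
        a, b = regions
        for trait in era_traits:
            va = sub.loc[sub["region"] == a, trait].dropna().to_numpy(dtype=float)
            vb = sub.loc[sub["region"] == b, trait].dropna().to_numpy(dtype=float)
            results.append(_compare(trait, era, (a, b), va, vb, alpha_c, method))
    return results


@dataclass
class FstSummary:
    region: str | None
    mean_fst: float
    se_fst: float  # NaN when undefined
    se_defined: bool
    fst_range: tuple[float, float]
    n_pairs: int


def fst_between_habitat_summary(
    pairwise: pd.DataFrame | np.ndarray,
    habitat_of: dict | pd.Series,
    region: str | None = None,
    populations: list[str] | None = None,
) -> FstSummary:
    """Mean, SE and range of pairwise F_ST over between-habitat pairs.

    ``pairwise`` is a symmetric matrix (diagonal ignored); only pairs whose
    two populations carry different habitat labels contribute.  SE is
    sd/sqrt(n_pairs) and is flagged undefined for a single pair.
    """
    if isinstance(pairwise, pd.DataFrame):
        pops = list(pairwise.index)
        mat = pairwise.to_numpy(dtype=float)
    else:
        mat = np.asarray(pairwise, dtype=float)
        if populations is None:
            raise ValueError("populations required for an array matrix")
        pops = list(populations)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != len(pops):
        raise ValueError("matrix must be square and match the population list")
    if not np.allclose(mat, mat.T, atol=1e-8, equal_nan=True):
        raise ValueError("F_ST matrix must be symmetric")
    habitat = pd.Series(habitat_of)

    vals = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if habitat[pops[i]] != habitat[pops[j]]:
                v = mat[i, j]
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"F_ST value {v} outside [0, 1]")
                vals.append(v)
    if not vals:
        raise ValueError("no between-habitat population pair in the matrix")
    vals = np.asarray(vals)
    n = len(vals)
    se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return FstSummary(
        region=region,
        mean_fst=float(vals.mean()),
        se_fst=se,
        se_defined=n > 1,
        fst_range=(float(vals.min()), float(vals.max())),
        n_pairs=n,
    )
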