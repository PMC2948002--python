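"""Trait transforms, covariance-structure gating, and principal components.

All analyses operate on log-transformed traits.  Pooling regions into one
PCA is gated on the region covariance matrices being equal or proportional
(likelihood-ratio tests against the unrestricted two-matrix model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SizeCorrection",
    "LrtResult",
    "CovStructResult",
    "PcaModel",
    "CovarianceGateError",
    "size_correct",
    "covariance_structure_test",
    "pooled_pca",
    "normalize_scores",
    "filter_historical",
    "add_derived_traits",
]

log = logging.getLogger(__name__)

#: traits never size-corrected (feeding performance depends on absolute bill size)
SIZE_CORRECTION_EXCLUDED = ("tarsus", "upper_mandible")


class CovarianceGateError(ValueError):
    """Pooled PCA refused: region covariances neither equal nor proportional."""


# ---------------------------------------------------------------------------
# size correction
# ---------------------------------------------------------------------------


@dataclass
class SizeCorrection:
    trait: str
    residuals: pd.Series  # aligned to the input index
    slope: float
    intercept: float
    p_value: float
    stderr: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def size_correct(table: pd.DataFrame, trait: str) -> SizeCorrection:
    """Residuals of log(trait) on log(tarsus), with the fitted regression.

    The regression p-value is reported so callers can skip size-corrected
    analyses when the allometric relationship is not significant.
    """
    if trait in SIZE_CORRECTION_EXCLUDED:
        raise ValueError(f"{trait!r} is never size-corrected")
    if trait not in table.columns:
        raise KeyError(trait)
    sub = table[[trait, "tarsus"]].dropna()
    if len(sub) < 3:
        raise ValueError("size correction needs >= 3 individuals")
    x = np.log(sub["tarsus"].to_numpy(dtype=float))
    y = np.log(sub[trait].to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    resid = pd.Series(y - (fit.intercept + fit.slope * x), index=sub.index, name=f"{trait}_sc")
    return SizeCorrection(
        trait=trait,
        residuals=resid,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(sub),
    )


# ---------------------------------------------------------------------------
# covariance structure (equality / proportionality hierarchy)
# ---------------------------------------------------------------------------


@dataclass
class LrtResult:
    statistic: float
    dof: int
    p_value: float


@dataclass
class CovStructResult:
    lrt_equality: LrtResult
    lrt_proportionality: LrtResult
    proportionality_constant: float
    verdict: str  # equal | proportional | neither
    alpha: float = 0.05


def _mle_cov(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    return xc.T @ xc / len(x)


def _logdet_pd(s: np.ndarray, what: str) -> float:
    sign, ld = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError(f"{what} covariance is singular or not positive definite")
    return float(ld)


def covariance_structure_test(
    x1: np.ndarray,
    x2: np.ndarray,
    alpha: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> CovStructResult:
    """Likelihood-ratio tests of equality and proportionality of two
    covariance matrices (samples on the log scale, rows = individuals).

    Equality: -2 log Lambda comparing the pooled-covariance MLE against
    separate MLEs, chi-squared with p(p+1)/2 dof.  Proportionality: ML under
    Sigma_2 = rho * Sigma_1 with rho estimated by fixed-point iteration
    (rho <- tr(Sigma^-1 S_2)/p), chi-squared with p(p+1)/2 - 1 dof.  The
    verdict is sequential at ``alpha``: equal if equality is not rejected,
    else proportional if proportionality is not rejected, else neither.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.ndim != 2 or x2.ndim != 2 or x1.shape[1] != x2.shape[1]:
        raise ValueError("inputs must be n x p matrices with matching p")
    p = x1.shape[1]
    n1, n2 = len(x1), len(x2)
    if n1 <= p or n2 <= p:
        raise ValueError("each region needs n > number of traits")
    s1, s2 = _mle_cov(x1), _mle_cov(x2)
    ld1 = _logdet_pd(s1, "region 1")
    ld2 = _logdet_pd(s2, "region 2")
    n = n1 + n2

    # equality
    pooled = (n1 * s1 + n2 * s2) / n
    ld_pooled = _logdet_pd(pooled, "pooled")
    stat_eq = max(0.0, n1 * (ld_pooled - ld1) + n2 * (ld_pooled - ld2))
    dof_eq = p * (p + 1) // 2
    lrt_eq = LrtResult(stat_eq, dof_eq, float(stats.chi2.sf(stat_eq, dof_eq)))

    # proportionality: Sigma_2 = rho * Sigma, Sigma_1 = Sigma
    rho = 1.0
    for _ in range(max_iter):
        sigma = (n1 * s1 + n2 * s2 / rho) / n
        rho_new = float(np.trace(np.linalg.solve(sigma, s2)) / p)
        if abs(rho_new - rho) / rho < tol:
            rho = rho_new
            break
        rho = rho_new
    sigma = (n1 * s1 + n2 * s2 / rho) / n
    ld_sigma = _logdet_pd(sigma, "proportional-model")
    stat_prop = max(
        0.0,
        n1 * (ld_sigma - ld1) + n2 * (ld_sigma + p * np.log(rho) - ld2),
    )
    dof_prop = dof_eq - 1
    lrt_prop = LrtResult(stat_prop, dof_prop, float(stats.chi2.sf(stat_prop, dof_prop)))

    if lrt_eq.p_value >= alpha:
        verdict = "equal"
    elif lrt_prop.p_value >= alpha:
        verdict = "proportional"
    else:
        verdict = "neither"
    return CovStructResult(lrt_eq, lrt_prop, rho, verdict, alpha)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    """PCA of the covariance matrix of log-transformed traits.

    Loadings are orthonormal eigenvector columns with nonincreasing
    eigenvalues; each component's sign is fixed so that its tarsus loading
    (falling back to the largest-magnitude loading) is positive, making PC1
    an overall-size axis with larger scores = larger birds.
    """

    traits: list[str]
    mean_log: np.ndarray
    loadings: np.ndarray  # p x p, columns = PCs
    eigenvalues: np.ndarray
    scope: str = "pooled"
    sign_convention: str = "tarsus_positive"

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Scores = centered log traits x loadings, one column per PC."""
        x = np.log(table[self.traits].to_numpy(dtype=float))
        scores = (x - self.mean_log) @ self.loadings
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=table.index, columns=cols)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "traits": self.traits,
            "mean_log": self.mean_log.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scope": self.scope,
            "sign_convention": self.sign_convention,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            traits=d["traits"],
            mean_log=np.asarray(d["mean_log"]),
            loadings=np.asarray(d["loadings"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            scope=d["scope"],
            sign_convention=d["sign_convention"],
        )


def _fix_signs(loadings: np.ndarray, traits: list[str]) -> np.ndarray:
    ref = traits.index("tarsus") if "tarsus" in traits else None
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = ref if ref is not None and abs(col[ref]) > 1e-12 else int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def pooled_pca(
    table: pd.DataFrame,
    traits: list[str],
    gate: str | CovStructResult = "auto",
    allow_neither: bool = False,
    alpha: float = 0.05,
    scope: str = "pooled",
) -> tuple[PcaModel, pd.DataFrame]:
    """Eigendecomposition of the log-trait covariance matrix, with scores.

    When the table spans two regions and ``gate='auto'``, the covariance
    structure test is run first and pooling is refused (unless
    ``allow_neither``) if the matrices are neither equal nor proportional.
    Pass ``gate='skip'`` for single-scope PCAs, or a precomputed
    :class:`CovStructResult`.
    """
    x = table[traits].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("traits must be finite and > 0 for the log transform")
    logx = np.log(x)

    verdict = None
    if isinstance(gate, CovStructResult):
        verdict = gate.verdict
    elif gate == "auto" and "region" in table.columns and table["region"].nunique() > 1:
        regions = table["region"].value_counts().index[:2]
        if table["region"].nunique() > 2:
            raise ValueError("auto gate supports exactly two regions; pass a gate")
        res = covariance_structure_test(
            logx[(table["region"] == regions[0]).to_numpy()],
            logx[(table["region"] == regions[1]).to_numpy()],
            alpha=alpha,
        )
        verdict = res.verdict
    if verdict == "neither" and not allow_neither:
        raise CovarianceGateError(
            "region covariance matrices are neither equal nor proportional; "
            "pooling refused (pass allow_neither=True to override)"
        )

    mean = logx.mean(axis=0)
    cov = np.cov(logx, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    evecs = _fix_signs(evecs, list(traits))
    model = PcaModel(
        traits=list(traits),
        mean_log=mean,
        loadings=evecs,
        eigenvalues=evals,
        scope=scope,
    )
    return model, model.transform(table)


def normalize_scores(scores: pd.Series, era: pd.Series) -> pd.Series:
    """Divide scores by the largest |score| within each era, scaling to [-1, 1].

    Eras are normalized independently, so ratios across eras are not
    preserved; this is a display convention for cross-era figures.
    """
    if len(scores) == 0:
        raise ValueError("empty score series")
    out = scores.astype(float).copy()
    for label, idx in scores.groupby(era).groups.items():
        m = scores.loc[idx].abs().max()
        if not m > 0:
            raise ValueError(f"all scores zero in era {label!r}")
        out.loc[idx] = scores.loc[idx] / m
    return out


def filter_historical(table: pd.DataFrame, cutoff_year: int = 1935) -> pd.DataFrame:
    """Keep rows collected strictly before ``cutoff_year`` with a usable
    habitat assignment; drops (and logs) everything else."""
    year = pd.to_numeric(table["collection_year"], errors="coerce")
    has_habitat = table["habitat"].notna()
    keep = year.notna() & (year < cutoff_year) & has_habitat
    n_year = int((~(year.notna() & (year < cutoff_year))).sum())
    n_hab = int((~has_habitat).sum())
    if n_year or n_hab:
        log.info(
            "filter_historical: dropped %d rows (year >= %d or missing: %d; "
            "no habitat: %d) of %d",
            int((~keep).sum()), cutoff_year, n_year, n_hab, len(table),
        )
    return table[keep].copy()


def add_derived_traits(
    table: pd.DataFrame,
    pca: PcaModel | None = None,
    sc_traits: tuple[str, ...] = ("wing", "tail"),
) -> pd.DataFrame:
    """Append log traits, size-corrected residual columns (``<trait>_sc``)
    and, if a PCA model is given, PC score columns."""
    out = table.copy()
    for trait in ("tarsus", "wing", "tail", "upper_mandible"):
        if trait in out.columns:
            out[f"log_{trait}"] = np.log(out[trait].astype(float))
    for trait in sc_traits:
        sc = size_correct(out, trait)
        out[f"{trait}_sc"] = sc.residuals
    if pca is not None:
        scores = pca.transform(out)
        for col in scores.columns:
            out[col] = scores[col]
    return out
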