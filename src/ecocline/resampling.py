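"""Habitat-stratified bootstrap null for "absence of divergence".

Replicates draw, with replacement, the focal region's per-habitat sample
sizes from the reference region's pool of individuals (or whole sites), and
record the absolute forest-ecotone difference in group means.  The p-value
is the proportion of replicates with divergence at or below the observed
focal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecocline._rng import substream
from ecocline.synthetic_data import TraitGenModel, _draw_log_traits

__all__ = [
    "BootstrapP",
    "BootstrapResult",
    "CalibrationConfig",
    "stratified_bootstrap_null",
    "population_bootstrap_null",
    "bootstrap_p",
    "observed_divergence",
    "run_bootstrap_test",
    "calibrate_null",
]


def _habitat_values(table: pd.DataFrame, trait: str, habitat: str) -> np.ndarray:
    vals = table.loc[table["habitat"] == habitat, trait].dropna().to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError(f"habitat {habitat!r} absent from the source table")
    return vals


def observed_divergence(table: pd.DataFrame, trait: str) -> float:
    """|mean(forest) - mean(ecotone)| of a trait column."""
    f = _habitat_values(table, trait, "forest")
    e = _habitat_values(table, trait, "ecotone")
    return float(abs(f.mean() - e.mean()))


def stratified_bootstrap_null(
    source: pd.DataFrame,
    n_forest: int,
    n_ecotone: int,
    trait: str,
    B: int,
    seed: int,
    identity_resample: bool = False,
) -> np.ndarray:
    """B bootstrap replicates of |forest mean - ecotone mean| from ``source``.

    Each replicate draws ``n_forest`` forest and ``n_ecotone`` ecotone
    individuals with replacement from the source region's pools.
    ``identity_resample`` is a testing hook: each replicate is the source
    itself (counts must match the pool sizes).
    """
    if n_forest < 1 or n_ecotone < 1:
        raise ValueError("target counts must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    f = _habitat_values(source, trait, "forest")
    e = _habitat_values(source, trait, "ecotone")
    if identity_resample:
        if n_forest != len(f) or n_ecotone != len(e):
            raise ValueError("identity resample requires counts equal to pool sizes")
        return np.full(B, abs(f.mean() - e.mean()))
    rng = substream(seed, f"bootstrap:{trait}")
    fi = rng.integers(0, len(f), size=(B, n_forest))
    ei = rng.integers(0, len(e), size=(B, n_ecotone))
    return np.abs(f[fi].mean(axis=1) - e[ei].mean(axis=1))


def population_bootstrap_null(
    source: pd.DataFrame,
    site_counts: dict[str, int],
    trait: str,
    B: int,
    seed: int,
    replace: bool = True,
) -> np.ndarray:
    """Whole-site bootstrap: replicates resample sites (with all their
    individuals) per habitat to match the focal region's site counts."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = substream(seed, f"popbootstrap:{trait}")
    pools: dict[str, list[np.ndarray]] = {}
    for habitat, k in site_counts.items():
        if k < 1:
            raise ValueError("site counts must be >= 1")
        sub = source[source["habitat"] == habitat]
        if len(sub) == 0:
            raise ValueError(f"habitat {habitat!r} absent from the source table")
        groups = [
            g[trait].dropna().to_numpy(dtype=float)
            for _, g in sub.groupby("site_id", sort=True)
        ]
        if not replace and len(groups) < k:
            raise ValueError(
                f"{len(groups)} distinct {habitat} sites < {k} requested "
                "(without replacement)"
            )
        pools[habitat] = groups
    habitats = list(site_counts)
    if set(habitats) != {"forest", "ecotone"}:
        raise ValueError("site_counts must cover exactly forest and ecotone")

    null = np.empty(B)
    for b in range(B):
        means = {}
        for habitat in ("forest", "ecotone"):
            groups = pools[habitat]
            k = site_counts[habitat]
            idx = (
                rng.integers(0, len(groups), size=k)
                if replace
                else rng.choice(len(groups), size=k, replace=False)
            )
            vals = np.concatenate([groups[i] for i in idx])
            means[habitat] = vals.mean()
        null[b] = abs(means["forest"] - means["ecotone"])
    return null


@dataclass
class BootstrapP:
    p: float
    report: str


def bootstrap_p(null: np.ndarray, observed: float) -> BootstrapP:
    """p = proportion of null replicates <= observed; '<1/B' style when 0."""
    null = np.asarray(null, dtype=float)
    if len(null) == 0:
        raise ValueError("empty null distribution")
    p = float((null <= observed).mean())
    if p == 0.0:
        report = f"p < {1.0 / len(null):g}"
    else:
        report = f"p = {p:.3g}"
    return BootstrapP(p=p, report=report)


@dataclass
class BootstrapResult:
    trait: str
    observed_abs_divergence: float
    B: int
    null_distribution: np.ndarray = field(repr=False)
    p: float
    report: str
    seed: int
    level: str  # individual | population


def run_bootstrap_test(
    source: pd.DataFrame,
    focal: pd.DataFrame,
    trait: str,
    B: int,
    seed: int,
    level: str = "individual",
    site_counts: dict[str, int] | None = None,
) -> BootstrapResult:
    """Full bootstrap test: observed focal divergence vs reference null.

    ``level='individual'`` matches the focal region's per-habitat individual
    counts; ``level='population'`` resamples whole sites to match its
    per-habitat site counts (pass ``site_counts`` to override).
    """
    observed = observed_divergence(focal, trait)
    if level == "individual":
        n_f = int((focal["habitat"] == "forest").sum())
        n_e = int((focal["habitat"] == "ecotone").sum())
        null = stratified_bootstrap_null(source, n_f, n_e, trait, B, seed)
    elif level == "population":
        if site_counts is None:
            site_counts = {
                h: focal.loc[focal["habitat"] == h, "site_id"].nunique()
                for h in ("forest", "ecotone")
            }
        null = population_bootstrap_null(source, site_counts, trait, B, seed)
    else:
        raise ValueError(f"unknown level {level!r}")
    bp = bootstrap_p(null, observed)
    return BootstrapResult(
        trait=trait,
        observed_abs_divergence=observed,
        B=B,
        null_distribution=null,
        p=bp.p,
        report=bp.report,
        seed=seed,
        level=level,
    )


# ---------------------------------------------------------------------------
# calibration harness
# ---------------------------------------------------------------------------


@dataclass
class CalibrationConfig:
    """Generator shared by focal and reference regions for size/power checks.

    The focal dataset is drawn with (``focal_n_forest``, ``focal_n_ecotone``)
    individuals at the two cover levels, the reference pool with the larger
    source counts; ``focal_divergence_scale`` rescales the focal region's
    forest-ecotone mean separation (1 = same process as reference, 0 = no
    divergence, for power checks).
    """

    model: TraitGenModel
    trait: str = "wing"
    cover_forest: float = 85.0
    cover_ecotone: float = 30.0
    source_n_forest: int = 100
    source_n_ecotone: int = 100
    focal_n_forest: int = 27
    focal_n_ecotone: int = 11
    focal_divergence_scale: float = 1.0


def _draw_pool(
    cfg: CalibrationConfig,
    n_forest: int,
    n_ecotone: int,
    rng: np.random.Generator,
    divergence_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    ti = list(cfg.model.traits).index(cfg.trait)
    mid = 0.5 * (cfg.cover_forest + cfg.cover_ecotone)
    cf = mid + divergence_scale * (cfg.cover_forest - mid)
    ce = mid + divergence_scale * (cfg.cover_ecotone - mid)
    f = _draw_log_traits(cfg.model, cf, None, n_forest, rng)[:, ti]
    e = _draw_log_traits(cfg.model, ce, None, n_ecotone, rng)[:, ti]
    return f, e


def calibrate_null(
    cfg: CalibrationConfig,
    B: int,
    n_sims: int,
    seed: int,
    alphas: tuple[float, ...] = (0.05,),
) -> pd.DataFrame:
    """Simulate focal datasets and report bootstrap rejection rates.

    Each simulation draws a reference pool and a focal dataset (log-scale
    trait values), runs the stratified bootstrap null at size B, and records
    the bootstrap p.  Returns a frame of rejection rates per alpha with the
    simulated p-values attached in ``attrs['p_values']``.
    """
    if B < 1 or n_sims < 1:
        raise ValueError("B and n_sims must be >= 1")
    rng = substream(seed, "calibration")
    pvals = np.empty(n_sims)
    for s in range(n_sims):
        src_f, src_e = _draw_pool(cfg, cfg.source_n_forest, cfg.source_n_ecotone, rng)
        foc_f, foc_e = _draw_pool(
            cfg,
            cfg.focal_n_forest,
            cfg.focal_n_ecotone,
            rng,
            divergence_scale=cfg.focal_divergence_scale,
        )
        observed = abs(foc_f.mean() - foc_e.mean())
        fi = rng.integers(0, len(src_f), size=(B, cfg.focal_n_forest))
        ei = rng.integers(0, len(src_e), size=(B, cfg.focal_n_ecotone))
        null = np.abs(src_f[fi].mean(axis=1) - src_e[ei].mean(axis=1))
        pvals[s] = (null <= observed).mean()
    out = pd.DataFrame(
        {
            "alpha": list(alphas),
            "rejection_rate": [float((pvals <= a).mean()) for a in alphas],
            "n_sims": n_sims,
            "B": B,
        }
    )
    out.attrs["p_values"] = pvals
    return out
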