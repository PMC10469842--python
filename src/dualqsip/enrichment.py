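"""Downstream statistics on atom-fraction-excess tables.

Covers the C/N enrichment partition (the Venn of taxa enriched in
13C, 15N, or both), standardized major axis (model II) regression of
AFE-N on AFE-C for co-enriched taxa, ordinary least squares contrasts
of community AFE against necromass melanin level and decomposition
stage, and rarefaction of community count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .qsip import AfeEstimate


@dataclass(frozen=True)
class EnrichmentPartition:
    """Counts of taxa enriched in C only, N only, or both."""

    domain_label: str
    set_c: frozenset
    set_n: frozenset

    @property
    def c_only(self) -> int:
        return len(self.set_c - self.set_n)

    @property
    def n_only(self) -> int:
        return len(self.set_n - self.set_c)

    @property
    def both(self) -> int:
        return len(self.set_c & self.set_n)

    @property
    def union(self) -> int:
        return len(self.set_c | self.set_n)

    @property
    def pct_c(self) -> int:
        """Percent of all enriched taxa that are C-enriched (nearest integer)."""
        return round(100 * len(self.set_c) / self.union) if self.union else 0

    @property
    def pct_n(self) -> int:
        return round(100 * len(self.set_n) / self.union) if self.union else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain": self.domain_label,
                    "c_only": self.c_only,
                    "n_only": self.n_only,
                    "both": self.both,
                    "union": self.union,
                    "pct_c": self.pct_c,
                    "pct_n": self.pct_n,
                }
            ]
        )


def partition_enrichment(
    afe_c: Sequence[AfeEstimate],
    afe_n: Sequence[AfeEstimate],
    domain_label: str = "",
) -> EnrichmentPartition:
    """Partition taxa by which isotope(s) they were retained for."""
    return EnrichmentPartition(
        domain_label=domain_label,
        set_c=frozenset(e.taxon_id for e in afe_c if e.retained),
        set_n=frozenset(e.taxon_id for e in afe_n if e.retained),
    )


# ---------------------------------------------------------------------------
# Standardized major axis (model II) regression


@dataclass(frozen=True)
class SmaFit:
    slope: float
    intercept: float
    r: float
    n: int
    ci_low: float
    ci_high: float

    @property
    def x_intercept(self) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("slope is zero; no x intercept")
        return -self.intercept / self.slope


def sma_regression(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> SmaFit:
    """Standardized major axis fit of y on x.

    The SMA line accommodates error in both variables:
    slope = sign(r) * sd(y)/sd(x), and the line passes through the
    centroid. The slope confidence interval is a percentile bootstrap
    over case resamples. When r is exactly 0 the slope sign defaults
    to positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")

    slope, intercept, r = _sma_point(x, y)
    if n_boot == 0:
        return SmaFit(slope, intercept, float(r), int(x.size), float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    idx = np.arange(x.size)
    for b in range(n_boot):
        take = rng.choice(idx, size=x.size, replace=True)
        xb, yb = x[take], y[take]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b], _, _ = _sma_point(xb, yb)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return SmaFit(slope, intercept, float(r), int(x.size), float(lo), float(hi))


def _sma_point(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    r = np.corrcoef(x, y)[0, 1]
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept), float(r)


def simulate_coenrichment(
    slope: float,
    n: int,
    seed: int,
    noise_sd: float = 0.05,
    latent_sd: float = 0.15,
    mean_x: float = 0.35,
    mean_y: float = 0.30,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate (AFE-C, AFE-N) data with a known population SMA slope.

    Latent points lie exactly on a line; independent Gaussian noise of
    equal sd is then added to both axes. The latent slope is
    pre-corrected so that after the noise the population sd(y)/sd(x) —
    and hence the population SMA slope — equals ``slope`` exactly.
    """
    if slope <= 0:
        raise ValueError("population slope must be positive")
    var_x = latent_sd**2 + noise_sd**2
    latent_var_y = slope**2 * var_x - noise_sd**2
    if latent_var_y <= 0:
        raise ValueError("noise too large for the requested slope")
    rng = np.random.default_rng(seed)
    t = rng.normal(0.0, 1.0, size=n)
    x = mean_x + latent_sd * t + rng.normal(0.0, noise_sd, size=n)
    y = mean_y + np.sqrt(latent_var_y) * t + rng.normal(0.0, noise_sd, size=n)
    return x, y


# ---------------------------------------------------------------------------
# Community-level AFE contrasts


@dataclass(frozen=True)
class AfeModelFit:
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared_adj: float
    direction: dict


def community_afe_model(
    afe_values: np.ndarray,
    melanin: Sequence[str],
    stage: Sequence[str],
) -> AfeModelFit:
    """OLS of per-taxon AFE on melanin level and decomposition stage.

    Both predictors are binary indicators: ``melanin_low`` is 1 for low
    melanin necromass (expected positive effect on enrichment) and
    ``stage_later`` is 1 at the later stage (expected negative).
    """
    afe = np.asarray(afe_values, dtype=float)
    mel = pd.Series(melanin, dtype="string")
    stg = pd.Series(stage, dtype="string")
    if mel.nunique() < 2 or stg.nunique() < 2:
        raise ValueError("need both levels of each predictor")
    X = pd.DataFrame(
        {
            "melanin_low": (mel == "low").astype(float).to_numpy(),
            "stage_later": (stg == "later").astype(float).to_numpy(),
        }
    )
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(afe, X).fit()
    direction = {
        "higher_melanin_level": "low" if fit.params["melanin_low"] > 0 else "high",
        "higher_stage": "later" if fit.params["stage_later"] > 0 else "earlier",
    }
    return AfeModelFit(
        params=fit.params,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        rsquared_adj=float(fit.rsquared_adj),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(
    counts: Mapping[str, int], depth: int, seed: int
) -> dict[str, int]:
    """Subsample a count table to a fixed depth without replacement.

    Raises ``ValueError`` when the sample has fewer reads than the
    requested depth (such samples are excluded upstream).
    """
    taxa = list(counts.keys())
    values = np.array([counts[t] for t in taxa], dtype=np.int64)
    if np.any(values < 0):
        raise ValueError("negative counts")
    total = int(values.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(values, depth)
    return {t: int(c) for t, c in zip(taxa, sub)}
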