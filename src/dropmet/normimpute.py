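"""Internal-standard normalization and left-censored (QRILC-style) imputation.

Abundances are expressed as ratios to the cinnamic-acid internal standard
spiked into the extraction solvent, which cancels per-sample extraction and
injection scale. Missing values are treated as *not missing at random*: a
value is absent because it fell below the detection limit, i.e. the
observed values of a metabolite are the upper part of a left-censored
distribution. Imputation therefore fits a normal distribution to the
log-scale observed values by maximum likelihood under left-censoring at the
per-metabolite observed minimum, and draws imputations from that normal
truncated above at the censor point. Metabolites missing in more than 20%
of samples are excluded from multivariate statistics (but kept for
univariate time-profile exports).

The censored fit is exposed statsmodels-style as
``CensoredNormalMLE(observed, n_censored, limit).fit()`` returning a results
object carrying the estimates, the log-likelihood and the sampler for
truncated imputation draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .panel import INTERNAL_STANDARD_NAME

logger = logging.getLogger(__name__)


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites normalized abundances with metadata join.

    ``values`` holds dimensionless IS-ratios (or their logs when
    ``log_scale``); missing entries are NaN and the mask view is derived
    from them. Metadata covers every sample row.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing_meta = set(self.values.index) - set(self.metadata.index)
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {sorted(missing_meta)[:5]} ...")
        if not self.log_scale and (self.values < 0).any().any():
            raise ValueError("negative abundances on linear scale")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is missing."""
        return self.values.isna()

    def to_log(self) -> "MetaboliteMatrix":
        if self.log_scale:
            return self
        with np.errstate(divide="ignore"):
            return replace(self, values=np.log(self.values), log_scale=True)

    def to_linear(self) -> "MetaboliteMatrix":
        if not self.log_scale:
            return self
        return replace(self, values=np.exp(self.values), log_scale=False)


@dataclass(frozen=True)
class ImputationPolicy:
    max_missing_frac: float = 0.20
    method: str = "qrilc_style"
    seed: int = 0
    scale: str = "log"
    min_observed: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")


# ---------------------------------------------------------------------------
# normalization


def normalize_is(
    quant: pd.DataFrame | Iterable[pd.DataFrame],
    metadata: pd.DataFrame,
    is_name: str = INTERNAL_STANDARD_NAME,
) -> MetaboliteMatrix:
    """Build the normalized matrix from per-sample QuantTable rows.

    Every sample must carry an internal-standard row with AUC > 0; samples
    without one are excluded with a log entry rather than silently rescaled.
    """
    if not isinstance(quant, pd.DataFrame):
        quant = pd.concat(list(quant), ignore_index=True)
    wide = quant.pivot_table(index="sample_id", columns="metabolite", values="auc", aggfunc="first")
    if is_name not in wide.columns:
        raise ValueError(f"internal standard {is_name!r} absent from all samples")
    is_auc = wide[is_name]
    bad = is_auc.isna() | (is_auc <= 0)
    if bad.any():
        for sid in wide.index[bad]:
            logger.warning("sample %s: missing/zero internal standard; sample excluded", sid)
        wide = wide.loc[~bad]
        is_auc = is_auc.loc[~bad]
    values = wide.drop(columns=[is_name]).div(is_auc, axis=0)
    values.columns.name = None
    return MetaboliteMatrix(values=values, metadata=metadata.loc[values.index], log_scale=False)


# ---------------------------------------------------------------------------
# missingness accounting


def missingness_report(
    matrix: MetaboliteMatrix, condition: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-metabolite missing fractions, optionally tested for
    condition-dependence (two-sided Fisher exact on missing counts per
    condition level pair, Benjamini-Hochberg adjusted)."""
    if matrix.values.empty:
        raise ValueError("empty matrix")
    mask = matrix.mask
    out = pd.DataFrame({"missing_frac": mask.mean(axis=0)})
    if condition is None:
        return out
    levels = sorted(matrix.metadata[condition].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"condition {condition!r} must have exactly 2 levels, got {levels}")
    in_a = (matrix.metadata[condition] == levels[0]).reindex(mask.index).to_numpy()
    pvals = []
    for met in mask.columns:
        m = mask[met].to_numpy()
        tab = [[int((m & in_a).sum()), int((~m & in_a).sum())],
               [int((m & ~in_a).sum()), int((~m & ~in_a).sum())]]
        pvals.append(stats.fisher_exact(tab, alternative="two-sided")[1])
    reject, qvals, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out["p_condition"] = pvals
    out["q_condition"] = qvals
    out["condition_associated"] = reject
    return out


# ---------------------------------------------------------------------------
# censored-normal maximum likelihood


class CensoredNormalMLE:
    """Normal model for values observed above a left-censoring limit.

    ``observed`` are the uncensored measurements; ``n_censored`` values are
    only known to lie below ``limit``. ``fit`` maximizes the censored
    likelihood
    ``sum log phi((x-mu)/sigma)/sigma + n_censored * log Phi((limit-mu)/sigma)``.
    """

    def __init__(self, observed: Sequence[float], n_censored: int, limit: float):
        self.observed = np.asarray(observed, dtype=float)
        if self.observed.size < 2:
            raise ValueError("need >= 2 observed values")
        self.n_censored = int(n_censored)
        self.limit = float(limit)

    def loglike(self, params: Sequence[float]) -> float:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        ll = np.sum(stats.norm.logpdf(self.observed, mu, sigma))
        if self.n_censored:
            ll += self.n_censored * stats.norm.logcdf(self.limit, mu, sigma)
        return float(ll)

    def fit(self) -> "CensoredNormalResults":
        x0 = np.array([self.observed.mean(), np.log(self.observed.std(ddof=1) + 1e-9)])
        res = optimize.minimize(lambda p: -self.loglike(p), x0, method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-10, maxiter=2000))
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        return CensoredNormalResults(self, float(mu), sigma, bool(res.success), float(-res.fun))


@dataclass
class CensoredNormalResults:
    model: CensoredNormalMLE
    mu: float
    sigma: float
    converged: bool
    llf: float

    def draw_censored(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n values from the fitted normal truncated above at the limit."""
        b = (self.model.limit - self.mu) / self.sigma
        return stats.truncnorm.rvs(-np.inf, b, loc=self.mu, scale=self.sigma,
                                   size=n, random_state=rng)

    def summary(self) -> str:
        return (
            f"Censored-normal MLE: mu={self.mu:.4f} sigma={self.sigma:.4f} "
            f"(n_obs={self.model.observed.size}, n_censored={self.model.n_censored}, "
            f"limit={self.model.limit:.4f}, llf={self.llf:.2f}, converged={self.converged})"
        )


# ---------------------------------------------------------------------------
# imputation and exclusion


def impute_qrilc(
    matrix: MetaboliteMatrix, policy: ImputationPolicy = ImputationPolicy()
) -> MetaboliteMatrix:
    """Left-censored imputation on the log scale, per metabolite.

    The censor point is the per-metabolite observed minimum (the detection
    limit is unknown; the smallest observed value is its usual surrogate).
    Imputed draws never exceed that minimum. Metabolites with fewer than
    ``policy.min_observed`` observed values cannot support the fit and are
    dropped. Deterministic for a fixed policy seed.
    """
    rng = np.random.default_rng(policy.seed)
    log_m = matrix.to_log()
    values = log_m.values.copy()
    dropped = []
    for met in list(values.columns):
        col = values[met]
        missing = col.isna()
        if not missing.any():
            continue
        obs = col[~missing].to_numpy()
        if obs.size < policy.min_observed:
            dropped.append(met)
            values = values.drop(columns=[met])
            continue
        limit = float(obs.min())
        fit = CensoredNormalMLE(obs, int(missing.sum()), limit).fit()
        values.loc[missing, met] = fit.draw_censored(int(missing.sum()), rng)
    if dropped:
        logger.warning("imputation dropped %d metabolite(s) with <%d observed values: %s",
                       len(dropped), policy.min_observed, dropped)
    out = replace(log_m, values=values)
    return out if matrix.log_scale else out.to_linear()


def replicate_rsd(matrix: MetaboliteMatrix) -> pd.Series:
    """Per-metabolite technical-replicate spread (log-scale RMS deviation).

    Duplicate measurements exist to gauge measurement accuracy; this is the
    root-mean-square log deviation of replicates from their within-time-point
    mean, i.e. roughly the replicate log-SD per metabolite. NaN when the
    design carries no replicates.
    """
    log_m = matrix.to_log()
    groups = log_m.metadata.groupby(["run", "time_label"], sort=False)
    devs = []
    for _, idx in groups.groups.items():
        sub = log_m.values.loc[idx]
        if len(sub) < 2:
            continue
        devs.append(sub - sub.mean())
    if not devs:
        return pd.Series(np.nan, index=matrix.values.columns)
    dev = pd.concat(devs)
    n_groups = len(devs)
    # ddof: one mean per replicate group
    return np.sqrt((dev**2).sum() / (len(dev) - n_groups))


def exclude_unreliable(
    matrix: MetaboliteMatrix, max_rsd: float = 0.3
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Exclude species whose duplicate measurements disagree too much.

    A standard multivariate-QC gate: metabolites with replicate log-RSD
    above ``max_rsd`` are too unstable for covariance-based modelling
    (factor analysis, clustering) and are dropped from the multivariate
    matrix; like the high-missingness exclusion, they remain available for
    univariate fold-change exports. No-op for designs without replicates.
    """
    rsd = replicate_rsd(matrix)
    excluded = rsd[rsd > max_rsd]
    kept = matrix.values.drop(columns=list(excluded.index))
    report = excluded.rename("replicate_rsd").rename_axis("metabolite").reset_index()
    if len(excluded):
        logger.info("replicate-QC excluded %d metabolite(s) with log-RSD > %.2f: %s",
                    len(excluded), max_rsd, list(excluded.index))
    return replace(matrix, values=kept), report


def exclude_high_missing(
    matrix: MetaboliteMatrix, policy: ImputationPolicy = ImputationPolicy()
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Exclude metabolites missing in more than ``max_missing_frac`` of
    samples (boundary kept: 'up to' the threshold is acceptable) from the
    multivariate matrix; the exclusion list reports their fractions so they
    can still feed univariate time-profile exports."""
    frac = matrix.mask.mean(axis=0)
    excluded = frac[frac > policy.max_missing_frac]
    kept = matrix.values.drop(columns=list(excluded.index))
    report = excluded.rename("missing_frac").rename_axis("metabolite").reset_index()
    return replace(matrix, values=kept), report
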