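"""Group statistics for the exertion cohort: fold changes, Spearman PCA,
Hotelling outlier removal, confidence-ellipse separation, hierarchical
clustering, Wilcoxon/Benjamini-Hochberg testing and RPE grouping.

Because the cohort is small and heterogeneous, rank statistics are used
throughout: the PCA is an eigendecomposition of the metabolite *Spearman*
correlation matrix (invariant to any per-metabolite strictly monotone
transform), and group comparisons use the two-sided Wilcoxon rank-sum test
with one Benjamini-Hochberg family across every metabolite x time x
comparison cell.

Runs that stopped before 30 min are re-encoded so their last exercise
sample occupies the final-exercise slot — the sample closest to the state
of maximal exertion the run reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .normimpute import MetaboliteMatrix

logger = logging.getLogger(__name__)

FINAL_EXERCISE = "30min"
EXERCISE_LABELS = ("10min", "20min", "30min")


# ---------------------------------------------------------------------------
# fold changes


def fold_changes(
    matrix: MetaboliteMatrix,
    final_label: str = FINAL_EXERCISE,
    exercise_labels: tuple[str, ...] = EXERCISE_LABELS,
) -> pd.DataFrame:
    """Per-run fold-vs-baseline table.

    Technical replicates are averaged by geometric mean before folding;
    for runs that stopped early the last exercise sample is re-labeled to
    the final-exercise slot. Runs lacking a baseline are dropped with a log
    entry. Returns a long frame: run, metabolite, time_label, fold, plus
    run-level metadata (arm, rpe_last, completed).
    """
    lin = matrix.to_linear()
    meta = lin.metadata
    long = lin.values.join(meta[["run", "time_label", "replicate"]]).melt(
        id_vars=["run", "time_label", "replicate"],
        var_name="metabolite", value_name="value", ignore_index=False,
    )
    # geometric mean over replicates (log-scale mean)
    agg = (
        long.assign(logv=np.log(long["value"]))
        .groupby(["run", "time_label", "metabolite"], sort=False)["logv"]
        .mean()
        .pipe(np.exp)
        .rename("value")
        .reset_index()
    )

    run_meta = meta.drop_duplicates("run").set_index("run")
    rows = []
    for run, sub in agg.groupby("run", sort=True):
        wide = sub.pivot(index="time_label", columns="metabolite", values="value")
        if "baseline" not in wide.index:
            logger.warning("run %s lacks a baseline sample; dropped", run)
            continue
        base = wide.loc["baseline"]
        folds = wide.div(base, axis=1)
        present_ex = [t for t in exercise_labels if t in folds.index]
        re_encoded = False
        if present_ex and final_label not in folds.index:
            last = present_ex[-1]
            folds = folds.rename(index={last: final_label})
            re_encoded = True
        for tl, r in folds.iterrows():
            for met, f in r.items():
                rows.append((run, met, tl, f, re_encoded and tl == final_label))
    out = pd.DataFrame(rows, columns=["run", "metabolite", "time_label", "fold", "re_encoded"])
    for col in ("arm_fio2", "rpe_last", "completed"):
        out[col] = out["run"].map(run_meta[col])
    return out


def folds_at(fc: pd.DataFrame, time_label: str = FINAL_EXERCISE) -> pd.DataFrame:
    """Runs x metabolites fold matrix at one time point."""
    sub = fc[fc["time_label"] == time_label]
    return sub.pivot(index="run", columns="metabolite", values="fold")


# ---------------------------------------------------------------------------
# Spearman-correlation PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # runs x components
    loadings: pd.DataFrame  # metabolites x components (orthonormal)
    eigenvalues: np.ndarray
    excluded: list[str] = field(default_factory=list)


def spearman_pca(data: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA on the metabolite Spearman rank-correlation matrix.

    Scores are the per-metabolite rank-transformed, standardized data
    projected on the eigenvectors, so both eigenvalues and loadings are
    invariant to strictly monotone per-metabolite transforms (up to sign).
    """
    if data.isna().any().any():
        raise ValueError("spearman_pca requires a complete matrix (impute first)")
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise ValueError("need >= 3 runs and >= 2 metabolites")
    constant = [c for c in data.columns if data[c].nunique() <= 1]
    if constant:
        logger.warning("excluding %d constant metabolite(s) from PCA: %s", len(constant), constant)
        data = data.drop(columns=constant)
    ranks = data.rank(axis=0)
    z = (ranks - ranks.mean()) / ranks.std(ddof=1)
    corr = np.corrcoef(ranks.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| element positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    k = n_components or len(evals)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(z.to_numpy() @ evecs[:, :k], index=data.index, columns=comps),
        loadings=pd.DataFrame(evecs[:, :k], index=data.columns, columns=comps),
        eigenvalues=evals[:k],
        excluded=constant,
    )


# ---------------------------------------------------------------------------
# Hotelling outlier removal


@dataclass
class OutlierReport:
    t2: pd.Series
    cutoff: float
    kept: list
    removed: list
    alpha: float
    n_components: int


def hotelling_filter(pca: PCAResult, alpha: float = 0.05, n_components: int = 2) -> OutlierReport:
    """Flag outlying runs by Hotelling's T-squared on retained components.

    T2_i = sum_j t_ij^2 / lambda_j over the first ``n_components`` score
    dimensions. The cutoff is the in-model (beta-distribution) upper control
    limit at 1 - alpha, the exact null distribution for points included in
    the PCA fit; removal is applied once, without iteration.
    """
    n = pca.scores.shape[0]
    k = n_components
    if n < k + 2:
        raise ValueError("need at least n_components + 2 runs")
    lam = pca.eigenvalues[:k] * 1.0
    if np.any(lam <= 1e-12):
        raise ValueError("degenerate covariance: zero eigenvalue among retained components")
    t2 = (pca.scores.iloc[:, :k] ** 2 / lam).sum(axis=1)
    # in-model UCL: T2 ~ ((n-1)^2/n) * Beta(k/2, (n-k-1)/2)
    cutoff = (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, k / 2, (n - k - 1) / 2)
    removed = t2.index[t2 > cutoff].tolist()
    return OutlierReport(t2=t2, cutoff=float(cutoff), kept=t2.index[t2 <= cutoff].tolist(),
                         removed=removed, alpha=alpha, n_components=k)


# ---------------------------------------------------------------------------
# confidence-ellipse separation


@dataclass
class EllipseSeparation:
    centers: dict
    ellipses: dict  # group -> (center, covariance, chi2 level)
    vector: np.ndarray  # unit center-to-center direction
    projections: pd.Series  # per-run scalar projection on the vector
    contributions: pd.Series  # per-metabolite loading along the vector, ranked
    degenerate: bool


def ellipse_separation(
    pca: PCAResult, groups: pd.Series, level: float = 0.95, n_components: int = 2
) -> EllipseSeparation:
    """Two-group 95% confidence ellipses and the center-to-center axis.

    Projections are centered scores projected on the unit vector between
    the two ellipse centers; metabolite contributions are the PCA loadings
    projected on the same vector, ranked by absolute value.
    """
    scores = pca.scores.iloc[:, :n_components]
    groups = groups.reindex(scores.index)
    names = sorted(groups.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    for g in names:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 runs")
    chi2_level = stats.chi2.ppf(level, df=n_components)
    centers, ellipses = {}, {}
    for g in names:
        pts = scores[groups == g]
        centers[g] = pts.mean().to_numpy()
        ellipses[g] = (centers[g], np.cov(pts.to_numpy(), rowvar=False), chi2_level)
    diff = centers[names[1]] - centers[names[0]]
    norm = np.linalg.norm(diff)
    degenerate = norm < 1e-10
    if degenerate:
        logger.warning("group centers coincide; separation vector undefined")
        vec = np.zeros(n_components)
        proj = pd.Series(0.0, index=scores.index)
        contrib = pd.Series(dtype=float)
    else:
        vec = diff / norm
        grand = scores.mean().to_numpy()
        proj = pd.Series((scores.to_numpy() - grand) @ vec, index=scores.index)
        contrib = pd.Series(
            pca.loadings.iloc[:, :n_components].to_numpy() @ vec, index=pca.loadings.index
        ).sort_values(key=np.abs, ascending=False)
    return EllipseSeparation(centers, ellipses, vec, proj, contrib, degenerate)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: list[str]
    partition: dict  # label -> cluster id (1..k)
    newick: str


def hcluster_samples(
    data: pd.DataFrame,
    k: int | None = None,
    metric: str = "euclidean",
    method: str = "average",
    zscore: bool = True,
) -> ClusterResult:
    """Deterministic agglomerative clustering of samples.

    Default distance is Euclidean on per-metabolite z-scored values;
    average linkage. SciPy's linkage breaks merge ties by lowest cluster
    index, which makes the dendrogram deterministic for identical input.
    """
    if data.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    X = data.to_numpy(dtype=float)
    if zscore:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    z = linkage(X, method=method, metric=metric)
    labels = [str(i) for i in data.index]
    partition = {}
    if k is not None:
        flat = fcluster(z, t=k, criterion="maxclust")
        partition = dict(zip(labels, (int(c) for c in flat)))
    return ClusterResult(z, labels, partition, _to_newick(z, labels))


def _to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i].replace(" ", "_").replace(",", "_") for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[n + i] = h
        del nodes[a], nodes[b]
    return nodes[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# group testing


def group_tests(
    fc: pd.DataFrame,
    group_col: str = "rpe_group",
    compare: tuple[str, str] = ("low", "high"),
    time_labels: tuple[str, ...] | None = None,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests per metabolite x time cell.

    The exact null distribution is used when both sides have <= 25 runs and
    the data are tie-free; otherwise the normal approximation with tie
    correction. Benjamini-Hochberg is applied jointly across every cell in
    one family. Cells with fewer than 2 runs per side yield NA with a flag.
    """
    rows = []
    labels = time_labels or sorted(fc["time_label"].unique())
    for met in sorted(fc["metabolite"].unique()):
        for tl in labels:
            cell = fc[(fc["metabolite"] == met) & (fc["time_label"] == tl)]
            x = cell.loc[cell[group_col] == compare[0], "fold"].dropna().to_numpy()
            y = cell.loc[cell[group_col] == compare[1], "fold"].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                rows.append(dict(metabolite=met, time=tl, comparison="-".join(compare),
                                 n1=len(x), n2=len(y), W=np.nan, p=np.nan, flag="empty_cell"))
                continue
            has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append(dict(metabolite=met, time=tl, comparison="-".join(compare),
                             n1=len(x), n2=len(y), W=float(res.statistic),
                             p=float(min(res.pvalue, 1.0)), flag=""))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# RPE grouping


@dataclass
class RPEGroups:
    assignment: pd.Series  # run -> low/median/high
    boundaries: tuple[float, float] | None
    method: str
    flags: list[str] = field(default_factory=list)


DEFAULT_FIXED_CUTS = (4.0, 7.0)


def rpe_grouping(
    rpe_last: pd.Series,
    method: str = "gmm",
    fixed_cuts: tuple[float, float] = DEFAULT_FIXED_CUTS,
    seed: int = 0,
) -> RPEGroups:
    """Partition runs into low/median/high perceived-exertion groups.

    Default: a three-component 1-D Gaussian mixture; group boundaries are
    the posterior crossover points between adjacent (mean-sorted)
    components. Falls back to fixed cuts for tiny samples (< 6 runs) or on
    request. Degenerate inputs (all RPE equal) collapse to a single group
    with a flag.
    """
    vals = rpe_last.astype(float)
    if (vals < 1).any() or (vals > 10).any():
        raise ValueError("RPE values must lie in [1, 10]")
    flags = []
    if vals.nunique() == 1:
        flags.append("degenerate_single_value")
        return RPEGroups(pd.Series("low", index=vals.index), None, "degenerate", flags)
    if method == "fixed" or len(vals) < 6:
        if len(vals) < 6 and method != "fixed":
            flags.append("too_few_runs_fixed_cuts")
        lo, hi = fixed_cuts
        cats = np.where(vals <= lo, "low", np.where(vals <= hi, "median", "high"))
        return RPEGroups(pd.Series(cats, index=vals.index), (lo, hi), "fixed", flags)

    gmm = GaussianMixture(n_components=3, random_state=seed, n_init=5)
    gmm.fit(vals.to_numpy().reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    comp_of = {int(c): rank for rank, c in enumerate(order)}
    pred = gmm.predict(vals.to_numpy().reshape(-1, 1))
    names = np.array(["low", "median", "high"])
    cats = names[[comp_of[int(c)] for c in pred]]
    # posterior crossovers on a fine grid, between mean-sorted neighbours
    grid = np.linspace(1, 10, 1801).reshape(-1, 1)
    post = gmm.predict_proba(grid)[:, order]
    b1 = grid[np.argmax(post[:, 1] > post[:, 0])][0] if (post[:, 1] > post[:, 0]).any() else np.nan
    b2 = grid[np.argmax(post[:, 2] > post[:, 1])][0] if (post[:, 2] > post[:, 1]).any() else np.nan
    return RPEGroups(pd.Series(cats, index=vals.index), (float(b1), float(b2)), "gmm", flags)
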