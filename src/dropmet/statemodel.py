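"""Redox ratios and the factor-analytic metabolic state model.

Two classical ratio pairs proxy the cytosolic and mitochondrial
NAD+/NADH redox state (after Krebs): lactate/pyruvate (cytosol) and
beta-hydroxybutyrate/acetoacetate (mitochondria); lactate/citrate and
pyruvate/citrate read out the switch between anaerobic glycolysis and
TCA-cycle flux. Being within-sample ratios they are invariant to any
per-sample normalization constant.

The state model reduces the metabolite panel to a small set of key
metabolites via factor analysis: principal-axis factoring of the
metabolite correlation matrix (log scale), varimax rotation, factor count
by the Kaiser criterion (eigenvalue > 1) when automatic, and key-metabolite
selection by ranked maximum absolute rotated loading. Factors receive
descriptive labels (anaerobic activity, TCA activity, oxygen release,
energetic) by matching their top loaders against canonical marker sets —
string metadata, no semantic inference.

Exposed statsmodels-style: ``MetabolicStateModel(matrix).fit()`` returns a
``StateModelResults`` with loadings, scores, the key set and a ``summary()``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from statsmodels.multivariate.factor import Factor

from .cohortstats import hcluster_samples
from .normimpute import MetaboliteMatrix

logger = logging.getLogger(__name__)

#: (numerator, denominator) redox / pathway-switch ratio definitions
KREBS_RATIOS: dict[str, tuple[str, str]] = {
    "lactate/pyruvate": ("lactate", "pyruvate"),
    "beta-hydroxybutyrate/acetoacetate": ("beta-hydroxybutyrate", "acetoacetate"),
    "lactate/citrate": ("lactate", "citrate"),
    "pyruvate/citrate": ("pyruvate", "citrate"),
}

#: canonical marker sets used only to *name* factors
FACTOR_MARKERS: dict[str, set[str]] = {
    "anaerobic activity": {"lactate", "pyruvate"},
    "TCA activity": {"citrate", "succinate"},
    "oxygen release": {"2,3-bisphosphoglycerate", "ribose-5-phosphate", "ribulose-5-phosphate"},
    "energetic": {"creatine", "triethanolamine"},
}


def krebs_ratios(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Per-sample redox / pathway ratios on linear scale.

    A ratio is defined only where its denominator is present and positive;
    missing constituents propagate as missing. A panel lacking a
    constituent entirely yields no column for that ratio (flagged in logs).
    """
    lin = matrix.to_linear()
    out = pd.DataFrame(index=lin.values.index)
    for name, (num, den) in KREBS_RATIOS.items():
        if num not in lin.values.columns or den not in lin.values.columns:
            logger.warning("ratio %s: constituent absent from matrix; column omitted", name)
            continue
        d = lin.values[den]
        out[name] = lin.values[num] / d.where(d > 0)
    return out


# ---------------------------------------------------------------------------
# state model


class MetabolicStateModel:
    """Factor-analysis reduction of a metabolite matrix to its key drivers.

    Parameters
    ----------
    matrix : MetaboliteMatrix
        Complete (imputed) matrix; log-transformed internally.
    n_factors : int or "auto"
        Number of factors; "auto" keeps eigenvalues > 1 (Kaiser).
    k_select : int or "auto"
        Size of the key-metabolite set; "auto" keeps every metabolite whose
        maximum absolute rotated loading is >= ``loading_min``.
    min_profile_sd : float
        Metabolites whose log-scale standard deviation falls below this are
        excluded before factoring (no dynamic range, e.g. flat glucose).
    identified_only : bool
        Restrict factoring to identified species (drop ``UNID_``/``DECOY_``
        columns); key metabolites must be nameable.
    """

    def __init__(
        self,
        matrix: MetaboliteMatrix,
        n_factors: int | str = "auto",
        k_select: int | str = "auto",
        loading_min: float = 0.7,
        min_profile_sd: float = 0.15,
        identified_only: bool = True,
    ):
        self.matrix = matrix
        self.n_factors = n_factors
        self.k_select = k_select
        self.loading_min = loading_min
        self.min_profile_sd = min_profile_sd
        self.identified_only = identified_only

    def fit(self) -> "StateModelResults":
        log_m = self.matrix.to_log()
        if log_m.values.isna().any().any():
            raise ValueError("state model requires a complete (imputed) matrix")
        data = log_m.values
        excluded = []
        if self.identified_only:
            excluded += [c for c in data.columns if c.startswith(("UNID_", "DECOY_"))]
            data = data.drop(columns=excluded)
        sd = data.std(ddof=1)
        flat = sd.index[sd < self.min_profile_sd].tolist()
        excluded += flat
        data = data.drop(columns=flat)
        if data.shape[0] < 6:
            raise ValueError("need >= 6 observations (replicates included)")
        corr = np.corrcoef(data.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        k = int(np.sum(evals > 1.0)) if self.n_factors == "auto" else int(self.n_factors)
        k = max(k, 1)
        if k >= data.shape[1]:
            raise ValueError(f"{k} factors requested for {data.shape[1]} metabolites")

        fa = Factor(endog=data.to_numpy(), n_factor=k, method="pa", smc=True)
        res = fa.fit()
        if k > 1:
            res.rotate("varimax")
        loadings = pd.DataFrame(
            res.loadings, index=data.columns, columns=[f"F{i + 1}" for i in range(k)]
        )
        # deterministic orientation: dominant loader of each factor positive
        for c in loadings.columns:
            if loadings[c].iloc[np.argmax(np.abs(loadings[c].to_numpy()))] < 0:
                loadings[c] = -loadings[c]

        # key metabolites: ranked by communality, the variance a metabolite
        # shares with the extracted factor space ("highest eigenvalues" at
        # the variable level); ties broken by name for determinism
        communality = (loadings**2).sum(axis=1)
        order = sorted(communality.index, key=lambda m: (-communality[m], m))
        if self.k_select == "auto":
            key = [m for m in order if communality[m] >= self.loading_min**2]
        else:
            key = order[: int(self.k_select)]

        labels = _label_factors(loadings)
        scores = _regression_scores(data, loadings)
        per_time = None
        if "time_label" in log_m.metadata.columns:
            per_time = scores.join(log_m.metadata["time_label"]).groupby("time_label", sort=False).mean()
            order = log_m.metadata.drop_duplicates("time_label").set_index("time_label").join(
                log_m.metadata.groupby("time_label")["minutes"].first().rename("m"), how="left"
            )
            per_time = per_time.loc[sorted(per_time.index, key=lambda t: order.loc[t, "m"])]
        return StateModelResults(
            model=self, loadings=loadings, eigenvalues=evals, n_factors=k,
            key_metabolites=key, factor_labels=labels, scores=scores,
            time_scores=per_time, excluded=excluded,
        )


def _label_factors(loadings: pd.DataFrame) -> dict[str, str]:
    labels = {}
    for c in loadings.columns:
        weight = {
            lab: float(loadings[c].abs().reindex(sorted(markers)).fillna(0).sum())
            for lab, markers in FACTOR_MARKERS.items()
        }
        best = max(sorted(weight), key=lambda k: weight[k])
        labels[c] = best if weight[best] > 0 else "unassigned"
    return labels


def _regression_scores(data: pd.DataFrame, loadings: pd.DataFrame) -> pd.DataFrame:
    """Thomson regression factor scores from standardized data."""
    z = (data - data.mean()) / data.std(ddof=1)
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    L = loadings.to_numpy()
    coef = np.linalg.solve(corr, L)
    return pd.DataFrame(z.to_numpy() @ coef, index=data.index, columns=loadings.columns)


@dataclass
class StateModelResults:
    model: MetabolicStateModel
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    n_factors: int
    key_metabolites: list[str]
    factor_labels: dict[str, str]
    scores: pd.DataFrame
    time_scores: pd.DataFrame | None
    excluded: list[str] = field(default_factory=list)

    def summary(self) -> str:
        buf = io.StringIO()
        print("Metabolic state model (principal-axis factoring, varimax)", file=buf)
        print(f"  factors: {self.n_factors}  "
              f"(Kaiser eigenvalues > 1: {int(np.sum(self.eigenvalues > 1))})", file=buf)
        for c in self.loadings.columns:
            top = self.loadings[c].abs().sort_values(ascending=False).head(3)
            print(f"  {c} [{self.factor_labels[c]}]: " +
                  ", ".join(f"{m} ({self.loadings.loc[m, c]:+.2f})" for m in top.index), file=buf)
        print(f"  key metabolites ({len(self.key_metabolites)}): "
              + ", ".join(self.key_metabolites), file=buf)
        if self.excluded:
            print(f"  excluded (flat profile): {', '.join(self.excluded)}", file=buf)
        return buf.getvalue()

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps({
            "n_factors": self.n_factors,
            "factor_labels": self.factor_labels,
            "key_metabolites": self.key_metabolites,
            "loadings": {c: self.loadings[c].round(6).to_dict() for c in self.loadings.columns},
            "excluded": self.excluded,
        }, indent=2))


def factor_reduce(
    matrix: MetaboliteMatrix,
    n_factors: int | str = "auto",
    k_select: int | str = "auto",
    **kwargs,
) -> StateModelResults:
    """Convenience wrapper: fit the state model in one call."""
    return MetabolicStateModel(matrix, n_factors=n_factors, k_select=k_select, **kwargs).fit()


# ---------------------------------------------------------------------------
# reduction verification


def verify_reduction(
    matrix: MetaboliteMatrix,
    key_set: list[str],
    k_groups: int = 3,
    method: str = "ward",
    min_profile_sd: float = 0.15,
) -> float:
    """Adjusted Rand index between sample partitions from the full panel and
    from the key subset (same clustering recipe for both).

    Ward linkage is used here (rather than the average-linkage default of
    ``hcluster_samples``) because the check compares whole partitions and
    Ward's balanced clusters make the cut heights decisive; species without
    dynamic range are dropped from the full panel first, as a flat z-scored
    column is pure noise in sample space.
    """
    if not key_set:
        raise ValueError("key set must be non-empty")
    log_m = matrix.to_log()
    data = log_m.values
    sd = data.std(ddof=1)
    data = data.loc[:, sd >= min_profile_sd]
    full = hcluster_samples(data, k=k_groups, method=method)
    sub = hcluster_samples(log_m.values[list(key_set)], k=k_groups, method=method)
    a = [full.partition[s] for s in full.labels]
    b = [sub.partition[s] for s in full.labels]
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# state timeline export


def state_timeline(
    results: StateModelResults, ratios: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format state timeline for circos/rose-style rendering.

    Rows: per time label, each factor's mean score; each key metabolite's
    mean log abundance min-max scaled to [0, 1] across time; and (when
    given) each redox ratio's per-time mean on linear scale.
    """
    if results.time_scores is None or len(results.time_scores) < 3:
        raise ValueError("need factor scores for >= 3 time points")
    rows = []
    for tl, r in results.time_scores.iterrows():
        for c in results.time_scores.columns:
            rows.append(dict(time_label=tl, kind="factor",
                             name=results.factor_labels[c], value=float(r[c])))
    log_m = results.model.matrix.to_log()
    meta = log_m.metadata
    per_time = log_m.values.join(meta["time_label"]).groupby("time_label", sort=False).mean()
    per_time = per_time.loc[results.time_scores.index]
    for met in results.key_metabolites:
        v = per_time[met]
        rng_ = v.max() - v.min()
        scaled = (v - v.min()) / rng_ if rng_ > 0 else v * 0.0
        for tl, val in scaled.items():
            rows.append(dict(time_label=tl, kind="key_metabolite", name=met, value=float(val)))
    if ratios is not None:
        rat_time = ratios.join(meta["time_label"]).groupby("time_label", sort=False).mean()
        rat_time = rat_time.loc[[t for t in results.time_scores.index if t in rat_time.index]]
        for col in ratios.columns:
            for tl, val in rat_time[col].items():
                rows.append(dict(time_label=tl, kind="ratio", name=col, value=float(val)))
    return pd.DataFrame(rows, columns=["time_label", "kind", "name", "value"])


def write_timeline(timeline: pd.DataFrame, path: str | Path) -> None:
    timeline.to_csv(path, index=False)


def read_timeline(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
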