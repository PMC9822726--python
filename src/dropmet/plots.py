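"""Thin plotting layer over pipeline outputs (data first, aesthetics last).

Each function takes the tabular stage outputs and writes one figure;
`render_run_figures` walks a run directory and renders whatever exists.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_time_profiles(fc: pd.DataFrame, out: str | Path, metabolites=None) -> Path:
    """Fold-change time profiles (mean +/- SEM per group where grouped)."""
    mets = metabolites or sorted(fc["metabolite"].unique())[:9]
    mets = [m for m in mets if m in set(fc["metabolite"])]
    ncol = 3
    nrow = int(np.ceil(len(mets) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), squeeze=False)
    groups = fc["rpe_group"].unique() if "rpe_group" in fc else [None]
    for ax, met in zip(axes.ravel(), mets):
        sub = fc[fc["metabolite"] == met]
        for g in groups:
            s = sub if g is None else sub[sub["rpe_group"] == g]
            prof = s.groupby("time_label", sort=False)["fold"]
            m, sem = prof.mean(), prof.sem()
            ax.errorbar(range(len(m)), m.values, yerr=sem.values, marker="o",
                        capsize=2, label=str(g) if g is not None else None)
            ax.set_xticks(range(len(m)), m.index, rotation=45, fontsize=6)
        ax.set_title(met, fontsize=8)
        ax.axhline(1.0, color="grey", lw=0.5, ls=":")
    for ax in axes.ravel()[len(mets):]:
        ax.axis("off")
    if groups[0] is not None:
        axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_pca_scores(scores: pd.DataFrame, groups: pd.Series | None, out: str | Path) -> Path:
    """PC1/PC2 score scatter, colored by group, with 95% ellipses."""
    from matplotlib.patches import Ellipse
    from scipy import stats

    fig, ax = plt.subplots(figsize=(4.5, 4))
    if groups is None:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=15)
    else:
        for g, sub in scores.groupby(groups.reindex(scores.index)):
            pts = sub.iloc[:, :2].to_numpy()
            ax.scatter(pts[:, 0], pts[:, 1], s=15, label=str(g))
            if len(pts) >= 3:
                cov = np.cov(pts, rowvar=False)
                vals, vecs = np.linalg.eigh(cov)
                r = np.sqrt(stats.chi2.ppf(0.95, 2))
                angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
                ax.add_patch(Ellipse(pts.mean(0), 2 * r * np.sqrt(vals[-1]),
                                     2 * r * np.sqrt(vals[0]), angle=angle,
                                     fill=False, lw=1))
        ax.legend(fontsize=7)
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_state_rose(timeline: pd.DataFrame, out: str | Path) -> Path:
    """Rose/ring rendering of the state timeline: factor scores per time
    point on a polar axis, key metabolites as stacked rings."""
    factors = timeline[timeline["kind"] == "factor"]
    labels = list(dict.fromkeys(factors["time_label"]))
    theta = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(5, 5))
    for name, sub in factors.groupby("name"):
        vals = sub.set_index("time_label")["value"].reindex(labels).to_numpy()
        ax.plot(np.r_[theta, theta[:1]], np.r_[vals, vals[:1]], marker="o", label=name)
    ax.set_xticks(theta, labels, fontsize=7)
    ax.legend(fontsize=6, loc="lower left", bbox_to_anchor=(0.9, 0.9))
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def render_run_figures(run_dir: str | Path) -> list[Path]:
    """Render figures for whatever stage outputs a run directory holds."""
    run_dir = Path(run_dir)
    made = []
    fc_p = run_dir / "fold_changes.tsv"
    if fc_p.exists():
        fc = pd.read_csv(fc_p, sep="\t")
        groups_p = run_dir / "rpe_groups.json"
        if groups_p.exists():
            import json

            assignment = json.loads(groups_p.read_text())["assignment"]
            fc["rpe_group"] = fc["run"].map(assignment)
        made.append(plot_time_profiles(fc, run_dir / "fig_time_profiles.png"))
    scores_p = run_dir / "pca_scores.tsv"
    if scores_p.exists():
        scores = pd.read_csv(scores_p, sep="\t", index_col=0)
        groups = None
        if (run_dir / "rpe_groups.json").exists():
            import json

            assignment = json.loads((run_dir / "rpe_groups.json").read_text())["assignment"]
            groups = pd.Series(assignment)
        made.append(plot_pca_scores(scores, groups, run_dir / "fig_pca_scores.png"))
    tl_p = run_dir / "state_timeline.csv"
    if tl_p.exists():
        made.append(plot_state_rose(pd.read_csv(tl_p), run_dir / "fig_state_rose.png"))
    return made
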