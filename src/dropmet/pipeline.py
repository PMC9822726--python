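"""End-to-end orchestration: simulate -> preprocess -> annotate -> quantify
-> normalize/impute -> statistics -> state model -> report.

Stages share pure in-memory core functions (used directly by tests and the
acceptance script) and thin file-based wrappers (used by the CLI). A run
directory accumulates each stage's outputs plus a manifest of SHA-256 hashes;
identical configuration and seed give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import cohortstats as cs
from . import normimpute as ni
from . import quantify as qt
from . import statemodel as sm
from . import synthgen as sg
from .panel import MetabolitePanel
from .peakio import PeakTable, assign_ri, filter_sn, fit_ri, read_peak_table, write_peak_table
from .scenario import COHORT_DESIGN, MPR_DESIGN, ScenarioConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "annotate", "quantify", "normalize", "stats", "state")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    idx = STAGES.index(stage) if stage in STAGES else 97
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineParams:
    """Stage knobs with the pipeline's documented defaults."""

    sn_threshold: float = 20.0
    ri_tol: float = 5.0
    sim_min: float = 0.6
    rule: qt.MassTraceRule = field(default_factory=qt.MassTraceRule)
    policy: ni.ImputationPolicy = field(default_factory=ni.ImputationPolicy)
    spike_amount: dict = field(default_factory=lambda: {"glucose": 1.0, "lactate": 1.0})


# ---------------------------------------------------------------------------
# in-memory core


def preprocess_tables(
    tables: list[PeakTable], sn_threshold: float = 20.0
) -> list[PeakTable]:
    """S/N filter then per-sample retention-index assignment."""
    out = []
    for t in tables:
        f = filter_sn(t, sn_threshold)
        out.append(assign_ri(f, fit_ri(f.ladder)))
    return out


def annotate_tables(
    tables: list[PeakTable],
    libraries: list[ann.LibraryEntry],
    ri_tol: float = 5.0,
    sim_min: float = 0.6,
) -> dict[str, ann.AnnotationResult]:
    results = {t.sample_id: ann.match_stepwise(t, libraries, ri_tol, sim_min) for t in tables}
    if len(results) >= 2:
        results = ann.consensus_unidentified(results, {t.sample_id: t for t in tables})
    return results


def quantify_tables(
    tables: list[PeakTable],
    annotations: dict[str, ann.AnnotationResult],
    panel: MetabolitePanel | None = None,
    rule: qt.MassTraceRule | None = None,
    spike_amount: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rule = rule or qt.MassTraceRule()
    quant = pd.concat(
        [qt.quantify_sample(t, annotations[t.sample_id], rule, panel) for t in tables],
        ignore_index=True,
    )
    iso = pd.concat(
        [qt.isotope_pair_quant(t, annotations[t.sample_id], spike_amount or {}) for t in tables],
        ignore_index=True,
    )
    return quant, iso


@dataclass
class PipelineData:
    matrix: ni.MetaboliteMatrix
    quant: pd.DataFrame
    isotopes: pd.DataFrame
    annotations: dict
    ground_truth: sg.GroundTruth | None = None


def run_dataset(
    panel: MetabolitePanel,
    tables: list[PeakTable],
    metadata: pd.DataFrame,
    params: PipelineParams | None = None,
    ground_truth: sg.GroundTruth | None = None,
) -> PipelineData:
    """Run peak tables through preprocessing, annotation, quantification and
    internal-standard normalization."""
    params = params or PipelineParams()
    processed = preprocess_tables(tables, params.sn_threshold)
    libraries = ann.panel_library(panel)
    annotations = annotate_tables(processed, libraries, params.ri_tol, params.sim_min)
    quant, iso = quantify_tables(processed, annotations, panel, params.rule, params.spike_amount)
    matrix = ni.normalize_is(quant, metadata)
    return PipelineData(matrix, quant, iso, annotations, ground_truth)


def mpr_fold_table(matrix: ni.MetaboliteMatrix) -> pd.DataFrame:
    """Single-runner fold-vs-baseline table (no re-encoding needed)."""
    fc = cs.fold_changes(matrix, final_label="__none__", exercise_labels=())
    return fc.pivot(index="time_label", columns="metabolite", values="fold")


def recover_mpr_folds(n_seeds: int = 50, base_seed: int = 0) -> pd.DataFrame:
    """Full-pipeline fold recovery on the packaged single-runner scenario.

    For each seed, generates the ``mpr_run`` preset at the peak level, runs
    S/N filtering, retention-index assignment, annotation, top-5
    quantification and internal-standard normalization, and computes the
    per-time-point fold table. Returns the seed-averaged fold profile
    (time points x metabolites), the basis for the headline recovered
    effects: the post-exercise ketone-body rise and the succinate maximum.
    """
    cfg = ScenarioConfig.preset("mpr_run")
    panel = sg.panel_for(cfg)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    profiles = []
    for s in seeds:
        tables, meta, _ = sg.simulate_mpr_run(panel, cfg, seed=int(s))
        data = run_dataset(panel, tables, meta)
        profiles.append(mpr_fold_table(data.matrix))
    mean_profile = sum(profiles) / len(profiles)
    order = [tp.label for tp in cfg.time_points]
    return mean_profile.loc[order]


# ---------------------------------------------------------------------------
# run directory orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """A materialized run directory with manifest bookkeeping."""

    def __init__(self, outdir: str | Path, config: ScenarioConfig, seed: int | None = None):
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        self.params = PipelineParams()

    def _record(self, stage: str, paths: list[Path]) -> None:
        self.manifest[stage] = {p.relative_to(self.dir).as_posix(): _sha256(p) for p in sorted(paths)}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        panel = sg.panel_for(cfg)
        seed = stage_seed(self.seed, "simulate")
        sim = sg.simulate_mpr_run if cfg.design == MPR_DESIGN else sg.simulate_cohort
        tables, meta, gt = sim(panel, cfg, seed=seed)
        peaks_dir = self.dir / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        paths = []
        for t in tables:
            p = peaks_dir / f"{t.sample_id}.csv"
            write_peak_table(t, p)
            paths.append(p)
        meta_p = self.dir / "metadata.csv"
        meta.to_csv(meta_p, index=False)
        truth_p = self.dir / "true_abundance.csv"
        gt.true_abundance.to_csv(truth_p)
        gt_p = self.dir / "ground_truth.json"
        gt_p.write_text(json.dumps({
            "planted_folds": gt.planted_folds,
            "rpe_groups": gt.rpe_groups,
            "factor": gt.factor,
            "censoring_events": int(len(gt.censoring)),
        }, indent=2))
        cfg_p = self.dir / "scenario.yaml"
        cfg.to_yaml(cfg_p)
        self._record("simulate", paths + [meta_p, truth_p, gt_p, cfg_p])
        logger.info("simulate: %d peak tables (design=%s, seed=%d)", len(tables), cfg.design, seed)

    def _load_tables(self, sub: str = "peaks") -> list[PeakTable]:
        return [read_peak_table(p) for p in sorted((self.dir / sub).glob("*.csv"))]

    def preprocess(self) -> None:
        tables = self._load_tables()
        processed = preprocess_tables(tables, self.params.sn_threshold)
        out = self.dir / "processed"
        out.mkdir(exist_ok=True)
        paths = []
        for t in processed:
            p = out / f"{t.sample_id}.csv"
            write_peak_table(t, p)
            paths.append(p)
        ri_p = self.dir / "ri_assignments.csv"
        pd.DataFrame(
            [
                dict(sample_id=t.sample_id, peak_id=pk.peak_id, ri=pk.ri,
                     extrapolated=pk.ri_extrapolated)
                for t in processed for pk in t.peaks
            ]
        ).to_csv(ri_p, index=False)
        self._record("preprocess", paths + [ri_p])
        logger.info("preprocess: S/N >= %g, RI assigned for %d samples",
                    self.params.sn_threshold, len(processed))

    def annotate(self) -> None:
        panel = sg.panel_for(self.config)
        tables = preprocess_tables(self._load_tables(), self.params.sn_threshold)
        annotations = annotate_tables(tables, ann.panel_library(panel),
                                      self.params.ri_tol, self.params.sim_min)
        p = self.dir / "annotations.csv"
        ann.annotation_frame(annotations).to_csv(p, index=False)
        self._record("annotate", [p])

    def _annotations(self, tables) -> dict:
        path = self.dir / "annotations.csv"
        if not path.exists():
            raise FileNotFoundError("annotate stage has not run")
        df = pd.read_csv(path)
        out: dict[str, ann.AnnotationResult] = {}
        for r in df.itertuples():
            out.setdefault(r.sample_id, {})[r.peak_id] = ann.Annotation(
                r.peak_id, r.name, float(r.similarity),
                float(r.ri_delta) if pd.notna(r.ri_delta) else np.nan,
                r.tier if pd.notna(r.tier) else None,
            )
        return out

    def quantify(self) -> None:
        panel = sg.panel_for(self.config)
        tables = preprocess_tables(self._load_tables(), self.params.sn_threshold)
        annotations = self._annotations(tables)
        quant, iso = quantify_tables(tables, annotations, panel, self.params.rule,
                                     self.params.spike_amount)
        qp, ip = self.dir / "quant.csv", self.dir / "isotope_report.csv"
        quant.to_csv(qp, index=False)
        iso.to_csv(ip, index=False)
        self._record("quantify", [qp, ip])

    def normalize(self) -> None:
        quant = pd.read_csv(self.dir / "quant.csv")
        meta = pd.read_csv(self.dir / "metadata.csv", index_col="sample_id")
        meta["sample_id"] = meta.index
        matrix = ni.normalize_is(quant, meta)
        report = ni.missingness_report(matrix)
        policy = dataclasses.replace(self.params.policy, seed=stage_seed(self.seed, "normalize"))
        retained, exclusions = ni.exclude_high_missing(matrix, policy)
        reliable, rsd_excl = ni.exclude_unreliable(retained)
        imputed = ni.impute_qrilc(matrix, policy)
        mp = self.dir / "matrix.tsv"
        imputed.values.to_csv(mp, sep="\t")
        side = self.dir / "matrix_meta.json"
        multivariate_excluded = sorted(
            set(exclusions["metabolite"]) | set(rsd_excl["metabolite"])
        )
        side.write_text(json.dumps({
            "policy": dataclasses.asdict(policy),
            "missing_frac": report["missing_frac"].round(6).to_dict(),
            "excluded": exclusions.to_dict(orient="records"),
            "unreliable": rsd_excl.round(4).to_dict(orient="records"),
            "multivariate_excluded": multivariate_excluded,
            "mask_counts": matrix.mask.sum().to_dict(),
        }, indent=2))
        self._record("normalize", [mp, side])
        logger.info("normalize: %d samples x %d metabolites (%d excluded at >%d%% missing)",
                    *imputed.values.shape, len(exclusions),
                    int(self.params.policy.max_missing_frac * 100))

    def _matrix(self, multivariate: bool = False) -> ni.MetaboliteMatrix:
        values = pd.read_csv(self.dir / "matrix.tsv", sep="\t", index_col=0)
        if multivariate:
            side = json.loads((self.dir / "matrix_meta.json").read_text())
            drop = [c for c in side.get("multivariate_excluded", []) if c in values.columns]
            values = values.drop(columns=drop).dropna(axis=1)
        meta = pd.read_csv(self.dir / "metadata.csv", index_col="sample_id")
        meta["sample_id"] = meta.index
        return ni.MetaboliteMatrix(values, meta.loc[values.index])

    def stats(self) -> None:
        matrix = self._matrix()
        mv = self._matrix(multivariate=True)
        paths = []
        fc = cs.fold_changes(matrix)
        fp = self.dir / "fold_changes.tsv"
        fc.to_csv(fp, sep="\t", index=False)
        paths.append(fp)
        if self.config.design == COHORT_DESIGN:
            groups = cs.rpe_grouping(
                matrix.metadata.drop_duplicates("run").set_index("run")["rpe_last"],
                seed=stage_seed(self.seed, "stats"),
            )
            fc["rpe_group"] = fc["run"].map(groups.assignment)
            mv_fc = cs.fold_changes(mv)
            final = cs.folds_at(mv_fc).dropna(axis=1)
            pca = cs.spearman_pca(np.log(final))
            outliers = cs.hotelling_filter(pca)
            run_groups = groups.assignment.reindex(pca.scores.index)
            sel = run_groups.isin(["low", "high"]) & run_groups.index.isin(outliers.kept)
            sep = cs.ellipse_separation(
                dataclasses.replace(pca, scores=pca.scores[sel]), run_groups[sel]
            )
            tests = cs.group_tests(fc)
            clus = cs.hcluster_samples(np.log(final), k=2)
            for name, obj in [
                ("pca_scores.tsv", pca.scores), ("pca_loadings.tsv", pca.loadings),
                ("group_tests.tsv", tests),
            ]:
                p = self.dir / name
                obj.to_csv(p, sep="\t")
                paths.append(p)
            op = self.dir / "outliers.json"
            op.write_text(json.dumps({
                "cutoff": outliers.cutoff, "alpha": outliers.alpha,
                "removed": list(map(str, outliers.removed)), "t2": outliers.t2.round(4).to_dict(),
            }, indent=2))
            paths.append(op)
            gp = self.dir / "rpe_groups.json"
            gp.write_text(json.dumps({
                "boundaries": groups.boundaries, "method": groups.method,
                "assignment": groups.assignment.to_dict(),
                "separation_contributions": sep.contributions.round(4).to_dict(),
            }, indent=2))
            paths.append(gp)
            dp = self.dir / "dendrogram.nwk"
            dp.write_text(clus.newick)
            paths.append(dp)
        self._record("stats", paths)

    def state(self) -> None:
        matrix = self._matrix()
        ratios = sm.krebs_ratios(matrix)
        rp = self.dir / "krebs_ratios.tsv"
        ratios.to_csv(rp, sep="\t")
        paths = [rp]
        if self.config.design == MPR_DESIGN:
            n_factors = len(self.config.factor_labels()) or "auto"
            k_sel = len(self.config.key_metabolites) or "auto"
            results = sm.factor_reduce(
                self._matrix(multivariate=True), n_factors=n_factors, k_select=k_sel
            )
            jp = self.dir / "state_model.json"
            results.to_json(jp)
            tp = self.dir / "state_timeline.csv"
            sm.write_timeline(sm.state_timeline(results, ratios), tp)
            sp = self.dir / "state_summary.txt"
            sp.write_text(results.summary())
            paths += [jp, tp, sp]
        self._record("state", paths)

    def run_all(self) -> None:
        for stage in STAGES:
            try:
                getattr(self, stage)()
            except Exception:
                logger.exception("stage %r failed; partial outputs retained in %s",
                                 stage, self.dir)
                raise


# ---------------------------------------------------------------------------
# report


def make_report(run_dir: str | Path) -> Path:
    """Assemble a markdown report from whatever stage outputs exist.

    Missing stages skip their section with a notice; regeneration is
    idempotent.
    """
    run_dir = Path(run_dir)
    lines = ["# dropmet run report", ""]
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        stages = sorted(json.loads(manifest.read_text()))
        lines += [f"Stages completed: {', '.join(stages)}", ""]

    def section(title: str, path: str, render) -> None:
        lines.append(f"## {title}")
        p = run_dir / path
        if not p.exists():
            lines.extend([f"_Section skipped: {path} not found._", ""])
            return
        lines.extend(render(p))
        lines.append("")

    def table_head(p, n=10):
        df = pd.read_csv(p, sep="\t" if p.suffix == ".tsv" else ",")
        return [df.head(n).to_markdown(index=False)]

    section("Missingness and exclusions", "matrix_meta.json", lambda p: [
        "Metabolites excluded from multivariate statistics (missing fraction):", ""
    ] + [
        f"- {r['metabolite']}: {r['missing_frac']:.2f}"
        for r in json.loads(p.read_text())["excluded"]
    ] or ["- none"])
    section("Time profiles (fold changes)", "fold_changes.tsv", table_head)
    section("PCA scores", "pca_scores.tsv", table_head)
    section("Group tests (Wilcoxon, BH-adjusted)", "group_tests.tsv", table_head)
    section("Hierarchical clustering", "dendrogram.nwk", lambda p: ["```", p.read_text(), "```"])
    section("Krebs redox ratios", "krebs_ratios.tsv", table_head)
    section("State model", "state_summary.txt", lambda p: ["```", p.read_text(), "```"])
    section("State timeline", "state_timeline.csv", table_head)

    try:
        from .plots import render_run_figures

        figures = render_run_figures(run_dir)
    except Exception:  # plotting must never break the report
        logger.exception("figure rendering failed; report continues without figures")
        figures = []
    if figures:
        lines.append("## Figures")
        lines.extend(f"![{p.stem}]({p.name})" for p in figures)
        lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
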