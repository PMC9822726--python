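"""Synthetic peak-level GC-MS study generator with planted ground truth.

The generator works in two layers:

1. *True abundances* — per-sample, per-species noiseless intensity values
   implied by the scenario's planted effect profiles (plus subject- and
   run-level biological variation when configured). These are the ground
   truth that recovery tests assert against.
2. *Peak rendering* — each sample's peak table: one chromatographic peak per
   species with Gaussian per-mass scan traces on a 20 Hz scan grid,
   log-normal technical (replicate) noise, retention-time and per-mass
   jitter, and a signal-to-noise value proportional to rendered abundance.

Technical noise is strictly multiplicative log-normal so intensities stay
positive. The internal standard and the 13C-labeled spikes are constant per
sample set up to technical noise (extraction-solvent spike model).
Left-censoring (``inject_missingness``) removes per-mass intensities below a
detection limit, so low-abundance species go missing more often — the
not-missing-at-random structure the downstream imputation assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (
    ALKANE,
    INTERNAL_STANDARD_NAME,
    MetabolitePanel,
    PanelEntry,
    build_panel,
)
from .peakio import AlkaneLadder, Peak, PeakTable
from .scenario import (
    COHORT_DESIGN,
    MPR_DESIGN,
    RPE_MAX,
    RPE_MIN,
    ScenarioConfig,
    arm_key,
)

SCAN_DT = 0.05  # 20 Hz scan grid, seconds
RPE_GROUPS = ("low", "median", "high")


@dataclass
class GroundTruth:
    """Planted truths of one simulated dataset, for recovery testing."""

    true_abundance: pd.DataFrame  # samples x species, noiseless intensities
    metadata: pd.DataFrame  # one row per sample
    planted_folds: dict  # metabolite -> (group ->) fold-vs-baseline profile
    rpe_groups: dict  # run id -> low/median/high (cohort)
    factor: dict  # n_factors, bases, loadings, labels, key_metabolites
    config: ScenarioConfig
    censoring: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "peak_id", "masses_censored", "removed"]
        )
    )


def zero_noise(config: ScenarioConfig) -> ScenarioConfig:
    """Copy of a scenario with every technical-noise knob set to zero."""
    d = config.to_dict()
    d.update(replicate_cv=0.0, subject_cv=0.0, run_cv=0.0, rt_jitter_s=0.0,
             mass_jitter_cv=0.0, lod=0.0, lap_wobble={}, decoy_coef_sd=0.0,
             decoy_wobble=0.0)
    return ScenarioConfig.from_dict(d)


def panel_for(config: ScenarioConfig) -> MetabolitePanel:
    return build_panel(config.n_extra_metabolites, seed=config.panel_seed)


# ---------------------------------------------------------------------------
# true-abundance layer


def _truncnorm_rpe(rng: np.random.Generator, center: float, sd: float) -> float:
    a, b = (RPE_MIN - center) / sd, (RPE_MAX - center) / sd
    return float(stats.truncnorm.rvs(a, b, loc=center, scale=sd, random_state=rng))


def _subject_factors(
    panel: MetabolitePanel, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-metabolite log-normal baseline offsets for one subject."""
    n = len(panel.entries)
    if config.subject_cv <= 0:
        return np.ones(n)
    out = np.exp(rng.normal(0.0, config.subject_cv, size=n))
    # spikes and alkanes are added at fixed amounts, not biological
    for i, e in enumerate(panel.entries):
        if e.class_tags & {ALKANE} or INTERNAL_STANDARD_NAME == e.name or "u-13C" in e.name:
            out[i] = 1.0
    return out


def _run_jitter(config, rng, n_mets: int) -> float | np.ndarray:
    if config.run_cv <= 0:
        return np.ones(n_mets)
    return np.exp(rng.normal(0.0, config.run_cv, size=n_mets))


def simulate_mpr_run(
    panel: MetabolitePanel,
    config: ScenarioConfig,
    seed: int | None = None,
    render: bool = True,
) -> tuple[list[PeakTable], pd.DataFrame, GroundTruth]:
    """Simulate the single-runner design: 8 time points x duplicate measurements."""
    if config.design != MPR_DESIGN:
        raise ValueError(f"simulate_mpr_run requires the {MPR_DESIGN!r} design")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = config.time_labels()
    n_tp = len(labels)
    folds = config.mpr_fold_profiles()
    rpe = list(config.rpe_model.get("trajectory", [5.0] * len(labels)))

    # decoy species: random factor-mixture effect profiles. A species'
    # exercise response is a property of the species, so coefficients come
    # from the panel seed and are identical across simulated runs.
    bases = config.all_bases()
    if bases and config.decoy_coef_sd > 0:
        decoy_rng = np.random.default_rng(np.random.SeedSequence([config.panel_seed, 211]))
        basis = np.array(list(bases.values()), dtype=float)
        for e in panel.decoys():
            coefs = decoy_rng.normal(0.0, config.decoy_coef_sd, size=len(bases))
            folds[e.name] = list(np.exp(coefs @ basis))

    # per-measurement biological wobble at exercise time points: unstable
    # species (ketone bodies and friends) scatter around their planted
    # trend lap to lap and drop to drop, while baseline and recovery keep
    # their planted folds exactly
    wobble_sd = {
        m: config.lap_wobble.get(m, config.decoy_wobble if m.startswith("DECOY_") else 0.0)
        for m in folds
    }

    names = panel.names()
    rows, meta_rows = [], []
    subj_f = _subject_factors(panel, config, rng)
    for ti, label in enumerate(labels):
        inner = 1 <= ti <= n_tp - 2
        for rep in range(1, config.replicates + 1):
            values = {}
            for e, sf in zip(panel.entries, subj_f):
                fold = folds.get(e.name, [1.0] * n_tp)[ti]
                sd = wobble_sd.get(e.name, 0.0)
                if inner and sd > 0:
                    fold = fold * np.exp(rng.normal(0.0, sd))
                values[e.name] = e.base_abundance * sf * fold
            sid = f"MPR_{label}_r{rep}"
            rows.append(pd.Series(values, name=sid))
            meta_rows.append(
                dict(sample_id=sid, subject="MPR", run="MPR-1", arm_fio2=config.arms[0],
                     time_label=label, minutes=config.time_points[ti].minutes,
                     rpe=rpe[ti], rpe_last=rpe[len(labels) - 2], completed=True,
                     replicate=rep, block=0, order=0)
            )
    truth = pd.DataFrame(rows)
    truth.columns = names
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)

    # measurement blocks of <= max_block_size, randomized order within block
    max_b = config.block_plan.get("max_block_size", 12)
    order = rng.permutation(len(meta))
    meta = meta.iloc[order]
    meta["block"] = np.arange(len(meta)) // max_b
    meta["order"] = np.arange(len(meta))
    meta = meta.sort_index()

    gt = GroundTruth(
        true_abundance=truth,
        metadata=meta,
        planted_folds=folds,
        rpe_groups={"MPR-1": "high"},
        factor=dict(
            n_factors=len(config.factor_labels()),
            bases=config.factor_model.get("bases", {}),
            loadings=config.factor_model.get("loadings", {}),
            labels=config.factor_labels(),
            key_metabolites=list(config.key_metabolites),
        ),
        config=config,
    )
    tables = render_tables(panel, gt, config, rng) if render else []
    return tables, meta, gt


def simulate_cohort(
    panel: MetabolitePanel,
    config: ScenarioConfig,
    seed: int | None = None,
    render: bool = True,
) -> tuple[list[PeakTable], pd.DataFrame, GroundTruth]:
    """Simulate the crossover trial: n_subjects x both arms, trimodal RPE,
    intensity-dependent early stopping, block-randomized measurement order."""
    if config.design != COHORT_DESIGN:
        raise ValueError(f"simulate_cohort requires the {COHORT_DESIGN!r} design")
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = config.time_labels()
    n_tp = len(labels)
    final_ex_idx = 3  # the 30 min / last-exercise slot
    names = panel.names()

    centers = config.rpe_model.get("centers", [2.5, 5.0, 8.5])
    sds = config.rpe_model.get("sds", [1.0] * len(centers))
    weights = np.asarray(config.rpe_model.get("weights", [1 / 3] * 3), dtype=float)
    weights = weights / weights.sum()
    inc = config.incomplete_model or {}

    rows, meta_rows = [], []
    rpe_groups: dict[str, str] = {}
    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        subj_f = _subject_factors(panel, config, rng)
        for fio2 in config.arms:
            run = f"{subject}-{arm_key(fio2)}"
            comp = int(rng.choice(len(centers), p=weights))
            group = RPE_GROUPS[comp]
            rpe_last = _truncnorm_rpe(rng, centers[comp], sds[comp])
            rpe_groups[run] = group

            # early stopping: more likely at high exertion and under hypoxia
            logit = (
                inc.get("intercept", -np.inf)
                + inc.get("rpe_coef", 0.0) * (rpe_last - 5.0)
                + inc.get("hypoxia_coef", 0.0) * (arm_key(fio2) == "hypoxia")
            )
            p_stop = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(logit) else 0.0
            stopped = bool(rng.random() < p_stop)
            if stopped:
                sw = inc.get("stop_weights", {"10min": 0.5, "20min": 0.5})
                stop_label = str(rng.choice(list(sw), p=np.array(list(sw.values())) / sum(sw.values())))
            else:
                stop_label = labels[final_ex_idx]
            stop_idx = labels.index(stop_label)

            jit = _run_jitter(config, rng, len(names))
            for ti, label in enumerate(labels):
                is_exercise = 1 <= ti <= final_ex_idx
                if is_exercise and ti > stop_idx:
                    continue  # run truncated before this sample
                # the sample at the stop point reflects the state at
                # exhaustion: planted folds use the final-exercise column
                eff_ti = final_ex_idx if (is_exercise and ti == stop_idx and stopped) else ti
                values = {}
                for j, (e, sf) in enumerate(zip(panel.entries, subj_f)):
                    fold = config.cohort_fold(e.name, group, fio2)[eff_ti]
                    # run-level biological jitter perturbs the response, not baseline
                    noise = jit[j] if (ti > 0 and fold != 1.0) else 1.0
                    values[e.name] = e.base_abundance * sf * fold * noise
                for rep in range(1, config.replicates + 1):
                    sid = f"{run}_{label}_r{rep}"
                    rows.append(pd.Series(values, name=sid))
                    minutes = config.time_points[ti].minutes
                    frac = min(minutes / config.time_points[final_ex_idx].minutes, 1.0)
                    rpe_tp = RPE_MIN + (rpe_last - RPE_MIN) * frac if ti <= final_ex_idx else max(
                        RPE_MIN, rpe_last * 0.4
                    )
                    meta_rows.append(
                        dict(sample_id=sid, subject=subject, run=run, arm_fio2=fio2,
                             time_label=label, minutes=minutes, rpe=float(np.clip(rpe_tp, 1, 10)),
                             rpe_last=rpe_last, completed=not stopped, replicate=rep,
                             block=si, order=0)
                    )
    truth = pd.DataFrame(rows)
    truth.columns = names
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)

    # block-randomized measurement order; one block = one subject's samples
    max_b = config.block_plan.get("max_block_size", 12)
    order_col = np.empty(len(meta), dtype=int)
    pos = 0
    blocks: list[tuple[int, np.ndarray]] = []
    for si in rng.permutation(config.n_subjects):
        idx = np.flatnonzero(meta["block"].to_numpy() == si)
        for chunk_start in range(0, len(idx), max_b):
            blocks.append((si, rng.permutation(idx[chunk_start : chunk_start + max_b])))
    for _, idx in blocks:
        order_col[idx] = np.arange(pos, pos + len(idx))
        pos += len(idx)
    meta["order"] = order_col

    gt = GroundTruth(
        true_abundance=truth,
        metadata=meta,
        planted_folds=dict(config.effect_profiles),
        rpe_groups=rpe_groups,
        factor=dict(n_factors=0, bases={}, loadings={}, labels=[],
                    key_metabolites=list(config.key_metabolites)),
        config=config,
    )
    tables = render_tables(panel, gt, config, rng) if render else []
    return tables, meta, gt


# ---------------------------------------------------------------------------
# peak-rendering layer


def _gaussian_trace(rt: float, sigma: float, integral: float) -> np.ndarray:
    """Discretized Gaussian peak on the absolute 20 Hz scan grid (no
    interpolation downstream: the trace sum approximates the true integral)."""
    lo = np.ceil((rt - 3.0 * sigma) / SCAN_DT) * SCAN_DT
    times = np.arange(lo, rt + 3.0 * sigma + 1e-9, SCAN_DT)
    w = stats.norm.pdf(times, loc=rt, scale=sigma) * SCAN_DT
    return integral * w


def render_sample(
    panel: MetabolitePanel,
    sample_id: str,
    abundances: pd.Series,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> PeakTable:
    """Render one sample's peak table from its true abundances."""
    peaks: list[Peak] = []
    ladder_rts: dict[int, float] = {}
    ladder_peaks: dict[int, Peak] = {}
    staged: list[tuple[float, PanelEntry, dict[int, np.ndarray], float]] = []
    for e in panel.entries:
        true_ab = float(abundances[e.name])
        if true_ab <= 0:
            continue
        tech = np.exp(rng.normal(0.0, config.replicate_cv)) if config.replicate_cv > 0 else 1.0
        ab = true_ab * tech
        rt = e.true_rt + (rng.normal(0.0, config.rt_jitter_s) if config.rt_jitter_s > 0 else 0.0)
        traces = {}
        for mass in sorted(e.library_spectrum):
            rel = e.library_spectrum[mass]
            if config.mass_jitter_cv > 0:
                rel = rel * np.exp(rng.normal(0.0, config.mass_jitter_cv))
            traces[mass] = _gaussian_trace(rt, e.peak_sigma_s, ab * rel)
        staged.append((rt, e, traces, ab))

    staged.sort(key=lambda s: s[0])
    for i, (rt, e, traces, ab) in enumerate(staged):
        sn = ab / config.sn_ref
        if ALKANE in e.class_tags:
            n = int(e.name.split("C")[-1])
            ladder_rts[n] = rt
            ladder_peaks[n] = Peak(f"ALKANE_C{n}", rt, sn, traces)
        else:
            peaks.append(Peak(f"P{i:03d}", rt, sn, traces))
    return PeakTable(sample_id, peaks, AlkaneLadder(ladder_rts), ladder_peaks)


def render_tables(
    panel: MetabolitePanel,
    ground_truth: GroundTruth,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> list[PeakTable]:
    tables = [
        render_sample(panel, sid, ground_truth.true_abundance.loc[sid], config, rng)
        for sid in ground_truth.true_abundance.index
    ]
    if config.lod > 0:
        tables = inject_missingness(tables, config.lod, ground_truth=ground_truth)
    return tables


def simulated_matrix(
    ground_truth: GroundTruth, config: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """Internal-standard-normalized measurement matrix straight from the
    truth layer (technical noise applied, no peak rendering) — the fast path
    for statistics-level Monte-Carlo tests."""
    rng = np.random.default_rng(seed)
    truth = ground_truth.true_abundance
    noisy = truth * np.exp(rng.normal(0.0, config.replicate_cv, size=truth.shape))
    is_col = noisy[INTERNAL_STANDARD_NAME]
    keep = [
        c for c in noisy.columns
        if c != INTERNAL_STANDARD_NAME and not c.startswith("alkane") and "u-13C" not in c
    ]
    return noisy[keep].div(is_col, axis=0)


# ---------------------------------------------------------------------------
# left-censoring


def inject_missingness(
    tables: Sequence[PeakTable],
    lod: float,
    ground_truth: GroundTruth | None = None,
    seed: int | None = None,  # reserved; censoring at a hard limit is deterministic
) -> list[PeakTable]:
    """Censor per-mass intensities below the detection limit.

    Scan intensities below ``lod`` fall to zero (detector floor); a mass
    trace disappears when all its scans are censored; a peak disappears when
    all its masses are censored. Values at or above ``lod`` are never
    touched, so missingness probability is monotone non-increasing in true
    abundance.
    """
    if lod < 0:
        raise ValueError("lod must be >= 0")
    if lod == 0:
        return list(tables)
    out = []
    records = []
    for t in tables:
        new_peaks = []
        for p in t.peaks:
            traces = {}
            n_censored = 0
            for mass, trace in p.traces.items():
                kept = np.where(trace >= lod, trace, 0.0)
                if np.any(kept > 0):
                    traces[mass] = kept
                else:
                    n_censored += 1
            if traces:
                new_peaks.append(Peak(p.peak_id, p.apex_rt_s, p.sn, traces, p.ri, p.ri_extrapolated))
            if n_censored:
                records.append(
                    dict(sample_id=t.sample_id, peak_id=p.peak_id,
                         masses_censored=n_censored, removed=not bool(traces))
                )
        out.append(PeakTable(t.sample_id, new_peaks, t.ladder, t.ladder_peaks))
    if ground_truth is not None and records:
        ground_truth.censoring = pd.concat(
            [ground_truth.censoring, pd.DataFrame(records)], ignore_index=True
        )
    return out
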