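"""Stepwise tiered spectral-library annotation of retention-indexed peaks.

Peaks are matched against libraries in a fixed tier order — authentic
standard mixes first, then the in-house library, then a public-database
subset — so an identification at an earlier (more trustworthy) tier is never
overridden by a later one. A candidate must agree in retention index within
``ri_tol`` and in spectrum above ``sim_min``; assignment is one-to-one per
sample, resolved greedily by descending similarity.

Spectral similarity is the cosine between square-root-transformed
intensities over the union of nominal masses, the common choice for unit-mass
GC-MS spectra (the square root damps base-peak dominance).

Peaks that match nothing are still tracked: ``consensus_unidentified``
single-linkage-clusters them on retention index across samples and assigns
stable ``UNID_<rank>`` labels, ranked by median RI, so consistently
occurring unknown species remain first-class columns downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .panel import ALKANE, MetabolitePanel
from .peakio import MASS_MAX, MASS_MIN, PeakTable, fit_ri

TIERS = ("standards", "inhouse", "golm_subset")

UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    ri: float
    spectrum: Mapping[int, float]
    tier: str

    def __post_init__(self) -> None:
        if self.ri <= 0:
            raise ValueError(f"{self.name}: ri must be > 0")
        if self.tier not in TIERS:
            raise ValueError(f"{self.name}: tier must be one of {TIERS}")
        for m in self.spectrum:
            if not MASS_MIN <= m <= MASS_MAX:
                raise ValueError(f"{self.name}: mass {m} outside [{MASS_MIN}, {MASS_MAX}]")


@dataclass
class Annotation:
    peak_id: str
    name: str  # library name, or UNMATCHED/UNID_<k>
    similarity: float
    ri_delta: float
    tier: str | None


AnnotationResult = dict[str, Annotation]  # peak_id -> Annotation


def spectral_similarity(a: Mapping[int, float], b: Mapping[int, float]) -> float:
    """Cosine similarity on sqrt intensities over the union of masses.

    1 iff the spectra are proportional, 0 iff their mass support is disjoint.
    """
    masses = sorted(set(a) | set(b))
    va = np.sqrt([max(a.get(m, 0.0), 0.0) for m in masses])
    vb = np.sqrt([max(b.get(m, 0.0), 0.0) for m in masses])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(va @ vb / (na * nb), 0.0, 1.0))


def match_stepwise(
    table: PeakTable,
    libraries: Sequence[LibraryEntry],
    ri_tol: float = 5.0,
    sim_min: float = 0.6,
) -> AnnotationResult:
    """Annotate one sample's peaks by stepwise tiered matching.

    Tiers are searched in order; a peak identified at an earlier tier is
    never re-matched. Within a tier, peak-entry pairs with |RI delta| <=
    ``ri_tol`` and similarity >= ``sim_min`` are assigned greedily by
    (similarity desc, |RI delta| asc, name asc), one-to-one per sample.
    """
    if not libraries:
        raise ValueError("libraries must be non-empty")
    if any(p.ri is None for p in table.peaks):
        raise ValueError(f"sample {table.sample_id}: peaks lack retention indices")

    result: AnnotationResult = {
        p.peak_id: Annotation(p.peak_id, UNMATCHED, 0.0, np.nan, None) for p in table.peaks
    }
    assigned_names: set[str] = set()
    free_peaks = {p.peak_id: p for p in table.peaks}

    for tier in TIERS:
        entries = [e for e in libraries if e.tier == tier]
        if not entries or not free_peaks:
            continue
        candidates = []
        for p in free_peaks.values():
            spec = p.spectrum()
            for e in entries:
                if e.name in assigned_names:
                    continue
                delta = p.ri - e.ri
                if abs(delta) > ri_tol:
                    continue
                sim = spectral_similarity(spec, e.spectrum)
                if sim >= sim_min:
                    candidates.append((-sim, abs(delta), e.name, p.peak_id, delta))
        for neg_sim, abs_delta, name, peak_id, delta in sorted(candidates):
            if name in assigned_names or peak_id not in free_peaks:
                continue
            result[peak_id] = Annotation(peak_id, name, -neg_sim, delta, tier)
            assigned_names.add(name)
            del free_peaks[peak_id]
    return result


def consensus_unidentified(
    results: Mapping[str, AnnotationResult],
    tables: Mapping[str, PeakTable],
    ri_cluster_tol: float = 5.0,
) -> dict[str, AnnotationResult]:
    """Give unmatched peaks stable cross-sample labels.

    Unmatched peaks from all samples are single-linkage-clustered on RI with
    threshold ``ri_cluster_tol``; each cluster becomes one ``UNID_<rank>``
    species, ranked by ascending median RI (deterministic regardless of
    sample order).
    """
    if len(results) < 2:
        raise ValueError("consensus labelling needs >= 2 samples")
    keys = []  # (sample_id, peak_id)
    ris = []
    for sid, res in results.items():
        table = tables[sid]
        for ann in res.values():
            if ann.name == UNMATCHED:
                keys.append((sid, ann.peak_id))
                ris.append(table.peak(ann.peak_id).ri)
    if not keys:
        return {sid: dict(res) for sid, res in results.items()}
    ris_arr = np.asarray(ris, dtype=float)
    if len(ris_arr) == 1:
        clusters = np.array([1])
    else:
        z = linkage(ris_arr.reshape(-1, 1), method="single")
        clusters = fcluster(z, t=ri_cluster_tol, criterion="distance")
    medians = {c: float(np.median(ris_arr[clusters == c])) for c in np.unique(clusters)}
    rank = {c: i + 1 for i, c in enumerate(sorted(medians, key=lambda c: (medians[c], c)))}

    out = {sid: dict(res) for sid, res in results.items()}
    for (sid, pid), c in zip(keys, clusters):
        old = out[sid][pid]
        out[sid][pid] = Annotation(pid, f"UNID_{rank[c]:03d}", old.similarity, old.ri_delta, None)
    return out


def annotation_frame(results: Mapping[str, AnnotationResult]) -> pd.DataFrame:
    """Flatten annotations to the export schema."""
    rows = [
        dict(sample_id=sid, peak_id=a.peak_id, name=a.name, tier=a.tier,
             similarity=a.similarity, ri_delta=a.ri_delta)
        for sid, res in results.items()
        for a in res.values()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "peak_id", "name", "tier", "similarity", "ri_delta"])


# ---------------------------------------------------------------------------
# libraries


def panel_library(
    panel: MetabolitePanel,
    tier_overrides: Mapping[str, str] | None = None,
) -> list[LibraryEntry]:
    """Build the matching library from a panel's named (non-decoy) species.

    Library RIs come from the panel's nominal retention times calibrated
    against its own alkane ladder — the same ladder the simulated instrument
    carries. Decoys are deliberately absent so they surface as consistently
    occurring unidentified species.
    """
    ladder = {int(e.name.split("C")[-1]): e.true_rt for e in panel.with_tag(ALKANE)}
    rimap = fit_ri(ladder)
    overrides = dict(tier_overrides or {})
    entries = []
    for e in panel.entries:
        if ALKANE in e.class_tags or e.name.startswith("DECOY_"):
            continue
        entries.append(
            LibraryEntry(
                name=e.name,
                ri=float(rimap(e.true_rt)),
                spectrum=dict(e.library_spectrum),
                tier=overrides.get(e.name, "standards"),
            )
        )
    return entries


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write library entries in NIST MSP text format (RI as a synon field)."""
    lines = []
    for e in entries:
        lines.append(f"Name: {e.name}")
        lines.append(f"Synon: RI: {e.ri:.2f}")
        lines.append(f"Comments: tier={e.tier}")
        lines.append(f"Num Peaks: {len(e.spectrum)}")
        pairs = [f"{m} {e.spectrum[m]:g}" for m in sorted(e.spectrum)]
        for i in range(0, len(pairs), 5):
            lines.append("; ".join(pairs[i : i + 5]) + ";")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_msp(path: str | Path, tier: str | None = None) -> list[LibraryEntry]:
    """Read an MSP-format library; tier comes per file unless embedded."""
    entries = []
    name, ri, file_tier, spectrum, n_expected = None, None, tier, {}, None

    def _flush():
        nonlocal name, ri, file_tier, spectrum, n_expected
        if name is not None:
            if n_expected is not None and len(spectrum) != n_expected:
                raise ValueError(f"{name}: expected {n_expected} peaks, parsed {len(spectrum)}")
            entries.append(LibraryEntry(name, float(ri), dict(spectrum), file_tier or "standards"))
        name, ri, spectrum, n_expected = None, None, {}, None
        file_tier = tier

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            _flush()
            continue
        low = line.lower()
        if low.startswith("name:"):
            _flush()
            name = line.split(":", 1)[1].strip()
        elif low.startswith("synon:") and "ri:" in low:
            ri = float(line.rsplit(":", 1)[1])
        elif low.startswith("comments:") and "tier=" in low:
            file_tier = line.split("tier=", 1)[1].strip()
        elif low.startswith("num peaks:"):
            n_expected = int(line.split(":", 1)[1])
        elif name is not None and line[0].isdigit():
            for pair in line.replace(",", ";").split(";"):
                pair = pair.strip()
                if pair:
                    m, i = pair.split()
                    spectrum[int(m)] = float(i)
    _flush()
    return entries
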