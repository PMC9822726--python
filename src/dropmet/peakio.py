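"""Peak-table I/O, signal-to-noise filtering and retention-index calibration.

A *peak table* is one sample's picked GC-MS peaks. Each peak carries its apex
retention time (seconds), a signal-to-noise ratio from the upstream peak
picker, and one intensity-vs-scan series ("mass trace") per nominal fragment
mass in the instrument's 70-600 Th window. Every sample also carries an
n-alkane ladder (C10...C36) from which a Kovats-style retention index (RI) is
calibrated: RI(rt of alkane Cn) = 100*n, linearly interpolated in between
(van den Dool-Kratz form, appropriate for temperature-programmed GC).

Peak tables are serialized as long-format CSV with columns
``sample_id, peak_id, apex_rt_s, sn, mass, scan_index, intensity``; alkane
ladder entries use the reserved peak ids ``ALKANE_C<n>``.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

MASS_MIN = 70
MASS_MAX = 600

#: carbon numbers of the packaged n-alkane retention-index markers
ALKANE_CARBONS = (10, 12, 15, 17, 19, 22, 28, 32, 36)

ALKANE_ID_RE = re.compile(r"^ALKANE_C(\d+)$")

CSV_COLUMNS = ["sample_id", "peak_id", "apex_rt_s", "sn", "mass", "scan_index", "intensity"]


class PeakTableError(ValueError):
    """Malformed peak-table content (bad schema, out-of-range mass, ...)."""


def _check_mass(mass: int) -> int:
    mass = int(mass)
    if not MASS_MIN <= mass <= MASS_MAX:
        raise PeakTableError(
            f"mass {mass} Th outside the instrument range [{MASS_MIN}, {MASS_MAX}]"
        )
    return mass


@dataclass
class Peak:
    """One chromatographic peak with per-mass scan traces.

    ``traces`` maps nominal mass (Th) to the ordered per-scan intensity
    series across the peak. The *spectrum* view of the peak is the per-mass
    trace sum.
    """

    peak_id: str
    apex_rt_s: float
    sn: float
    traces: dict[int, np.ndarray]
    ri: float | None = None
    ri_extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.sn <= 0:
            raise PeakTableError(f"peak {self.peak_id}: sn must be > 0, got {self.sn}")
        if not self.traces:
            raise PeakTableError(f"peak {self.peak_id}: no mass traces")
        clean: dict[int, np.ndarray] = {}
        for mass, trace in self.traces.items():
            arr = np.asarray(trace, dtype=float)
            if arr.size == 0:
                raise PeakTableError(f"peak {self.peak_id}: empty trace for mass {mass}")
            clean[_check_mass(mass)] = arr
        self.traces = clean

    def spectrum(self) -> dict[int, float]:
        """Per-mass summed intensities (the peak's mass spectrum)."""
        return {m: float(t.sum()) for m, t in self.traces.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Peak):
            return NotImplemented
        return (
            self.peak_id == other.peak_id
            and np.isclose(self.apex_rt_s, other.apex_rt_s)
            and np.isclose(self.sn, other.sn)
            and self.ri == other.ri
            and set(self.traces) == set(other.traces)
            and all(np.allclose(self.traces[m], other.traces[m]) for m in self.traces)
        )


@dataclass
class AlkaneLadder:
    """Apex retention times of the n-alkane RI markers, by carbon number."""

    rts: dict[int, float]

    def __post_init__(self) -> None:
        if len(self.rts) < 2:
            raise PeakTableError("alkane ladder needs >= 2 entries")
        ns = sorted(self.rts)
        rts = [self.rts[n] for n in ns]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise PeakTableError("alkane RTs must be strictly increasing with carbon number")
        self.rts = {n: float(self.rts[n]) for n in ns}

    def carbons(self) -> list[int]:
        return sorted(self.rts)


@dataclass
class PeakTable:
    """All picked peaks of one sample plus its alkane ladder."""

    sample_id: str
    peaks: list[Peak]
    ladder: AlkaneLadder
    #: optional traces of the ladder peaks, for lossless round-tripping
    ladder_peaks: dict[int, Peak] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PeakTableError(f"duplicate peak_id(s) in sample {self.sample_id}: {sorted(dupes)}")

    def peak(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)


# ---------------------------------------------------------------------------
# CSV round-trip


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a peak table to long-format CSV (one row per mass per scan)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)

        def _rows(peak: Peak) -> Iterable[list]:
            for mass in sorted(peak.traces):
                for i, inten in enumerate(peak.traces[mass]):
                    yield [
                        table.sample_id,
                        peak.peak_id,
                        repr(float(peak.apex_rt_s)),
                        repr(float(peak.sn)),
                        mass,
                        i,
                        repr(float(inten)),
                    ]

        for n in sorted(table.ladder.rts):
            ladder_peak = table.ladder_peaks.get(n) or Peak(
                peak_id=f"ALKANE_C{n}",
                apex_rt_s=table.ladder.rts[n],
                sn=1.0,
                traces={71: np.array([1.0])},
            )
            writer.writerows(_rows(ladder_peak))
        for peak in table.peaks:
            writer.writerows(_rows(peak))


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a long-format peak-table CSV; malformed rows raise with line numbers."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PeakTableError(f"{path}: no header") from None
        if header != CSV_COLUMNS:
            raise PeakTableError(
                f"{path}: missing mandatory columns; expected {CSV_COLUMNS}, got {header}"
            )
        sample_id: str | None = None
        # peak_id -> (apex_rt, sn, {mass -> {scan_index -> intensity}})
        acc: dict[str, tuple[float, float, dict[int, dict[int, float]]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise PeakTableError(f"{path}:{lineno}: expected {len(CSV_COLUMNS)} fields")
            sid, pid, rt_s, sn_s, mass_s, scan_s, inten_s = row
            if sample_id is None:
                sample_id = sid
            elif sid != sample_id:
                raise PeakTableError(f"{path}:{lineno}: mixed sample_ids {sample_id!r}/{sid!r}")
            try:
                rt, sn = float(rt_s), float(sn_s)
                mass, scan = int(mass_s), int(scan_s)
                inten = float(inten_s)
            except ValueError as exc:
                raise PeakTableError(f"{path}:{lineno}: {exc}") from None
            try:
                _check_mass(mass)
            except PeakTableError as exc:
                raise PeakTableError(f"{path}:{lineno}: {exc}") from None
            if pid not in acc:
                acc[pid] = (rt, sn, {})
            acc[pid][2].setdefault(mass, {})[scan] = inten
        if sample_id is None:
            raise PeakTableError(f"{path}: no data rows")

    peaks: list[Peak] = []
    ladder_rts: dict[int, float] = {}
    ladder_peaks: dict[int, Peak] = {}
    for pid, (rt, sn, masses) in acc.items():
        traces = {}
        for mass, scans in masses.items():
            idx = sorted(scans)
            if idx != list(range(len(idx))):
                raise PeakTableError(
                    f"{path}: peak {pid} mass {mass}: scan indices not contiguous from 0"
                )
            traces[mass] = np.array([scans[i] for i in idx])
        peak = Peak(peak_id=pid, apex_rt_s=rt, sn=sn, traces=traces)
        m = ALKANE_ID_RE.match(pid)
        if m:
            n = int(m.group(1))
            ladder_rts[n] = rt
            ladder_peaks[n] = peak
        else:
            peaks.append(peak)
    if len(ladder_rts) < 2:
        raise PeakTableError(f"{path}: fewer than 2 ALKANE_Cn ladder rows")
    return PeakTable(
        sample_id=sample_id,
        peaks=peaks,
        ladder=AlkaneLadder(ladder_rts),
        ladder_peaks=ladder_peaks,
    )


# ---------------------------------------------------------------------------
# S/N filter


def filter_sn(table: PeakTable, threshold: float = 20.0) -> PeakTable:
    """Retain peaks with sn >= threshold (the picker's acceptance bound).

    The boundary is inclusive: a stated threshold is read as the minimum
    acceptable ratio. The alkane ladder is never touched.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    kept = [p for p in table.peaks if p.sn >= threshold]
    if not kept and table.peaks:
        logger.warning(
            "sample %s: all %d peaks below S/N %g", table.sample_id, len(table.peaks), threshold
        )
    return PeakTable(
        sample_id=table.sample_id,
        peaks=kept,
        ladder=table.ladder,
        ladder_peaks=table.ladder_peaks,
    )


# ---------------------------------------------------------------------------
# Retention-index calibration


@dataclass
class RIMap:
    """Piecewise-linear retention-time -> retention-index map.

    Anchored exactly at the alkanes (RI = 100*n); linear interpolation
    between bracketing alkanes, linear continuation of the terminal segments
    outside the ladder span (extrapolated assignments are flagged).
    """

    knots_rt: np.ndarray
    knots_ri: np.ndarray

    def __call__(self, rt: float | np.ndarray) -> np.ndarray | float:
        rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
        ri = np.interp(rt_arr, self.knots_rt, self.knots_ri)
        # linear continuation outside the span
        lo, hi = self.knots_rt[0], self.knots_rt[-1]
        slope_lo = (self.knots_ri[1] - self.knots_ri[0]) / (self.knots_rt[1] - self.knots_rt[0])
        slope_hi = (self.knots_ri[-1] - self.knots_ri[-2]) / (self.knots_rt[-1] - self.knots_rt[-2])
        below = rt_arr < lo
        above = rt_arr > hi
        ri[below] = self.knots_ri[0] + slope_lo * (rt_arr[below] - lo)
        ri[above] = self.knots_ri[-1] + slope_hi * (rt_arr[above] - hi)
        if np.isscalar(rt) or np.ndim(rt) == 0:
            return float(ri[0])
        return ri

    def is_extrapolated(self, rt: float) -> bool:
        return rt < self.knots_rt[0] or rt > self.knots_rt[-1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"knots_rt": self.knots_rt.tolist(), "knots_ri": self.knots_ri.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RIMap":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["knots_rt"], float), np.asarray(d["knots_ri"], float))


def fit_ri(ladder: AlkaneLadder | Mapping[int, float]) -> RIMap:
    """Calibrate the RT -> RI map from an alkane ladder (RI = 100*n anchors)."""
    if not isinstance(ladder, AlkaneLadder):
        ladder = AlkaneLadder(dict(ladder))
    ns = ladder.carbons()
    return RIMap(
        knots_rt=np.array([ladder.rts[n] for n in ns], dtype=float),
        knots_ri=np.array([100.0 * n for n in ns], dtype=float),
    )


def assign_ri(table: PeakTable, rimap: RIMap) -> PeakTable:
    """Assign a retention index to every peak from the sample's fitted map."""
    if rimap is None or len(rimap.knots_rt) < 2:
        raise ValueError("rimap is not fitted")
    new_peaks = []
    for p in table.peaks:
        new_peaks.append(
            Peak(
                peak_id=p.peak_id,
                apex_rt_s=p.apex_rt_s,
                sn=p.sn,
                traces=p.traces,
                ri=float(rimap(p.apex_rt_s)),
                ri_extrapolated=rimap.is_extrapolated(p.apex_rt_s),
            )
        )
    return PeakTable(
        sample_id=table.sample_id,
        peaks=new_peaks,
        ladder=table.ladder,
        ladder_peaks=table.ladder_peaks,
    )
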