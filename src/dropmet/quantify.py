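"""Top-5 mass-trace quantification and the labeled-standard cross-check.

Each annotated peak is quantified as the summed intensity (AUC, no
interpolation, no baseline model) of its five most intense mass traces,
after dropping derivatization-reagent fragments (73 and 147 Th) and any
nominal mass also present in an adjacent peak's spectrum. Characteristic
masses are then included purposefully for certain compound classes (299 Th
for phosphates) even when they fall outside the top five, so the selection
may exceed five masses.

The uniformly 13C-labeled spikes added during extraction supply a scale-free
concentration estimate: per published ion pair (glucose 319/323 and 217/220
Th; lactate 117/119 and 190/193 Th), concentration = light/heavy AUC ratio
times the spiked amount, averaged over the pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationResult, UNMATCHED
from .panel import HEAVY_GLUCOSE, HEAVY_LACTATE, MetabolitePanel, PHOSPHATE, PHOSPHATE_MASS
from .peakio import Peak, PeakTable

NO_INTERNAL_STANDARD = "no_internal_standard"
NO_ADMISSIBLE_MASS = "no_admissible_mass"


@dataclass(frozen=True)
class MassTraceRule:
    excluded_masses: frozenset[int] = frozenset({73, 147})
    forced_masses_by_class: Mapping[str, int] = field(
        default_factory=lambda: {PHOSPHATE: PHOSPHATE_MASS}
    )
    top_n: int = 5
    adjacency_window: float = 3.0  # seconds between apexes counting as adjacent

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.excluded_masses & set(self.forced_masses_by_class.values()):
            raise ValueError("excluded and forced masses must be disjoint")


#: published ion pairs (light, heavy) for the 13C cross-check
DEFAULT_ISOTOPE_PAIRS: dict[str, list[tuple[int, int]]] = {
    "glucose": [(319, 323), (217, 220)],
    "lactate": [(117, 119), (190, 193)],
}

#: which labeled species carries the heavy trace of each analyte
HEAVY_PARTNER = {"glucose": HEAVY_GLUCOSE, "lactate": HEAVY_LACTATE}


def select_mass_traces(
    peak: Peak,
    neighbors: Sequence[Peak],
    rule: MassTraceRule = MassTraceRule(),
    class_tags: frozenset[str] = frozenset(),
) -> list[int]:
    """Choose the quantification masses for one peak.

    Masses are ranked by total trace intensity; reagent masses and masses
    shared with any adjacent peak are dropped; the top ``top_n`` survivors
    are taken; forced class-characteristic masses are added afterwards (the
    selection may exceed ``top_n``).
    """
    neighbor_masses: set[int] = set()
    for nb in neighbors:
        if nb.peak_id != peak.peak_id and abs(nb.apex_rt_s - peak.apex_rt_s) <= rule.adjacency_window:
            neighbor_masses.update(nb.traces)
    spectrum = peak.spectrum()
    forced = {
        m for tag, m in rule.forced_masses_by_class.items() if tag in class_tags and m in spectrum
    }
    admissible = [
        m for m in spectrum
        if m not in rule.excluded_masses and m not in neighbor_masses and m not in forced
    ]
    admissible.sort(key=lambda m: (-spectrum[m], m))
    selection = admissible[: rule.top_n]
    selection.extend(sorted(forced))
    return selection


def integrate_auc(peak: Peak, selection: Sequence[int]) -> float:
    """AUC = the plain sum of scan intensities over the selected masses."""
    if not selection:
        raise ValueError("selection must be non-empty")
    return float(sum(peak.traces[m].sum() for m in selection))


def quantify_sample(
    table: PeakTable,
    annotations: AnnotationResult,
    rule: MassTraceRule = MassTraceRule(),
    panel: MetabolitePanel | None = None,
) -> pd.DataFrame:
    """Quantify every annotated peak of one sample.

    Returns the QuantTable rows for this sample: one row per annotated
    species (unmatched peaks keep their UNID labels). A species whose peak
    is absent is *missing*, never zero. Class tags (for forced masses) come
    from the panel when given.
    """
    rows = []
    seen: set[str] = set()
    for p in table.peaks:
        ann = annotations.get(p.peak_id)
        if ann is None or ann.name == UNMATCHED:
            continue
        if ann.name in seen:
            raise ValueError(f"sample {table.sample_id}: duplicate metabolite {ann.name!r}")
        seen.add(ann.name)
        tags: frozenset[str] = frozenset()
        if panel is not None:
            try:
                tags = panel.get(ann.name).class_tags
            except KeyError:
                pass
        selection = select_mass_traces(p, table.peaks, rule, tags)
        if not selection:
            rows.append(
                dict(sample_id=table.sample_id, metabolite=ann.name, auc=np.nan,
                     n_masses=0, masses="", flags=NO_ADMISSIBLE_MASS)
            )
            continue
        rows.append(
            dict(sample_id=table.sample_id, metabolite=ann.name,
                 auc=integrate_auc(p, selection), n_masses=len(selection),
                 masses=";".join(map(str, selection)), flags="")
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "metabolite", "auc", "n_masses", "masses", "flags"]
    )


def _mass_auc(table: PeakTable, annotations: AnnotationResult, name: str, mass: int) -> float:
    for p in table.peaks:
        ann = annotations.get(p.peak_id)
        if ann is not None and ann.name == name:
            trace = p.traces.get(mass)
            return float(trace.sum()) if trace is not None else 0.0
    return np.nan  # species not found in this sample


def isotope_pair_quant(
    table: PeakTable,
    annotations: AnnotationResult,
    spike_amount: Mapping[str, float],
    pairs: Mapping[str, Sequence[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Estimate concentrations from light/heavy ion-pair AUC ratios.

    Per pair, ratio = light-mass AUC of the analyte peak over heavy-mass AUC
    of its co-eluting labeled-standard peak; the concentration estimate is
    the arithmetic mean of the per-pair ratios times the spiked amount.
    Per-pair ratios are reported for concordance checks. Being a ratio, the
    estimate is invariant to any sample-wide intensity scale.
    """
    pairs = DEFAULT_ISOTOPE_PAIRS if pairs is None else pairs
    rows = []
    for met, pair_list in pairs.items():
        heavy_name = HEAVY_PARTNER.get(met, met)
        ratios, flags = [], ""
        for light_m, heavy_m in pair_list:
            light = _mass_auc(table, annotations, met, light_m)
            heavy = _mass_auc(table, annotations, heavy_name, heavy_m)
            if not np.isfinite(heavy) or heavy <= 0:
                flags = NO_INTERNAL_STANDARD
                ratios.append(np.nan)
            else:
                ratios.append(light / heavy)
        ratios_arr = np.asarray(ratios, dtype=float)
        ok = np.isfinite(ratios_arr)
        conc = float(np.mean(ratios_arr[ok])) * spike_amount.get(met, 1.0) if ok.any() else np.nan
        delta = float(np.ptp(ratios_arr[ok])) if ok.sum() > 1 else np.nan
        rows.append(
            dict(sample_id=table.sample_id, metabolite=met,
                 concentration=conc if not flags else np.nan,
                 concordance_delta=delta,
                 **{f"ratio_pair{i + 1}": r for i, r in enumerate(ratios)},
                 flags=flags)
        )
    return pd.DataFrame(rows)
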