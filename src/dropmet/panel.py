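"""The simulated metabolite panel: central-carbon metabolites, standards, alkanes.

The panel mirrors what a methoxyamine/TMS-derivatized blood-drop GC-MS run
contains: the central-carbon metabolites the analysis tracks, cinnamic acid
as extraction-solvent internal standard, uniformly 13C-labeled glucose and
lactate spiked during extraction, the n-alkane retention-index ladder, and
optionally random "decoy" species standing in for the many real but
unidentified peaks of a blood-drop chromatogram.

Fragment spectra are stylized nominal-mass spectra, not measured EI spectra:
each metabolite owns a set of characteristic masses (the isotope-ratio ion
pairs for glucose and lactate are the published ones: 319/323 + 217/220 Th
and 117/119 + 190/193 Th), every derivatized species additionally shows the
ubiquitous TMS reagent fragments 73 and 147 Th, and phosphates show the
characteristic 299 Th fragment at low relative intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

import numpy as np

from .peakio import ALKANE_CARBONS, MASS_MAX, MASS_MIN

# class tags
PHOSPHATE = "phosphate"
KETONE_BODY = "ketone_body"
SUGAR = "sugar"
ORGANIC_ACID = "organic_acid"
AMINO_ACID = "amino_acid"
INTERNAL_STANDARD = "internal_standard"
LABELED_STANDARD = "labeled_standard"
ALKANE = "alkane"

#: TMS-derivatization reagent fragments present in every derivatized spectrum
REAGENT_MASSES = {73: 0.9, 147: 0.7}
#: characteristic phosphate fragment, included purposefully during quantification
PHOSPHATE_MASS = 299

INTERNAL_STANDARD_NAME = "cinnamic acid"
HEAVY_GLUCOSE = "u-13C glucose"
HEAVY_LACTATE = "u-13C lactate"


@dataclass(frozen=True)
class PanelEntry:
    """One simulated species: identity, elution, spectrum, abundance, shape."""

    name: str
    true_rt: float  # apex retention time, seconds
    library_spectrum: dict[int, float]  # nominal mass (Th) -> relative intensity
    base_abundance: float  # baseline AUC-scale intensity units
    class_tags: FrozenSet[str]
    peak_sigma_s: float = 1.0  # chromatographic Gaussian width, seconds

    def __post_init__(self) -> None:
        nonzero = [m for m, i in self.library_spectrum.items() if i > 0]
        if len(nonzero) < 3:
            raise ValueError(f"{self.name}: spectrum needs >= 3 nonzero masses")
        for m in self.library_spectrum:
            if not MASS_MIN <= m <= MASS_MAX:
                raise ValueError(f"{self.name}: mass {m} outside [{MASS_MIN}, {MASS_MAX}]")


@dataclass
class MetabolitePanel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("panel names must be unique")

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def with_tag(self, tag: str) -> list[PanelEntry]:
        return [e for e in self.entries if tag in e.class_tags]

    def metabolites(self) -> list[PanelEntry]:
        """Entries that are analytes (neither standards nor alkanes)."""
        skip = {INTERNAL_STANDARD, LABELED_STANDARD, ALKANE}
        return [e for e in self.entries if not (e.class_tags & skip)]

    def decoys(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.name.startswith("DECOY_")]


# (masses, intensities) beyond the shared reagent fragments; first mass is
# the base peak. Masses are unique across metabolites (other than 73/147 and
# the phosphate 299) so that the stylized spectra are mutually distinctive.
_CHARACTERISTIC: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "pyruvate": ((174, 115, 158, 98), (1.0, 0.55, 0.3, 0.2)),
    "lactate": ((117, 190, 219, 89, 143), (1.0, 0.55, 0.3, 0.2, 0.12)),
    HEAVY_LACTATE: ((119, 193, 222, 91, 146), (1.0, 0.55, 0.3, 0.2, 0.12)),
    "alanine": ((188, 110, 224, 260), (1.0, 0.55, 0.3, 0.2)),
    "alpha-hydroxybutyrate": ((213, 177, 96, 251), (1.0, 0.55, 0.3, 0.2)),
    "beta-hydroxybutyrate": ((233, 191, 131, 255), (1.0, 0.55, 0.3, 0.2)),
    "acetoacetate": ((231, 116, 86, 201), (1.0, 0.55, 0.3, 0.2)),
    "glycerol": ((218, 293, 103, 133), (1.0, 0.55, 0.3, 0.2)),
    "succinate": ((247, 129, 172, 262), (1.0, 0.55, 0.3, 0.2)),
    "creatine": ((327, 282, 171, 107), (1.0, 0.55, 0.3, 0.2)),
    "triethanolamine": ((277, 338, 118, 104), (1.0, 0.55, 0.3, 0.2)),
    INTERNAL_STANDARD_NAME: ((161, 145, 249, 203), (1.0, 0.55, 0.3, 0.2)),
    "citrate": ((273, 347, 183, 375, 257), (1.0, 0.6, 0.45, 0.3, 0.2)),
    "glucose": ((319, 217, 205, 160, 364, 435), (1.0, 0.9, 0.5, 0.3, 0.15, 0.1)),
    HEAVY_GLUCOSE: ((323, 220, 208, 163, 370, 441), (1.0, 0.9, 0.5, 0.3, 0.15, 0.1)),
    "2,3-bisphosphoglycerate": ((387, 227, 211, 199, 176, 299), (1.0, 0.55, 0.3, 0.2, 0.12, 0.07)),
    "ribose-5-phosphate": ((357, 283, 243, 178, 166, 299), (1.0, 0.55, 0.3, 0.2, 0.12, 0.07)),
    "ribulose-5-phosphate": ((467, 311, 223, 181, 186, 299), (1.0, 0.55, 0.3, 0.2, 0.12, 0.07)),
}

# (rt_s, base_abundance, sigma_s, tags)
_LAYOUT: dict[str, tuple[float, float, float, frozenset]] = {
    "pyruvate": (320.0, 1.2e5, 0.8, frozenset({ORGANIC_ACID})),
    "lactate": (345.0, 4.0e5, 0.8, frozenset({ORGANIC_ACID})),
    HEAVY_LACTATE: (346.2, 1.0e5, 0.8, frozenset({LABELED_STANDARD})),
    "alanine": (372.0, 2.0e5, 0.8, frozenset({AMINO_ACID})),
    "alpha-hydroxybutyrate": (398.0, 5.0e4, 0.8, frozenset({ORGANIC_ACID, KETONE_BODY})),
    "beta-hydroxybutyrate": (424.0, 8.0e4, 0.85, frozenset({KETONE_BODY})),
    "acetoacetate": (450.0, 6.0e4, 0.85, frozenset({KETONE_BODY})),
    "glycerol": (476.0, 1.1e5, 0.9, frozenset({SUGAR})),
    "succinate": (520.0, 9.0e4, 0.9, frozenset({ORGANIC_ACID})),
    "creatine": (560.0, 7.0e4, 0.9, frozenset({AMINO_ACID})),
    "triethanolamine": (610.0, 6.0e4, 0.9, frozenset(set())),
    INTERNAL_STANDARD_NAME: (650.0, 2.5e5, 0.9, frozenset({INTERNAL_STANDARD})),
    "citrate": (740.0, 1.5e5, 1.0, frozenset({ORGANIC_ACID})),
    "glucose": (780.0, 6.0e5, 1.0, frozenset({SUGAR})),
    HEAVY_GLUCOSE: (781.2, 1.2e5, 1.0, frozenset({LABELED_STANDARD})),
    "ribose-5-phosphate": (980.0, 2.2e4, 1.1, frozenset({PHOSPHATE, SUGAR})),
    "ribulose-5-phosphate": (1012.0, 1.8e4, 1.1, frozenset({PHOSPHATE, SUGAR})),
    "2,3-bisphosphoglycerate": (1070.0, 3.0e4, 1.1, frozenset({PHOSPHATE})),
}

#: alkane ladder retention times (seconds) under the simulated oven program
ALKANE_RTS: dict[int, float] = {
    10: 280.0, 12: 400.0, 15: 585.0, 17: 705.0, 19: 830.0,
    22: 1005.0, 28: 1360.0, 32: 1600.0, 36: 1850.0,
}

_ALKANE_SPECTRUM = {71: 1.0, 85: 0.8, 99: 0.45, 113: 0.25}

#: the 15 tracked metabolites every panel must contain
MANDATORY_METABOLITES = tuple(
    n for n in _LAYOUT if n not in (HEAVY_GLUCOSE, HEAVY_LACTATE, INTERNAL_STANDARD_NAME)
)

#: ketone bodies proper (acetoacetate and its reduction product)
KETONE_BODIES = ("acetoacetate", "beta-hydroxybutyrate")


def _derivatized_spectrum(name: str) -> dict[int, float]:
    masses, intens = _CHARACTERISTIC[name]
    spec = dict(zip(masses, intens))
    spec.update(REAGENT_MASSES)
    return spec


def build_panel(n_extra_metabolites: int = 0, seed: int = 0) -> MetabolitePanel:
    """Build the mandatory panel plus ``n_extra_metabolites`` random decoys.

    Decoys emulate the many unidentified but consistently occurring species
    of a real chromatogram: random retention times (kept clear of the named
    species), random characteristic masses drawn from the unused part of the
    70-600 Th window, and log-uniform abundances spanning the S/N-threshold
    region. Deterministic for a fixed seed.
    """
    if n_extra_metabolites < 0:
        raise ValueError("n_extra_metabolites must be >= 0")
    rng = np.random.default_rng(seed)

    entries = [
        PanelEntry(
            name=name,
            true_rt=rt,
            library_spectrum=_derivatized_spectrum(name),
            base_abundance=abund,
            class_tags=tags,
            peak_sigma_s=sigma,
        )
        for name, (rt, abund, sigma, tags) in _LAYOUT.items()
    ]
    entries.extend(
        PanelEntry(
            name=f"alkane C{n}",
            true_rt=ALKANE_RTS[n],
            library_spectrum=dict(_ALKANE_SPECTRUM),
            base_abundance=5.0e5,
            class_tags=frozenset({ALKANE}),
            peak_sigma_s=0.8,
        )
        for n in ALKANE_CARBONS
    )

    used_masses = set(REAGENT_MASSES) | {PHOSPHATE_MASS} | set(_ALKANE_SPECTRUM)
    for masses, _ in _CHARACTERISTIC.values():
        used_masses.update(masses)
    free_masses = np.array(sorted(set(range(MASS_MIN, MASS_MAX + 1)) - used_masses))
    occupied_rts = [e.true_rt for e in entries]

    for k in range(n_extra_metabolites):
        # keep decoys >= 6 s away from named species so stylized annotation
        # exercises spectra, not accidental co-elution
        for _ in range(1000):
            rt = float(rng.uniform(300.0, 1840.0))
            if all(abs(rt - r) >= 6.0 for r in occupied_rts):
                break
        occupied_rts.append(rt)
        masses = rng.choice(free_masses, size=5, replace=False)
        intens = np.sort(rng.uniform(0.05, 1.0, size=5))[::-1]
        intens = intens / intens[0]
        spec = {int(m): float(i) for m, i in zip(masses, intens)}
        spec.update(REAGENT_MASSES)
        entries.append(
            PanelEntry(
                name=f"DECOY_{k:03d}",
                true_rt=rt,
                library_spectrum=spec,
                base_abundance=float(10 ** rng.uniform(3.5, 5.3)),
                class_tags=frozenset(),
                peak_sigma_s=float(rng.uniform(0.7, 1.2)),
            )
        )
    return MetabolitePanel(entries)
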