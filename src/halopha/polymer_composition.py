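"""PHBV composition from ¹H-NMR methine integrals, PHA content, C/N/P ratios.

The 3-hydroxyvalerate mole fraction of a PHBV copolymer equals the ratio of
the methine (backbone CH) proton peak areas: each monomer contributes
exactly one methine proton, so

    %3HV = 100 * I_V / (I_B + I_V)

with I_B and I_V the integrals of the 3HB and 3HV methine peaks.  Default
assignment windows (5.20–5.30 ppm for 3HB, 5.10–5.20 ppm for 3HV, CDCl₃)
follow standard PHBV assignments and are configurable.

PHA content is the extracted polymer mass as a percentage of lyophilised
cell dry weight.

Medium C/N/P ratios sum elemental millimoles per litre over the recipe's
nutrient components and normalise to phosphorus = 1.0, on a molar or mass
basis.  Atomic masses are part of the recipe so alternative conventions can
be reproduced; the shipped recipe fixtures default to a phosphorus
reference mass of 32 g/mol, which is the convention under which their
printed ratios were originally derived (standard IUPAC masses are also
included in every fixture under ``standard_masses``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: IUPAC 2021 standard atomic masses (g/mol).
STANDARD_MASSES = {"C": 12.011, "N": 14.007, "P": 30.974}

ASSIGN_3HB = "3HB_methine"
ASSIGN_3HV = "3HV_methine"
UNASSIGNED = "unassigned"

#: ppm windows (lo inclusive, hi exclusive) for the two methine resonances.
DEFAULT_WINDOWS = {ASSIGN_3HB: (5.20, 5.30), ASSIGN_3HV: (5.10, 5.20)}


@dataclass(frozen=True)
class NmrPeak:
    shift: float  # ppm
    integral: float  # arbitrary area units, >= 0
    assignment: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("peak integral must be >= 0")


@dataclass(frozen=True)
class CompositionResult:
    hv_mol_percent: float
    hb_mol_percent: float
    integral_3hb: float
    integral_3hv: float


@dataclass(frozen=True)
class MassSample:
    """Lyophilised biomass and the polymer extracted from it (mg)."""

    lyophilized_mass: float
    polymer_mass: float

    def __post_init__(self) -> None:
        if self.lyophilized_mass <= 0:
            raise ValueError("lyophilized mass must be positive")
        if not 0 <= self.polymer_mass <= self.lyophilized_mass:
            raise ValueError("polymer mass must lie in [0, lyophilized mass]")


@dataclass(frozen=True)
class Component:
    """One medium component with its concentration and C/N/P formula counts.

    ``counted=False`` marks buffer components excluded from nutrient C/N/P
    sums (e.g. Tris).  Concentration is either millimolar (``mM``) or mass
    (``g_per_l`` with ``molar_mass``).
    """

    name: str
    c: int = 0
    n: int = 0
    p: int = 0
    mM: float | None = None
    g_per_l: float | None = None
    molar_mass: float | None = None
    counted: bool = True

    def millimolar(self) -> float:
        if self.mM is not None:
            return self.mM
        if self.g_per_l is not None:
            if not self.molar_mass:
                raise ValueError(
                    f"component {self.name!r}: g/l concentration needs a molar mass"
                )
            return 1000.0 * self.g_per_l / self.molar_mass
        raise ValueError(f"component {self.name!r} has no concentration")


@dataclass(frozen=True)
class MediumRecipe:
    name: str
    components: tuple[Component, ...]
    atomic_masses: Mapping[str, float] = field(default_factory=lambda: dict(STANDARD_MASSES))


def assign_methine_peaks(
    peaks: Sequence[NmrPeak],
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> list[NmrPeak]:
    """Label peaks falling inside the 3HB/3HV methine windows.

    Windows are half-open ``[lo, hi)`` and must be disjoint; peaks outside
    both stay unassigned.  Multiple peaks in one window are summed by
    :func:`composition_from_peaks`.
    """
    win = dict(windows or DEFAULT_WINDOWS)
    items = sorted(win.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
        if lo2 < hi1:
            raise ValueError("assignment windows overlap")
    out: list[NmrPeak] = []
    for peak in peaks:
        label = UNASSIGNED
        for name, (lo, hi) in win.items():
            if lo <= peak.shift < hi:
                label = name
                break
        out.append(NmrPeak(peak.shift, peak.integral, label))
    return out


def hv_mol_percent(integral_3hb: float, integral_3hv: float) -> CompositionResult:
    """Mole-percent 3HV from the two methine integrals."""
    if integral_3hb < 0 or integral_3hv < 0:
        raise ValueError("integrals must be >= 0")
    total = integral_3hb + integral_3hv
    if total == 0:
        raise ValueError("no methine signal (both integrals zero)")
    hv = 100.0 * integral_3hv / total
    return CompositionResult(hv, 100.0 - hv, integral_3hb, integral_3hv)


def composition_from_peaks(
    peaks: Sequence[NmrPeak],
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> CompositionResult:
    """Assign peaks and compute %3HV in one step."""
    assigned = assign_methine_peaks(peaks, windows)
    i_b = sum(p.integral for p in assigned if p.assignment == ASSIGN_3HB)
    i_v = sum(p.integral for p in assigned if p.assignment == ASSIGN_3HV)
    return hv_mol_percent(i_b, i_v)


def read_peaklist(source: str | Path) -> list[NmrPeak]:
    """Read a peak CSV with columns ``shift_ppm, integral``."""
    import pandas as pd

    df = pd.read_csv(source)
    missing = {"shift_ppm", "integral"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing column(s) {sorted(missing)}")
    return [NmrPeak(float(r.shift_ppm), float(r.integral)) for r in df.itertuples()]


def pha_content_percent(sample: MassSample) -> float:
    """Polymer mass as a percentage of cell dry weight."""
    return 100.0 * sample.polymer_mass / sample.lyophilized_mass


def cnp_ratio(recipe: MediumRecipe, basis: str = "mass") -> tuple[float, float, float]:
    """Elemental C : N : P ratio of a medium, normalised to P = 1.0.

    ``basis="molar"`` compares millimoles of atoms; ``basis="mass"``
    (default) weights by the recipe's atomic masses first.  Buffer
    components flagged ``counted=False`` are excluded.
    """
    if basis not in ("molar", "mass"):
        raise ValueError("basis must be 'molar' or 'mass'")
    totals = {"C": 0.0, "N": 0.0, "P": 0.0}
    for comp in recipe.components:
        if not comp.counted:
            continue
        conc = comp.millimolar()
        totals["C"] += conc * comp.c
        totals["N"] += conc * comp.n
        totals["P"] += conc * comp.p
    if totals["P"] <= 0:
        raise ValueError("recipe contains no phosphorus")
    if basis == "mass":
        totals = {el: v * recipe.atomic_masses[el] for el, v in totals.items()}
    p = totals["P"]
    return (totals["C"] / p, totals["N"] / p, 1.0)


def elemental_millimolar(recipe: MediumRecipe) -> dict[str, float]:
    """Total counted millimoles of C, N and P atoms per litre."""
    totals = {"C": 0.0, "N": 0.0, "P": 0.0}
    for comp in recipe.components:
        if not comp.counted:
            continue
        conc = comp.millimolar()
        totals["C"] += conc * comp.c
        totals["N"] += conc * comp.n
        totals["P"] += conc * comp.p
    return totals


def load_recipe(source: str | Path) -> MediumRecipe:
    """Load a recipe YAML (see ``halopha/data/recipes`` for the schema)."""
    with open(source, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _recipe_from_dict(raw)


def builtin_recipe(name: str) -> MediumRecipe:
    """Load one of the shipped recipes: ``hv_min``, ``glycerol``,
    ``hv_min_valeric``."""
    ref = resources.files("halopha").joinpath(f"data/recipes/{name}.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _recipe_from_dict(raw)


def _recipe_from_dict(raw: Mapping) -> MediumRecipe:
    comps = tuple(
        Component(
            name=c["name"],
            c=int(c.get("C", 0)),
            n=int(c.get("N", 0)),
            p=int(c.get("P", 0)),
            mM=c.get("mM"),
            g_per_l=c.get("g_per_l"),
            molar_mass=c.get("molar_mass"),
            counted=bool(c.get("counted", True)),
        )
        for c in raw["components"]
    )
    masses = dict(raw.get("atomic_masses", STANDARD_MASSES))
    return MediumRecipe(name=raw["name"], components=comps, atomic_masses=masses)
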