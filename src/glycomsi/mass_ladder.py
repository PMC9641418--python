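"""Exact-mass chemistry of isoamylase-released glucose polymers and N-glycans.

Isoamylase cleaves the alpha-1,6 branch points of glycogen and releases
linear alpha-1,4 glucose chains, observed in MALDI spectra as a ladder of
singly charged ions spaced one hexose residue (~162 Da) apart.  This module
builds the theoretical m/z ladder for those chains (optionally carrying
covalent phosphate), computes N-glycan masses for the multiplexed
PNGase F assay, and assigns observed centroided peaks to ladder species.

All ions are singly charged, as is standard for MALDI of carbohydrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Adduct",
    "IonKind",
    "MassConstants",
    "CONSTANTS",
    "IonSpecies",
    "PeakAssignment",
    "polymer_mz",
    "glycan_mz",
    "build_ladder",
    "match_peaks",
    "round_half_up",
    "write_ladder_table",
    "read_ladder_table",
]


class Adduct(str, Enum):
    """Charge carrier of a singly charged positive ion."""

    proton = "proton"
    sodium = "sodium"
    potassium = "potassium"


class IonKind(str, Enum):
    glucose_polymer = "glucose_polymer"
    n_glycan = "n_glycan"


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic residue and charge-carrier masses (Da).

    Residue masses are the dehydrated (in-chain) monosaccharide masses;
    a free oligosaccharide is the sum of its residues plus one water.
    Adduct masses are charge-carrier masses corrected for the electron.
    """

    hexose_residue: float = 162.05282
    hexnac_residue: float = 203.07937
    fucose_residue: float = 146.05791
    neuac_residue: float = 291.09542
    water: float = 18.01056
    phosphate_delta: float = 79.96633  # HPO3 addition on a glucose hydroxyl
    adduct_masses: Mapping[Adduct, float] = field(
        default_factory=lambda: {
            Adduct.proton: 1.00728,
            Adduct.sodium: 22.98922,
            Adduct.potassium: 38.96316,
        }
    )


CONSTANTS = MassConstants()

#: Residue-mass lookup for glycan compositions (Hex/HexNAc/Fuc/NeuAc counts).
_GLYCAN_RESIDUES = {
    "Hex": CONSTANTS.hexose_residue,
    "HexNAc": CONSTANTS.hexnac_residue,
    "Fuc": CONSTANTS.fucose_residue,
    "NeuAc": CONSTANTS.neuac_residue,
}


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (species-label convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class IonSpecies:
    """A theoretical singly charged ion of the glucose-polymer or glycan class.

    ``dp`` is the degree of polymerization (glucose units) for polymers;
    ``glycan_composition`` holds Hex/HexNAc/Fuc/NeuAc counts for glycans.
    """

    kind: IonKind
    adduct: Adduct
    mz: float
    dp: int | None = None
    n_phosphate: int = 0
    glycan_composition: Mapping[str, int] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.kind is IonKind.glucose_polymer:
            if self.dp is None or self.dp < 2:
                raise ValueError(f"dp must be >= 2 for polymers, got {self.dp}")
            if not 0 <= self.n_phosphate <= self.dp:
                raise ValueError(
                    f"n_phosphate must be in [0, dp], got {self.n_phosphate}"
                )


@dataclass(frozen=True)
class PeakAssignment:
    """An observed peak matched to its nearest theoretical species."""

    observed_mz: float
    intensity: float
    species: IonSpecies
    delta_mz: float
    within_tolerance: bool


def polymer_mz(dp: int, n_phosphate: int = 0, adduct: Adduct = Adduct.sodium,
               constants: MassConstants = CONSTANTS) -> float:
    """Theoretical m/z of a linear glucose polymer of ``dp`` units.

    The free chain is dp hexose residues plus one water; each covalent
    phosphate adds an HPO3 group.  Singly charged with the given adduct.
    """
    if dp < 2:
        raise ValueError(f"dp must be >= 2, got dp={dp}")
    if n_phosphate < 0:
        raise ValueError(f"n_phosphate must be >= 0, got n_phosphate={n_phosphate}")
    if n_phosphate > dp:
        raise ValueError(
            f"n_phosphate must not exceed dp, got n_phosphate={n_phosphate}, dp={dp}"
        )
    adduct = Adduct(adduct)
    return (
        dp * constants.hexose_residue
        + constants.water
        + n_phosphate * constants.phosphate_delta
        + constants.adduct_masses[adduct]
    )


def glycan_mz(composition: Mapping[str, int], adduct: Adduct = Adduct.sodium,
              constants: MassConstants = CONSTANTS) -> float:
    """Theoretical m/z of an N-glycan given Hex/HexNAc/Fuc/NeuAc counts."""
    unknown = set(composition) - set(_GLYCAN_RESIDUES)
    if unknown:
        raise ValueError(f"unknown residues in composition: {sorted(unknown)}")
    if any(n < 0 for n in composition.values()):
        raise ValueError("residue counts must be nonnegative")
    if sum(composition.values()) == 0:
        raise ValueError("composition must contain at least one residue")
    adduct = Adduct(adduct)
    mass = sum(_GLYCAN_RESIDUES[r] * n for r, n in composition.items())
    return mass + constants.water + constants.adduct_masses[adduct]


def polymer_label(dp: int, n_phosphate: int = 0) -> str:
    prefix = "P" * n_phosphate
    return f"{prefix}-CL{dp}" if n_phosphate else f"CL{dp}"


def glycan_label(composition: Mapping[str, int]) -> str:
    order = ["Hex", "HexNAc", "Fuc", "NeuAc"]
    return "".join(f"{r}{composition[r]}" for r in order if composition.get(r, 0))


def make_polymer(dp: int, n_phosphate: int = 0,
                 adduct: Adduct = Adduct.sodium) -> IonSpecies:
    """Construct a glucose-polymer :class:`IonSpecies` with its display label."""
    return IonSpecies(
        kind=IonKind.glucose_polymer,
        adduct=Adduct(adduct),
        mz=polymer_mz(dp, n_phosphate, adduct),
        dp=dp,
        n_phosphate=n_phosphate,
        label=polymer_label(dp, n_phosphate),
    )


def make_glycan(composition: Mapping[str, int],
                adduct: Adduct = Adduct.sodium) -> IonSpecies:
    comp = {r: int(n) for r, n in composition.items() if n}
    return IonSpecies(
        kind=IonKind.n_glycan,
        adduct=Adduct(adduct),
        mz=glycan_mz(comp, adduct),
        glycan_composition=comp,
        label=glycan_label(comp),
    )


def build_ladder(dp_min: int = 3, dp_max: int = 25, phospho_max: int = 0,
                 adducts: Iterable[Adduct] = (Adduct.sodium,),
                 mz_window: tuple[float, float] = (500.0, 3000.0)
                 ) -> list[IonSpecies]:
    """Enumerate the theoretical polymer ladder inside an acquisition window.

    Returns every (dp, n_phosphate, adduct) combination with
    dp_min <= dp <= dp_max, 0 <= n_phosphate <= phospho_max, and
    theoretical m/z inside ``mz_window``; sorted by m/z.  The defaults match
    the chain-length range released by isoamylase (DP 3-25) and the typical
    500-3,000 m/z MALDI-TOF acquisition window.
    """
    if dp_min < 2:
        raise ValueError(f"dp_min must be >= 2, got {dp_min}")
    if dp_min > dp_max:
        raise ValueError(f"dp_min must be <= dp_max, got {dp_min} > {dp_max}")
    lo, hi = mz_window
    if not lo < hi:
        raise ValueError(f"invalid mz_window {mz_window}")
    ladder = []
    for adduct in adducts:
        for dp in range(dp_min, dp_max + 1):
            for k in range(0, min(phospho_max, dp) + 1):
                mz = polymer_mz(dp, k, adduct)
                if lo <= mz <= hi:
                    ladder.append(make_polymer(dp, k, adduct))
    ladder.sort(key=lambda s: s.mz)
    return ladder


def match_peaks(peaks: Sequence[tuple[float, float]],
                ladder: Sequence[IonSpecies],
                tolerance: float = 0.2,
                ppm: bool = False) -> list[PeakAssignment]:
    """Assign observed (m/z, intensity) peaks to the nearest ladder species.

    Each peak goes to the in-tolerance species with the smallest |delta m/z|
    (ties broken toward the lower-mass species); each species then keeps only
    its most intense in-tolerance peak.  Unmatched peaks are dropped.
    ``tolerance`` is in Th, or parts-per-million when ``ppm`` is true.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    species = sorted(ladder, key=lambda s: s.mz)
    best: dict[int, PeakAssignment] = {}
    for mz, intensity in peaks:
        tol = tolerance * mz * 1e-6 if ppm else tolerance
        chosen = None
        chosen_abs = None
        for idx, sp in enumerate(species):
            d = abs(mz - sp.mz)
            if d <= tol and (chosen_abs is None or d < chosen_abs):
                # strict < keeps the lower-mass species on an exact tie
                chosen, chosen_abs = idx, d
        if chosen is None:
            continue
        sp = species[chosen]
        assignment = PeakAssignment(
            observed_mz=mz,
            intensity=intensity,
            species=sp,
            delta_mz=mz - sp.mz,
            within_tolerance=True,
        )
        prev = best.get(chosen)
        if prev is None or intensity > prev.intensity:
            best[chosen] = assignment
    return [best[i] for i in sorted(best)]


def write_ladder_table(ladder: Sequence[IonSpecies], path) -> None:
    """Export a ladder as a tab-delimited table."""
    rows = []
    for sp in ladder:
        rows.append({
            "label": sp.label,
            "kind": sp.kind.value,
            "dp": sp.dp if sp.dp is not None else "",
            "n_phosphate": sp.n_phosphate,
            "adduct": sp.adduct.value,
            "mz": sp.mz,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ladder_table(path) -> list[IonSpecies]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kind = IonKind(row["kind"])
        if kind is IonKind.glucose_polymer:
            out.append(make_polymer(int(row["dp"]), int(row["n_phosphate"]),
                                    Adduct(row["adduct"])))
        else:
            comp = _parse_glycan_label(str(row["label"]))
            out.append(make_glycan(comp, Adduct(row["adduct"])))
    return out


def _parse_glycan_label(label: str) -> dict[str, int]:
    import re

    comp: dict[str, int] = {}
    for residue, count in re.findall(r"(Hex(?!NAc)|HexNAc|Fuc|NeuAc)(\d+)", label):
        comp[residue] = int(count)
    if not comp:
        raise ValueError(f"cannot parse glycan label {label!r}")
    return comp
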