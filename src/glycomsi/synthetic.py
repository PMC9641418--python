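"""Seeded generator of glyco-MSI datasets with known ground truth.

Emulates an enzyme-digested tissue section: a rectangular pixel grid with
2-4 spatial regions, each carrying its own total-glycogen scale, discrete
chain-length distribution over DP 3-25, phosphorylated-chain fraction,
N-glycan panel and adduct mixture.  Observed peaks get Gaussian m/z jitter,
multiplicative lognormal intensity noise (keeps intensities nonnegative and
mimics MALDI hotspotting), a small additive floor, per-pixel lognormal TIC
variation, and class-specific drift times from linear trends in
drift vs sqrt(m/z).

One pseudo-random stream is derived per pixel from (seed, x, y), so a fixed
seed yields a bit-reproducible dataset regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mass_ladder as ml
from .mass_ladder import Adduct
from .mobility import GLYCAN, POLYMER
from .msi_io import MSIDataset, RegionMask, Spectrum

__all__ = [
    "RegionSpec",
    "DriftTrend",
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "default_two_region_config",
    "default_liver_like_config",
    "poisson_cl_distribution",
]

DP_AXIS = np.arange(3, 26)  # isoamylase-released chains span DP 3-25


def poisson_cl_distribution(mean_dp: float) -> dict[int, float]:
    """Discrete chain-length distribution over DP 3-25.

    A Poisson pmf shifted to start at DP 3 and renormalized; ``mean_dp``
    sets the approximate modal chain length.
    """
    if mean_dp <= 3:
        raise ValueError("mean_dp must exceed 3")
    w = stats.poisson.pmf(DP_AXIS - 3, mu=mean_dp - 3)
    w = w / w.sum()
    return {int(dp): float(p) for dp, p in zip(DP_AXIS, w)}


@dataclass(frozen=True)
class RegionSpec:
    """One spatial region: geometry plus its glycogen/glycan ground truth.

    ``bounds`` are 1-based inclusive (x0, y0, x1, y1); ``shape`` is a filled
    rectangle or the inscribed ellipse.  ``glycogen_scale`` is the region's
    relative total glycogen; ``cl_distribution`` the probability vector over
    DP 3-25; ``phospho_fraction`` the fraction of each chain carrying one
    phosphate; ``phospho_cl_distribution`` defaults to the unphospho one.
    ``glycan_panel`` maps composition tuples to relative levels.
    """

    name: str
    bounds: tuple[int, int, int, int]
    glycogen_scale: float
    cl_distribution: Mapping[int, float]
    phospho_fraction: float = 0.0
    phospho_cl_distribution: Mapping[int, float] | None = None
    glycan_panel: Mapping[tuple[tuple[str, int], ...], float] = field(
        default_factory=dict
    )
    shape: str = "rect"

    def contains(self, x: int, y: int) -> bool:
        x0, y0, x1, y1 = self.bounds
        if self.shape == "rect":
            return x0 <= x <= x1 and y0 <= y <= y1
        cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
        rx, ry = max((x1 - x0) / 2, 0.5), max((y1 - y0) / 2, 0.5)
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class DriftTrend:
    """Linear drift model drift = slope*sqrt(m/z) + intercept + N(0, sd)."""

    slope: float
    intercept: float
    noise_sd: float


@dataclass(frozen=True)
class SimulationConfig:
    width: int
    height: int
    regions: tuple[RegionSpec, ...]
    pixel_size: float = 50.0
    adduct_mix: Mapping[Adduct, float] = field(
        default_factory=lambda: {Adduct.sodium: 0.85, Adduct.potassium: 0.15}
    )
    mz_jitter_sd: float = 0.03
    intensity_lognorm_sd: float = 0.25
    intensity_floor: float = 1e-4
    tic_variation_sd: float = 0.2
    # MALDI spectra are dominated by matrix/chemical-noise ions; these keep
    # the pixel TIC roughly constant across regions so TIC normalization
    # preserves (slightly compresses) regional glycogen contrast.
    background_ions: int = 40
    background_tic: float = 50.0
    background_drift_sd: float = 1.0
    mz_window: tuple[float, float] = (500.0, 3000.0)
    drift: Mapping[str, DriftTrend] = field(
        default_factory=lambda: {
            POLYMER: DriftTrend(slope=0.35, intercept=0.5, noise_sd=0.15),
            GLYCAN: DriftTrend(slope=0.35, intercept=2.0, noise_sd=0.15),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.width < 1 or self.height < 1:
            errors.append("width/height: must be >= 1")
        if not self.regions:
            errors.append("regions: at least one region required")
        for r in self.regions:
            x0, y0, x1, y1 = r.bounds
            if not (1 <= x0 <= x1 <= self.width and 1 <= y0 <= y1 <= self.height):
                errors.append(f"regions[{r.name}].bounds: outside grid")
            if r.glycogen_scale <= 0:
                errors.append(f"regions[{r.name}].glycogen_scale: must be > 0")
            if abs(sum(r.cl_distribution.values()) - 1.0) > 1e-6:
                errors.append(f"regions[{r.name}].cl_distribution: must sum to 1")
            if any(dp < 3 or dp > 25 for dp in r.cl_distribution):
                errors.append(f"regions[{r.name}].cl_distribution: DP outside 3-25")
            if not 0.0 <= r.phospho_fraction <= 1.0:
                errors.append(f"regions[{r.name}].phospho_fraction: not in [0, 1]")
        if any(w < 0 for w in self.adduct_mix.values()) or \
                sum(self.adduct_mix.values()) <= 0:
            errors.append("adduct_mix: weights must be nonnegative, sum > 0")
        for name in ("mz_jitter_sd", "intensity_lognorm_sd", "intensity_floor",
                     "tic_variation_sd", "background_ions", "background_tic",
                     "background_drift_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be >= 0")
        if errors:
            raise ValueError("invalid simulation config:\n  " + "\n  ".join(errors))

    def region_masks(self) -> list[RegionMask]:
        """Boolean masks of the configured regions (first region wins overlap)."""
        masks = []
        claimed = np.zeros((self.height, self.width), dtype=bool)
        for r in self.regions:
            grid = np.zeros((self.height, self.width), dtype=bool)
            for y in range(1, self.height + 1):
                for x in range(1, self.width + 1):
                    if r.contains(x, y) and not claimed[y - 1, x - 1]:
                        grid[y - 1, x - 1] = True
            claimed |= grid
            masks.append(RegionMask(name=r.name, mask=grid))
        return masks


@dataclass
class GroundTruth:
    """What the simulator actually generated, for recovery tests."""

    config: SimulationConfig
    region_map: np.ndarray  # (height, width) of region names, "" = background
    expected: dict[str, pd.DataFrame]  # region -> per-species expected table
    species_class: dict[str, str]  # species label -> ion class


def _region_species_table(region: RegionSpec,
                          config: SimulationConfig) -> pd.DataFrame:
    """Noise-free expected peak list for one region."""
    adducts = {Adduct(a): w for a, w in config.adduct_mix.items()}
    total_w = sum(adducts.values())
    rows = []
    p_dist = region.phospho_cl_distribution or region.cl_distribution
    for adduct, w in adducts.items():
        w = w / total_w
        for dp, p in region.cl_distribution.items():
            expected = region.glycogen_scale * p * (1 - region.phospho_fraction) * w
            if expected > 0:
                rows.append((ml.polymer_label(dp), POLYMER, dp, 0, adduct.value,
                             ml.polymer_mz(dp, 0, adduct), expected))
        for dp, p in p_dist.items():
            expected = region.glycogen_scale * p * region.phospho_fraction * w
            if expected > 0:
                rows.append((ml.polymer_label(dp, 1), POLYMER, dp, 1,
                             adduct.value, ml.polymer_mz(dp, 1, adduct), expected))
        for comp, level in region.glycan_panel.items():
            comp_d = dict(comp)
            if level > 0:
                rows.append((ml.glycan_label(comp_d), GLYCAN, None, 0,
                             adduct.value, ml.glycan_mz(comp_d, adduct),
                             level * w))
    return pd.DataFrame(rows, columns=["label", "class", "dp", "n_phosphate",
                                       "adduct", "mz", "expected_intensity"])


def _background_mz(rng: np.random.Generator, config: SimulationConfig,
                   species_mz: np.ndarray) -> np.ndarray:
    """Random matrix-ion m/z positions kept >= 0.5 Th away from any species."""
    lo, hi = config.mz_window
    out = np.empty(0)
    while out.size < config.background_ions:
        cand = rng.uniform(lo, hi, config.background_ions * 2)
        if species_mz.size:
            idx = np.searchsorted(species_mz, cand)
            left = np.abs(cand - species_mz[np.clip(idx - 1, 0, None)])
            right = np.abs(species_mz[np.clip(idx, None, species_mz.size - 1)]
                           - cand)
            cand = cand[np.minimum(left, right) >= 0.5]
        out = np.concatenate([out, cand])
    return out[: config.background_ions]


def simulate(config: SimulationConfig) -> tuple[MSIDataset, GroundTruth]:
    """Generate a dataset and its ground truth from a validated config."""
    config.validate()
    region_map = np.full((config.height, config.width), "", dtype=object)
    tables: dict[str, pd.DataFrame] = {}
    species_class: dict[str, str] = {}
    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for r in config.regions:
        tab = _region_species_table(r, config)
        tables[r.name] = tab
        species_class.update(dict(zip(tab["label"], tab["class"])))
        arrays[r.name] = (tab["mz"].to_numpy(float),
                          tab["expected_intensity"].to_numpy(float),
                          tab["class"].to_numpy())
    all_species_mz = np.sort(np.concatenate(
        [a[0] for a in arrays.values()] or [np.empty(0)]))
    mid_drift = np.mean([t.intercept for t in config.drift.values()])
    mean_slope = np.mean([t.slope for t in config.drift.values()])

    pixels: dict[tuple[int, int], Spectrum] = {}
    for y in range(1, config.height + 1):
        for x in range(1, config.width + 1):
            region = next((r for r in config.regions if r.contains(x, y)), None)
            rng = np.random.default_rng([config.seed, x, y])
            if region is None:
                pixels[(x, y)] = Spectrum(mz=np.empty(0), intensity=np.empty(0),
                                          drift=np.empty(0))
                continue
            region_map[y - 1, x - 1] = region.name
            theor_mz, expected, cls_arr = arrays[region.name]
            n = len(theor_mz)
            mz = theor_mz + rng.normal(0, config.mz_jitter_sd, n) \
                if config.mz_jitter_sd > 0 else theor_mz.copy()
            sd = config.intensity_lognorm_sd
            noise = rng.lognormal(-sd * sd / 2, sd, n) if sd > 0 else np.ones(n)
            inten = expected * noise
            if config.intensity_floor > 0:
                inten = inten + config.intensity_floor * rng.random(n)
            drift = np.empty(n)
            for cls in (POLYMER, GLYCAN):
                sel = cls_arr == cls
                trend = config.drift[cls]
                drift[sel] = (trend.slope * np.sqrt(mz[sel]) + trend.intercept
                              + (rng.normal(0, trend.noise_sd, int(sel.sum()))
                                 if trend.noise_sd > 0 else 0.0))
            if config.background_ions > 0 and config.background_tic > 0:
                bg_mz = _background_mz(rng, config, all_species_mz)
                bg_int = rng.dirichlet(np.ones(config.background_ions)) \
                    * config.background_tic
                bg_drift = (mean_slope * np.sqrt(bg_mz) + mid_drift
                            + rng.normal(0, config.background_drift_sd,
                                         config.background_ions))
                bg_drift = np.maximum(bg_drift, 1e-3)
                mz = np.concatenate([mz, bg_mz])
                inten = np.concatenate([inten, bg_int])
                drift = np.concatenate([drift, bg_drift])
                n = len(mz)
            tic_sd = config.tic_variation_sd
            if tic_sd > 0:
                inten = inten * rng.lognormal(-tic_sd * tic_sd / 2, tic_sd)
            order = np.argsort(mz)
            mz, inten, drift = mz[order], inten[order], drift[order]
            # jitter can collide two theoretical peaks; nudge to keep mz strict
            for i in range(1, n):
                if mz[i] <= mz[i - 1]:
                    mz[i] = np.nextafter(mz[i - 1], np.inf)
            pixels[(x, y)] = Spectrum(mz=mz, intensity=np.maximum(inten, 0),
                                      drift=drift)
    dataset = MSIDataset(pixels=pixels, width=config.width, height=config.height,
                         pixel_size=config.pixel_size,
                         metadata={"simulated": True, "seed": config.seed})
    truth = GroundTruth(config=config, region_map=region_map, expected=tables,
                        species_class=species_class)
    return dataset, truth


_DEFAULT_GLYCANS = {
    (("Hex", 5), ("HexNAc", 4)): 0.6,
    (("Hex", 5), ("HexNAc", 4), ("Fuc", 1)): 0.4,
}


def default_two_region_config(seed: int = 0, width: int = 40,
                              height: int = 40) -> SimulationConfig:
    """Two-region section with a 3:1 total-glycogen contrast.

    The left half ("high") carries three times the glycogen of the right
    half ("low"); both share a chain-length distribution peaked near DP 7
    and a 10% phosphorylated-chain fraction.
    """
    cl = poisson_cl_distribution(mean_dp=7.0)
    half = width // 2
    high = RegionSpec(name="high", bounds=(1, 1, half, height),
                      glycogen_scale=3.0, cl_distribution=cl,
                      phospho_fraction=0.10, glycan_panel=_DEFAULT_GLYCANS)
    low = RegionSpec(name="low", bounds=(half + 1, 1, width, height),
                     glycogen_scale=1.0, cl_distribution=cl,
                     phospho_fraction=0.10, glycan_panel=_DEFAULT_GLYCANS)
    return SimulationConfig(width=width, height=height, regions=(high, low),
                            seed=seed)


def default_liver_like_config(seed: int = 0) -> SimulationConfig:
    """Liver-like section: capsule/vein lining rich in glycogen over a
    hepatocyte background.

    Unphosphorylated chains peak at DP 6-8 (liver-like) while the
    phosphorylated profile peaks at shorter chains, reflecting the higher
    phosphate content of short chains.
    """
    cl = poisson_cl_distribution(mean_dp=7.5)
    cl_phospho = poisson_cl_distribution(mean_dp=4.5)
    capsule = RegionSpec(name="capsule", bounds=(1, 1, 40, 6),
                         glycogen_scale=3.0, cl_distribution=cl,
                         phospho_fraction=0.10,
                         phospho_cl_distribution=cl_phospho,
                         glycan_panel=_DEFAULT_GLYCANS)
    vein = RegionSpec(name="central_vein", bounds=(14, 14, 27, 27),
                      glycogen_scale=2.0, cl_distribution=cl,
                      phospho_fraction=0.10,
                      phospho_cl_distribution=cl_phospho,
                      glycan_panel=_DEFAULT_GLYCANS, shape="ellipse")
    hepatocyte = RegionSpec(name="hepatocyte", bounds=(1, 1, 40, 40),
                            glycogen_scale=1.0, cl_distribution=cl,
                            phospho_fraction=0.10,
                            phospho_cl_distribution=cl_phospho,
                            glycan_panel=_DEFAULT_GLYCANS)
    return SimulationConfig(width=40, height=40,
                            regions=(capsule, vein, hepatocyte), seed=seed)


def config_to_yaml(config: SimulationConfig, path) -> None:
    """Write a config as a YAML document (the documented schema is simply
    the dataclass field tree; glycan compositions as residue->count maps)."""
    import yaml

    doc = {
        "width": config.width, "height": config.height,
        "pixel_size": config.pixel_size,
        "adduct_mix": {Adduct(a).value: float(w)
                       for a, w in config.adduct_mix.items()},
        "mz_jitter_sd": config.mz_jitter_sd,
        "intensity_lognorm_sd": config.intensity_lognorm_sd,
        "intensity_floor": config.intensity_floor,
        "tic_variation_sd": config.tic_variation_sd,
        "background_ions": config.background_ions,
        "background_tic": config.background_tic,
        "background_drift_sd": config.background_drift_sd,
        "mz_window": list(config.mz_window),
        "seed": config.seed,
        "drift": {cls: {"slope": t.slope, "intercept": t.intercept,
                        "noise_sd": t.noise_sd}
                  for cls, t in config.drift.items()},
        "regions": [
            {
                "name": r.name, "shape": r.shape, "bounds": list(r.bounds),
                "glycogen_scale": r.glycogen_scale,
                "cl_distribution": {int(k): float(v)
                                    for k, v in r.cl_distribution.items()},
                "phospho_fraction": r.phospho_fraction,
                "phospho_cl_distribution": (
                    {int(k): float(v)
                     for k, v in r.phospho_cl_distribution.items()}
                    if r.phospho_cl_distribution else None),
                "glycan_panel": [
                    {"composition": dict(comp), "level": float(level)}
                    for comp, level in r.glycan_panel.items()],
            }
            for r in config.regions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = []
    for r in doc["regions"]:
        panel = {}
        for entry in r.get("glycan_panel") or []:
            comp = tuple((str(k), int(v))
                         for k, v in entry["composition"].items())
            panel[comp] = float(entry["level"])
        regions.append(RegionSpec(
            name=r["name"], shape=r.get("shape", "rect"),
            bounds=tuple(r["bounds"]),
            glycogen_scale=float(r["glycogen_scale"]),
            cl_distribution={int(k): float(v)
                             for k, v in r["cl_distribution"].items()},
            phospho_fraction=float(r.get("phospho_fraction", 0.0)),
            phospho_cl_distribution=(
                {int(k): float(v)
                 for k, v in r["phospho_cl_distribution"].items()}
                if r.get("phospho_cl_distribution") else None),
            glycan_panel=panel,
        ))
    drift = {cls: DriftTrend(**t) for cls, t in doc["drift"].items()}
    return SimulationConfig(
        width=int(doc["width"]), height=int(doc["height"]),
        pixel_size=float(doc.get("pixel_size", 50.0)),
        regions=tuple(regions),
        adduct_mix={Adduct(a): float(w)
                    for a, w in doc["adduct_mix"].items()},
        mz_jitter_sd=float(doc["mz_jitter_sd"]),
        intensity_lognorm_sd=float(doc["intensity_lognorm_sd"]),
        intensity_floor=float(doc["intensity_floor"]),
        tic_variation_sd=float(doc["tic_variation_sd"]),
        background_ions=int(doc.get("background_ions", 40)),
        background_tic=float(doc.get("background_tic", 50.0)),
        background_drift_sd=float(doc.get("background_drift_sd", 1.0)),
        mz_window=tuple(doc.get("mz_window", (500.0, 3000.0))),
        drift=drift, seed=int(doc["seed"]),
    )


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every noise source switched off."""
    return replace(config, mz_jitter_sd=0.0, intensity_lognorm_sd=0.0,
                   intensity_floor=0.0, tic_variation_sd=0.0,
                   background_ions=0, background_tic=0.0,
                   drift={c: DriftTrend(t.slope, t.intercept, 0.0)
                          for c, t in config.drift.items()})
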