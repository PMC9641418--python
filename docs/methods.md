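# Methods

## Ion chemistry

A linear glucose polymer of `dp` units released by isoamylase is `dp`
in-chain hexose residues plus one water; covalent phosphate (at the C2-,
C3- or C6-hydroxyls of glucose) adds one HPO3 group per site. All ions are
treated as singly charged, the MALDI norm for carbohydrates:

    m/z(dp, n_P, adduct) = dp·162.05282 + 18.01056 + n_P·79.96633 + m(adduct)

with monoisotopic constants (Da): hexose residue 162.05282, HexNAc
203.07937, fucose 146.05791, NeuAc 291.09542, water 18.01056, HPO3
79.96633, and electron-corrected charge carriers H+ 1.00728, Na+ 22.98922,
K+ 38.96316. Sodiated ions are the default: CHCA positive-mode MALDI of
neutral oligosaccharides is dominated by [M+Na]+, and only the sodiated
series reproduces the conventional integer species labels (CL7 → 1,175;
ladder spacing → 162, round-half-up). Potassiated satellites are supported
but not summed into the sodiated series. N-glycan masses are sums of
Hex/HexNAc/Fuc/NeuAc residues plus water plus the adduct; the default
two-glycan panel (Hex5HexNAc4 at m/z 1663.58, Hex5HexNAc4Fuc1 at 1809.64,
sodiated) represents the biantennary species commonly imaged after
PNGase F digestion.

Peak annotation assigns each observed centroid to the nearest theoretical
species within a tolerance (default ±0.2 Th, appropriate for TOF
resolution at 500–3,000 m/z; a ppm mode exists). An exact tie between two
species goes to the lower-mass one; each species keeps only its most
intense in-tolerance peak. Degenerate inputs (empty peak lists, windows
containing no species) return empty results rather than errors.

## Dataset model and I/O

Datasets are per-pixel centroided spectra on a 1-based rectangular grid
(y increasing downward, imzML convention), pixel size defaulting to 50 μm
(typical MALDI laser spot). m/z is stored as float64 and intensity as
float32, mirroring common vendor exports; the write→read round trip is
exact at those precisions. Ion-mobility drift times are carried as a
per-peak array and serialized to a plain-text sidecar
(`<name>.drift.tsv`, `%.17g` so float64 values survive exactly) next to
the .imzML/.ibd pair. When drift is absent, mobility operations refuse
rather than impute. The imzML file UUID is derived from a content hash so
identical datasets produce byte-identical files — simulator runs with the
same seed are checksum-reproducible. ROI masks are raster images (PNG/PGM,
nonzero = selected) or whitespace-delimited 0/1 grids with the dataset's
dimensions; empty or mismatched masks are rejected.

## Quantification

Ion images sum, per pixel, the intensity within the tolerance window of a
species; under TIC normalization (the default, matching standard MSI
practice) the pixel is first divided by its total ion current, with
zero-TIC pixels mapped to zero.

Chain-length profiles are computed over an ROI split into `n` technical
replicates (default 3). Replicates are contiguous row-major runs of equal
size through the ROI's pixels — a deterministic, seed-free convention
chosen because regional "technical replicates" in imaging studies are
sub-areas of one region. Within a tile, TIC-normalized species signals are
summed over pixels and expressed as relative abundance in one of two
conventions:

- `ladder_share` (default): each species' share of the summed
  unphosphorylated ladder signal. Profiles sum to one, are comparable
  across tissues, and isolate *architecture* from *amount*.
- `tic`: mean per-pixel TIC share. This retains between-ROI differences in
  absolute glycogen level and is the right mode for comparing total
  glycogen across regions (the ladder-share total is scale-free by
  construction and cannot carry that contrast).

The phosphorylated (n_P = 1) ladder is quantified with the same
denominator as the unphosphorylated one, so phospho levels plot on the
same scale. When an ROI has no unphosphorylated signal at all, the
phospho sum takes over as denominator so purely phosphorylated material
still yields a defined profile.

Summary metrics: total glycogen is the sum of mean relative abundances
over CL3–CL18 (longer quantified chains are excluded by definition); the
CL3-normalized distribution divides each mean by the CL3 mean and is
reported as missing with a warning when CL3 is absent; the per-chain
phosphorylation fraction is phospho/(phospho+unphospho), undefined (NaN,
warned) when both are zero. SEMs are over replicate tiles throughout.

Note that the default sodiated ladder restricted to the 500–3,000 Th
acquisition window spans DP 3–18; DP 19–25 lie above 3,000 Th and are
only reachable with a wider window.

## Mobility classification

For singly charged ions of one chemical class, drift time through a
traveling-wave cell grows approximately with collision cross section,
which for a homologous series scales like the square root of mass; each
class therefore traces a line in the drift vs √(m/z) plane. The model
fits one least-squares line per class from ions identified confidently by
mass alone (ladder matches within half the matching tolerance), requiring
at least three seed points per class. The residual scale is the median
absolute residual × 1.4826 (a robust Gaussian sigma), floored at 1e-9 ms
so exact fits remain usable. Classification assigns each ion to the class
with the smaller |residual|/scale, leaves it unassigned beyond
`max_sigma` (default 4), and breaks exact ties toward the glucose-polymer
class. The procedure is deterministic and order-invariant. No quantitative
class boundary exists in the assay itself — the visual separation in the
drift-time scatter is what `max_sigma` formalizes.

## Spatial analysis

Radial profiles bin pixels by center-to-center Euclidean distance (μm,
via the pixel size) from a landmark pixel into contiguous annuli,
reporting per-bin mean, SEM and counts — the "pixel analysis" of a
gradient radiating from an anatomical landmark. ROI summaries report
mean, tile-based SEM and pixel count per mask, flagging overlapping
masks; over a partition of the grid the pixel-weighted ROI means
reconstruct the global mean exactly. Heatmaps scale intensity linearly
over the image's finite range (percentile clipping at e.g. 0.1–99.9 is
available because MALDI hotspots otherwise dominate a linear display) and
render through white→red, blue→red or black→yellow gradients with a scale
bar derived from the pixel size.

## Group statistics

One-way ANOVA uses the classical F test with Tukey HSD adjusted p-values
from the studentized-range distribution. Two-way ANOVA (type II sums of
squares via statsmodels) reports main effects and interaction; pairwise
Tukey comparisons are made between levels of the first factor *within
each level of the second* (region differences per chain length), using
the pooled residual MSE of the full two-way model — the convention of
per-chain-length comparisons in regional imaging figures. Unpaired
t-tests default to Welch (unequal-variance-safe; pooled available);
degenerate zero-variance inputs return p = 1 (equal means) or p = 0
(unequal), flagged. Significance bands: * 0.01<p<0.05, ** 0.001<p<0.01,
*** p<0.001, **** p<0.0001.

## Simulator

The generator emulates an enzyme-digested section: 2–4 regions (filled
rectangles or inscribed ellipses; the first containing region claims a
pixel), each with a glycogen scale, a discrete chain-length distribution
over DP 3–25 (a shifted-Poisson family is provided; the default peaks at
DP 6–7, liver-like), a phosphorylated-chain fraction (default 10%), an
optional separate phospho chain-length distribution (the liver-like
config peaks it at shorter DP, reflecting the higher phosphate content of
short chains), and an N-glycan panel. Expected peak intensity is
scale × P(dp) × phospho-weight × adduct-weight (default Na 0.85 / K
0.15). Noise: Gaussian m/z jitter (0.03 Th), mean-one multiplicative
lognormal intensity noise (sigma 0.25) chosen over additive Gaussian to
keep intensities nonnegative and mimic MALDI hotspotting, a small
additive floor, and per-pixel lognormal TIC variation (sigma 0.2). Drift
times follow the per-class linear trends plus Gaussian noise (0.15 ms).

Each pixel additionally receives 40 matrix-background ions (Dirichlet-
split total intensity 50, uniform random m/z kept ≥ 0.5 Th from every
ladder/glycan species, broad drift spread). Real MALDI TICs are dominated
by matrix and chemical noise; without this component TIC normalization
would erase regional glycogen contrast entirely. With it, the simulated
3:1 contrast reads out as ≈ 2.9 — the same mild compression real
TIC-normalized data show.

Randomness is drawn from one `numpy` Philox-family stream per pixel,
keyed by (seed, x, y): output is bit-reproducible for a fixed seed and
independent of generation order. The default study conditions are a
40×40 grid with two half-sections at scales 3.0 and 1.0 — sized so the
recovery tests run in seconds while leaving several hundred pixels per
replicate tile.

What the simulator does **not** model: desorption/ionization physics,
matrix crystal heterogeneity, detector saturation, isotope envelopes,
in-source fragmentation, chemical background that overlaps ladder masses,
or spatial autocorrelation of noise. Passing recovery tests therefore
demonstrates that the pipeline's estimators are correct and well
calibrated under the stated generative model, not that the assay itself
is free of matrix or digestion artifacts on real tissue.

## Numerical conventions

Integer species labels round half-up. Peak-match ties go to the
lower-mass species; mobility ties to the glucose-polymer class. Jittered
peaks that collide in m/z are nudged apart by one float64 ulp to keep
axes strictly increasing. Monte-Carlo calibration checks in the test
suite use 2,000 null replicates (standard error ≈ 0.005 on a 0.05 rate)
with fixed seeds.
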