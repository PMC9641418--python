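# glycomsi

Spatial glycogen architecture from enzyme-assisted MALDI mass spectrometry
imaging (MSI).

Glycogen stores and their molecular architecture — chain-length
distribution and covalent phosphate content — vary between tissue regions
and are reshaped in disease, but classical stains (PAS) and bulk
chromatography cannot resolve them in space. In the enzyme-assisted MSI
assay, isoamylase sprayed onto a fixed tissue section cleaves the
α-1,6 branch points of glycogen, releasing linear α-1,4 glucose chains of
3–25 units that appear in every pixel's MALDI spectrum as a ladder of
singly charged ions spaced one hexose residue (162.05 Da) apart.
Co-spraying PNGase F additionally releases N-linked glycans, which
traveling-wave ion mobility separates from the glucose polymers by drift
time. `glycomsi` is the computational read-out of that assay, for mass
spectrometrists and glycobiologists working with imzML imaging data:

- **mass_ladder** — theoretical m/z of glucose polymers
  (dp·162.05282 + 18.01056 + adduct, optionally + n·79.96633 for covalent
  phosphate), N-glycan compositions, ladder construction over an
  acquisition window, and nearest-species peak annotation.
- **msi_io** — imzML read/write (continuous and processed modes), drift-time
  sidecars, ROI masks (image or 0/1 text grids).
- **quantify** — TIC-normalized ion images; per-ROI chain-length
  distributions with n = 3 technical-replicate tiles; total glycogen as the
  CL3–CL18 sum; CL3-normalized distributions; per-chain phosphorylation
  fractions.
- **mobility** — per-class linear trends drift = a·√(m/z) + b fitted from
  confident mass matches, then scaled-residual classification of every ion
  as glucose polymer vs N-glycan.
- **spatial** — ROI summaries, radial pixel analyses (e.g. gradients away
  from a central vein), heatmap rendering (white→red, blue→red,
  black→yellow gradients).
- **group_stats** — one-/two-way ANOVA with Tukey's multiple comparisons
  and two-tailed t-tests, with the figure-style significance bands.
- **synthetic** — a seeded simulator of glyco-MSI tissue sections with
  known ground truth (regional glycogen scales, chain-length
  distributions, phospho fractions, adduct mixtures, drift trends, noise).

## Worked example

Simulate the default two-region section (40×40 pixels, 3:1 glycogen
contrast, 10% phosphorylated chains), then quantify both regions:

```python
import numpy as np
import glycomsi as g
from glycomsi import mass_ladder as ml

cfg = g.default_two_region_config(seed=7)
dataset, truth = g.simulate(cfg)
ladder = ml.build_ladder(3, 25, phospho_max=1)
high, low = cfg.region_masks()

hi = g.chain_length_profile(dataset, high, ladder, abundance="tic")
lo = g.chain_length_profile(dataset, low, ladder, abundance="tic")
print(f"ratio={hi.total_glycogen / lo.total_glycogen:.2f}")

prof = g.chain_length_profile(dataset, high, ladder)
for i in np.argsort(prof.mean_abundance)[::-1][:3]:
    print(f"CL{prof.dp_axis[i]}: {prof.mean_abundance[i]:.3f} "
          f"+/- {prof.sem[i]:.3f}")
print(f"phospho fraction at CL7: {g.phospho_fraction(prof, 7):.3f}")
```

prints

```
ratio=2.88
CL7: 0.194 +/- 0.003
CL6: 0.194 +/- 0.001
CL8: 0.158 +/- 0.001
phospho fraction at CL7: 0.101
```

The TIC-share total-glycogen ratio recovers the simulated 3:1 contrast
(slightly compressed by TIC normalization against the matrix background);
the most abundant chain lengths sit at CL6–CL8 as configured, with
mean ± SEM over the three replicate tiles; and the per-chain
phosphorylation fraction recovers the simulated 10%.

The same workflow is available from the shell:

```sh
glycomsi simulate --seed 7 --out run/
glycomsi profile --input run/section.imzML \
    --mask run/mask_high.txt --mask run/mask_low.txt --out run/profiles/
glycomsi compare --profiles run/profiles/profiles.tsv \
    --design two_way --out run/stats/
glycomsi render --input run/section.imzML --species CL7 \
    --colormap white_red --out run/images/
```

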