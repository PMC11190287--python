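# biotex

Quantitative crystallographic-texture analysis for biomineral EBSD maps,
with a companion Raman screen for diagenetic alteration. Built for the
question of how much control an organism exerts over the orientation of
apatite crystals in its hard tissues — conodont dental elements being the
motivating system, where crystallographic order in the enamel-like crown
tissue tracks the evolution of dental function — but applicable to any
hexagonal biomineral mapped on a square grid.

## What it computes

Given per-pixel crystal orientations (Oxford CTF or EDAX ANG text formats),
`biotex` estimates the orientation distribution function as a de la Vallée
Poussin kernel density on SO(3),

    f(g) = (1/N) Σᵢ ψ_κ(ω(g, gᵢ)),   ψ_κ(ω) = C(κ) cos^{2κ}(ω/2),

symmetrized over the 12 proper rotations of hexagonal apatite (point group
622), with κ set by a halfwidth of 4° (half maximum in misorientation
angle). From the ODF and the raw orientations it derives the scalar indices
used to compare fabrics:

* **Texture Index** TI = ∫ f(g)² dg — 1 for a random fabric, growing with
  preferred orientation (deterministic fundamental-zone quadrature,
  cross-checked against a closed-form kernel series and Monte Carlo);
* **M-index** — half the total-variation distance between the uncorrelated
  misorientation-angle distribution and the symmetry's random (Mackenzie)
  reference; 0 random, → 1 single crystal;
* **pole figures / MUD** — antipodally symmetric spherical kernel densities
  of <0001>, <10-10> or <11-20> in specimen coordinates, normalized to
  multiples of uniform density, with **pfJ** = ∫ MUD² their per-axis
  texture index;
* **grain-reconstruction diagnostics** — threshold segmentation with the
  sub-2-pixel discard and fill steps, plus the fraction of inferred grain
  boundaries coinciding with non-indexed pixels (the reason grain sizes are
  not trustworthy in these tissues);
* **subsampling statistics** — TI/M-index/pfJ over randomly placed squares,
  the Pearson TI-versus-area test, Kruskal-Wallis and pairwise Wilcoxon
  comparisons with Bonferroni correction (α/6 → 0.83%, 99.17% CIs);
* **Raman ν₁-PO₄³⁻ band** — pseudo-Voigt + linear-baseline fits giving the
  peak center (PCMI) and FWHM, and ranged major axis (model II) regression
  of FWHM on PCMI for cross-dataset diagenesis screening.

A first-class synthetic-data generator produces EBSD maps with known ground
truth — c-axes dispersed about the occlusal axis, a-axis rotation ranging
from a uniform girdle through dispersed to 3-cluster archetypes, elongated
spatially coherent patches, and realistic non-indexed fractions — so every
stage of the pipeline is testable without any instrument data.

## Worked example

Generate a synthetic map (default recipe: c-axis dispersion 10° about the
specimen X axis, 25% non-indexed pixels), then summarize its texture:

```
$ biotex simulate map --seed 11 --width 48 --height 48 --out demo.ctf
wrote demo.ctf (+ ground truth), indexed fraction 0.75

$ biotex texture --input demo.ctf
{"ti": 35.2639316496964, "pfj_c": 22.772067068829045,
 "pfj_a": 4.584789763559302, "max_mud": 46.6858892648665,
 "area_um2": 576.0, "n_orientations": 1728}

$ biotex mindex --input demo.ctf --pairs 100000 --seed 42
{"m_index": 0.791088, "n_pairs": 100000}
```

Reading the numbers: TI ≈ 35 means the squared ODF integrates to 35 times
the uniform value — a strongly ordered fabric (real conodont crown tissues
span roughly 12–68 on average per taxon, coniform taxa at the low end,
platform-bearing taxa at the high end). pfJ_c ≫ pfJ_a says most of that
order is c-axis alignment with the functional axis, with the rotation about
c only moderately constrained; max MUD ≈ 47 is the peak pole-figure
density, and M ≈ 0.79 confirms a misorientation distribution far from the
random reference. All indices are inflated on small pixel counts (kernel
density bias ≈ 709/N at 4° halfwidth) — which is why the subsampling
commands exist:

```
$ biotex subsample --input demo.ctf --sizes 13,18,25,34 --n 25 --seed 7 --out sub.csv
$ biotex compare --tables ti_by_taxon.csv     # Kruskal-Wallis + pairwise Wilcoxon
$ biotex grains --input demo.ctf --thresholds 1,5,9,13,17 --out grains.csv
$ biotex raman fit --input spectrum.csv
```

The same functionality is importable (`biotex.build_odf`,
`biotex.texture_index`, `biotex.pole_density`, `biotex.subsample_squares`,
`biotex.fit_v1_band`, ...); the CLI is a thin wrapper.

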