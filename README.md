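# fibrilscape

Quantitative analysis of polyglutamine (huntingtin exon-1) fibril
polymorphs: small-angle X-ray scattering modelling and fitting, fibril-core
geometry arithmetic, ThT aggregation-kinetics preprocessing, 1D ssNMR
window integration, and TEM width morphometrics — with a seeded
synthetic-data generator for every input type, so the whole pipeline
builds and tests without instrument data.

## The problem

Huntingtin exon-1 fragments with an expanded polyQ tract aggregate into
amyloid fibrils whose rigid core is built from polyQ β-strands
(~0.35 nm rise per residue), decorated by flexible flanking domains
("fuzzy coat").  Small-molecule inhibitors such as curcumin can reroute
the misfolding pathway, producing thinner fibrils whose polyQ tract is
folded into β-hairpins rather than extended strands.  The experimental
fingerprints of that switch are:

* **SAXS** — the 1D profile of a fibril bundle suspension,

  I(q) = A·[∫ P(q, r, L) N(r) dr]·S(q, d, ν) + B/qⁿ + C,

  with P the orientation-averaged form factor of a long cylinder
  (length L fixed at 1000 nm), N(r) a log-normal distribution of
  cross-section radii, and S a PRISM-style structure factor whose broad
  maximum at q_max encodes the inter-fibrillar stacking distance
  d = 2π/q_max inside bundles.  Fitting yields the cross-section
  diameter 2r and d.
* **TEM** — fibril-width histograms per preparation condition.
* **ThT kinetics** — sigmoidal fluorescence time courses whose lag
  phase reports nucleation; inhibitors extend it.
* **ssNMR** — 1D ¹³C CP spectra; the ratio of integrated Gln Cα to Pro
  Cα/Cδ windows (Q/P ratio) reports the rigidity of the proline-rich
  flanking domain.
* **Geometry** — core width = ((Q − (s−1)·t)/s)·0.35 nm for a tract of
  Q residues in s strands with t-residue turns, times the filament
  count; enumerating (s, filaments) architectures against an observed
  width ranks candidate fibril models.

## Worked example

Rank polyQ-core architectures against a 10 nm TEM width for a Q32 tract:

```
$ fibrilscape geometry --polyq 32 --observed-width 10
strands=2 filaments=2 width=9.80 nm err=2.0%
strands=1 filaments=1 width=11.20 nm err=12.0%
```

Two architectures are compatible: a double filament of β-hairpins
(2 × 4.9 nm) or a single filament of extended strands (11.2 nm).

Simulate a bundle scattering curve at the uninhibited ground truth
(2r = 12 nm, d = 24 nm, 2% noise) and fit it back:

```
$ fibrilscape synth --kind saxs --seed 7 --out saxs_demo.dat
$ fibrilscape saxs-fit saxs_demo.dat --seed 7 --out fit.json
2r = 11.84 nm, d = 24.18 nm -> fit.json
$ fibrilscape saxs-analyze saxs_demo.dat --out analysis.json
alpha = 1.067 -> analysis.json
```

The fit recovers the cross-section and stacking distance within a few
percent, and the low-q power-law exponent α ≈ 1 is the signature of
long rod-like scatterers.  Width morphometrics on synthetic TEM data
(10 ± 1.5 nm vs 4 ± 1 nm conditions):

```
$ fibrilscape synth --kind tem --seed 7 --out tem_demo.csv
$ fibrilscape tem-stats tem_demo.csv
control: n=200 mean=9.89 nm sd=1.50 median=9.81
inhibited: n=200 mean=3.95 nm sd=0.96 median=3.98
control - inhibited: diff=5.94 nm (95% CI 5.69..6.17), p=5.447e-67
```

`fibrilscape demo --seed 7` runs every stage end-to-end on a synthetic
with/without-inhibitor pair, and `fibrilscape run config.toml` drives
selected stages from a TOML config.

## Layout

```
src/fibrilscape/
  saxs_model.py   forward model + profile analyses (slope, peak, Guinier)
  saxs_fit.py     multi-start log-space least squares, region segmentation
  geometry.py     polyQ core-width arithmetic, architecture enumeration
  kinetics.py     ThT preprocessing, lag/t50/growth-rate extraction
  ssnmr.py        window integration, Q/P ratios, noise-based errors
  tem.py          width statistics and condition comparison
  synthetic.py    seeded generators for all of the above
  io.py           plain-text format readers/writers
  cli.py          command-line interface and config-driven pipeline
```
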