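# camovis

Avian colour-vision modelling and camouflage-analysis pipeline for
reflectance-spectrometry experiments, with the statistical machinery used in
larval colour-change and background-choice studies:

- **spectra** — read delimited spectrometer tables (comma/tab autodetected,
  percent-vs-proportion autodetected), resample to the fixed 1 nm grid over
  300–700 nm, average replicate measurements per individual, group
  mean ± SE summaries.
- **vision** — blue tit viewer built from the Govardovskii A1 pigment
  template (λmax 371/448/503/563 nm, double cone sharing the LW pigment)
  under quantal D65 (or a flat "ideal" illuminant); quantum catches,
  greenness `MW/(MW+LW)`, double-cone luminance, tetrahedral colour-space
  coordinates (circumradius 0.75, UV on +z), and receptor-noise-limited
  chromatic/achromatic discriminability in JND units (Weber fraction 0.05,
  cone abundances UV 0.3704 / SW 0.7111 / MW 0.9926 / LW 1.0) with the
  <1 / 1–3 / >3 JND interpretation classes.
- **behaviour** — linear models with per-term F tests (Type II marginal by
  default, Type I selectable) on (log10) greenness/luminance/JND, and
  logit-link binomial GLMs of background-choice matching success with Wald
  z statistics and a separation flag.
- **expression** — RT-qPCR relative expression
  `(E_ref^Cp_ref)/(E_target^Cp_target)` against the *spectrin* reference
  (E idealised to 2), dermal proportion `dermal/(head+dermal)`, a
  hand-written maximum-likelihood beta regression of stage effects, and
  log10 stage contrasts.
- **simulate** — seeded generators for smooth synthetic reflectance
  spectra (treatment × blindfold reaction-norm design), Bernoulli choice
  trials, and structured qPCR Cp tables, so the whole pipeline is testable
  without any external data.
- **pipeline / cli** — end-to-end orchestration with YAML config,
  deterministic CSV/JSON outputs and a text report.

## CLI

```sh
# full synthetic run: simulate -> perceive -> stats -> expression -> report
camovis run --seed 1 --out runs/demo
camovis report --run-dir runs/demo

# individual stages
camovis simulate colour --seed 1 --out sim/
camovis simulate choice --seed 1 --out sim/
camovis simulate qpcr   --seed 1 --out sim/
camovis perceive --spectra sim/spectra.csv --metadata sim/metadata.csv --out out/
camovis stats --summaries out/perceptual_summary.csv --jnd out/discrimination.csv --out out/
camovis expression --qpcr sim/qpcr.csv --out out/
```

Useful flags: `--viewer` (built-in `bluetit`, `bluetit-ideal`, or a YAML
viewer file overriding λmax/abundances/Weber/illuminant),
`--aggregate {individual,measurement}` (average the six replicate
measurements per larva, the default, or model every measurement),
`--anova-type {1,2}`, and `--config` for a YAML run configuration
(generator parameters, design group sizes, input paths).

### Input dialects

Spectra: first column `wavelength_nm`, one column per measurement named
`<individual_id>_<rep>`. Metadata sidecar: `individual_id`, `family`,
`treatment` (black|white|brown|green), `blindfold` (control|painted|none),
`life_stage` (larva|dowel). Choice trials and qPCR tables are long CSVs;
see `camovis simulate` output for exemplars of every dialect.

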