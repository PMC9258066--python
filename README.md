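# methylosip

Identify active methanol-utilizing bacteria from RNA stable-isotope-probing
(SIP) experiments and estimate potential methanol consumption rates from
14C-methanol incubations.

In RNA-SIP, plants or soils are fed a 13C-labelled substrate; organisms that
assimilate it build isotopically heavy rRNA, which equilibrates at higher
buoyant density (BD) in an isopycnic CsTFA gradient. After fractionating
paired 13C-treatment and 12C-control gradients and sequencing 16S rRNA
amplicons per fraction, a taxon *i* is called **13C-labelled** when all three
criteria hold for a matched gradient pair:

1. `p_i(heavy, 13C) > p_i(heavy, 12C)` — more abundant in the treatment's
   heavy fraction than in the control's;
2. `p_i(heavy, 13C) > K · p_i(light, 13C)` with `K = 2` — enriched in the
   heavy over the light fraction of the same gradient;
3. `p_i(heavy, 13C) ≥ 0.05 %` — above the noise floor,

where `p_i(f, ·)` is the relative abundance in density class *f* after
pooling fractions per class. For radiotracer incubations, the cumulative
14CO2 activity `A(t)` in NaOH traps is regressed on time and converted to a
potential consumption rate

```
rate [nmol g⁻¹ h⁻¹] = slope(A ~ t) [Bq h⁻¹] / (specific activity [Bq nmol⁻¹] × dry mass [g])
```

with trap mass-balance and NaOH-vs-BaCO3 cross-check QC. The package also
provides the standard OTU-table summaries (singleton removal, Shannon,
bias-corrected Chao1, analytic rarefaction, Michaelis–Menten asymptotic
richness, Bray–Curtis) and δ13C two-point VPDB normalization, plus a
synthetic-data module that simulates the full study design (2 plant species
× 3 compartments × 2 isotopes × 2 timepoints) with known ground truth.

## Worked example

```sh
methylosip simulate sip --seed 4 --outdir data/
methylosip call-labelled --otu data/otu.tsv --meta data/fractions.tsv --out calls.tsv
```

`data/` now holds a 20-taxon, 60-fraction simulated experiment
(`truth.tsv` lists which 5 OTUs truly assimilated the substrate).
`calls.tsv` has one row per taxon per gradient pair:

```
context                          taxon_id  abund_heavy_c13  abund_heavy_c12  abund_light_c13  c1     c2     c3     labelled
T_officinale|phyllosphere|8h     OTU003    0.00042          0.10872          0.18054          False  False  False  False
T_officinale|phyllosphere|8h     OTU004    0.22966          0.01470          0.01520          True   True   True   True
```

OTU004 is 23 % of the treatment's heavy fraction but only 1.5 % of the
control's heavy and of the treatment's light fraction — it passes all three
criteria and is called labelled; OTU003 shows no heavy enrichment and is
not. Comparing against `truth.tsv` (true labelled set OTU004, OTU009,
OTU010, OTU012, OTU019), every truly labelled OTU is recovered.

The same library drives rate estimation:

```sh
methylosip simulate traps --seed 4 --outdir data/
methylosip rates --traps data/traps.tsv --incubations data/incubations.tsv --out rates.tsv
```

which fits one regression per incubation and reports
`rate_nmol_per_g_per_h` together with `r_squared`, the trap recoveries and
QC flags (24 simulated incubations: 2 species × 3 compartments × 4
replicate bottles, rates of order 60–150 nmol g⁻¹ h⁻¹). A full
config-driven run (`methylosip run --config cfg.yaml --outdir run/`) chains
simulation, fraction classification, labelling calls, rate estimation and
diversity summaries, and writes a `manifest.json` with checksums of every
output.

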