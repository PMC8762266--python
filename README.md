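# admiximpute

Genotype-imputation accuracy in admixed cohorts depends on how well each
ancestry is represented in the reference panel. For Latin American
populations — a three-way mosaic of African, European and Native American
ancestry — standard panels are rich in African and European haplotypes but
carry very few Native American genomes, and commercial genotyping arrays
are ascertained mostly in European discovery samples. `admiximpute` is a
desk-scale pipeline for quantifying the resulting accuracy gap and for
projecting how many reference genomes from the underrepresented ancestry
are needed to close it.

The pipeline:

1. **Simulation** (`admiximpute.sim`): three differentiated source
   populations (Balding–Nichols site frequencies around shared ancestral
   frequencies, founder-mosaic haplotypes for realistic LD) and a
   single-pulse admixed cohort (1/6 AFR, 1/3 EUR, 1/2 NAT, 12 generations
   ago) whose haplotypes are ancestry mosaics with exact truth tracts.
2. **Array design** (`admiximpute.arraydesign`): an emulated SNP array that
   matches a common-variant-weighted MAF spectrum in the European source
   (ascertainment bias) and a target mean marker spacing; everything not on
   the array is held out as imputation truth.
3. **Imputation** (`admiximpute.hmm`): a haploid Li–Stephens copying HMM
   per target haplotype. The hidden state is the reference haplotype being
   copied; between adjacent typed sites the switch probability is
   `s = 1 − exp(−4·Ne·d/H)` (`d` in Morgans, `H` reference haplotypes), and
   the observed allele differs from the copied one with mis-copy
   probability λ. Posteriors come from scaled forward–backward recursions,
   are linearly interpolated in genetic distance at untyped sites, and the
   two haploid allele probabilities `a, b` of an individual combine into
   genotype probabilities `(P(AA), P(Aa), P(aa))`, dosage
   `d = P(Aa) + 2·P(aa)`, and the IMPUTE-style INFO score.
4. **Stratified evaluation** (`admiximpute.strata`, `admiximpute.evaluation`):
   dosage r² pooled within local-ancestry-diplotype × MAF-class strata
   (diplotypes AFR_AFR … NAT_NAT from truth tracts; classes common
   0.05–0.5, low 0.01–0.05, rare 0.003–0.01), GWAS-quality SNP counts
   (MAF ≥ 0.01 and INFO > 0.3), paired panel comparisons, and the
   incremental-reference-panel experiment with its gap analysis.

## Worked example

`analysis/` contains the numbered study scripts. The headline experiment
(`python analysis/04_incremental_panels.py`) imputes 30 admixed targets
against a base panel of 66 AFR + 50 EUR + 35 admixed individuals plus
0/20/50/100 added NAT reference individuals on a 50 Mb chromosome, and
prints:

```
NAT_NAT dosage r2 by added NAT references:
maf_bin     common    low   rare
added_refs
0            0.576  0.230  0.000
20           0.824  0.632  0.074
50           0.940  0.840  0.549
100          0.980  0.939  0.786

EUR_EUR (reference ancestry, expected flat):
maf_bin     common    low   rare
added_refs
0            0.929  0.821  0.459
20           0.927  0.818  0.462
50           0.926  0.817  0.451
100          0.925  0.817  0.442
```

Reading this: with no NAT references, variants inside double-NAT ancestry
tracts impute far worse than in double-EUR tracts (rare bin: r² 0.00 vs
0.46). Adding NAT reference genomes raises accuracy only in
NAT-containing tracts — double-EUR accuracy stays flat — and the rare bin
improves the most (Δr² 0.79 vs 0.40 for common). The script also reports
the smallest addition at which NAT_NAT accuracy reaches EUR_EUR per
frequency class (a 2 % split), the simulated analogue of asking how many
genomes close the gap.

The same machinery is scriptable from a YAML config:

```sh
admiximpute experiment --config configs/demo.yaml -o out/
admiximpute report --accuracy out/accuracy.tsv -o out/curves.png
```

where the config needs at least a `seed` (all other keys — panel
sizes or a `scale` factor, chromosome, array targets, HMM parameters —
have defaults; see `docs/methods.md`). The `simulate`, `ascertain`,
`impute` and `evaluate` subcommands run the same stages file-by-file
(VCF / TSV / site-list formats) and reproduce `experiment` exactly.

## Layout

- `src/admiximpute/` — library: `sim`, `arraydesign`, `hmm`, `strata`,
  `evaluation`, `io`, `config`, `cli`.
- `analysis/` — numbered study drivers writing to `results/analysis/`.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — model details, parameter choices, limitations.
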