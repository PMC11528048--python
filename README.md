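# snoridr

Quantitative tooling around the lysine-rich (KKE/D) intrinsically
disordered regions of nucleolar snoRNP proteins and their consequences for
ribosomal RNA modification. The package bundles three analysis tracks that
normally live in separate toolchains, plus synthetic-data generators that
make every track testable end to end without any external download:

1. **rRNA modification scoring from read-end counts.**
   RiboMethSeq exploits the protection of the phosphodiester bond 3' of a
   2'-O-methylated ribose against alkaline cleavage: with `c(i)` the
   combined 5'/3'-read-end count at internucleotide bond `i`, the
   methylated fraction at a site is estimated by the MethScore (ScoreC2)

   `score = clamp(1 − c_site / μ, 0, 1)`, `μ = ½(mean c over 2 bonds left + mean over 2 bonds right)`.

   HydraPsiSeq exploits the resistance of pseudouridine to
   hydrazine/aniline cleavage: 5'-end counts at each uridine are
   normalized to the A/C/G background in a 10-nt window (NormUcount) and
   to a robust baseline over all uridines, giving a PsiScore with the
   same clamp(1 − ratio) form. Wild-type/mutant comparisons use the
   unpaired two-sample Wilcoxon test with box-plot summaries
   (median, quartiles, 1.5·IQR whiskers) and the usual star convention.

2. **IDR charge patterning.** Per-segment fraction of charged residues
   (FCR = f⁺ + f⁻), net charge per residue (NCPR = f⁺ − f⁻), net charge
   per domain (NCPD), the kappa charge-segregation index (blob sizes 5
   and 6, normalized by the maximally segregated rearrangement of the
   same composition), a diagram-of-states classification (weak /
   boundary / strong polyampholyte / strong polyelectrolyte), and a
   detector for the KKE/D hallmark: chains of KK doublets spaced by 1–3
   polar residues (E/D/H/S).

3. **Enrichment statistics.** ChIP-qPCR IP/Input ratios from
   triplicate-median Ct values with dilution correction
   (`ratio = 2^−ΔCt`), TurboID proximity-labeling enrichment (median
   iBAQ normalization, Perseus-style down-shifted imputation of missing
   control values, log2 bait/control enrichment, pairwise Welch tests
   between protein categories), and microscopy ROI statistics
   (max/average focal ratio, nucleolus/nucleoplasm intensity ratio).

The synthetic generators plant known truths — per-site modified
fractions under a lognormal cleavage-propensity noise model, KKE/D
segments in a synthetic proteome, enrichment effects in qPCR/iBAQ/ROI
tables — so every score has a recovery target.

## Worked example

The analysis drivers run the whole study from nothing:

```bash
python analysis/01_simulate_study.py     # synthetic reference, reads, proteome, fixtures
python analysis/02_score_modifications.py
python analysis/03_idr_charge_scan.py
python analysis/04_enrichment_stats.py
```

`02_score_modifications.py` scores 55 Nm and 47 Ψ sites (depth 1000,
propensity noise sd 0.5, three replicates per condition) and prints:

```
Nm wt: 55 sites, MAE vs truth 0.053, 27 highly modified (>0.8)
Psi wt: 47 sites, MAE vs truth 0.076, 17 highly modified (>0.8)
Nm: WT median 0.80 vs mutant 0.44, Wilcoxon p = 5.70e-15 ****
Psi: WT median 0.72 vs mutant 0.33, Wilcoxon p = 1.20e-10 ****
```

i.e. the planted modification fractions are recovered to within ~0.05–0.08
mean absolute error in the wild type, and the simulated global 0.4 loss of
modification in the mutant is detected with overwhelming significance.
`03_idr_charge_scan.py` prints the charge arithmetic of the published
[KKE/D]x9 peptide:

```
[KKE/D]x9 peptide (28 aa):
  FCR = 1.000, NCPR = 0.357, NCPD = +10
  class: positive strong polyelectrolyte
  KKE/D detector: 1 segment, 9 KK doublets, spacers {'E': 4, 'D': 4}
```

Every residue of the peptide is charged (19 K against 5 E + 4 D), its net
charge per residue 10/28 ≈ 0.357 puts it past the strong-polyelectrolyte
boundary of the diagram of states, and the repeat detector recovers the
nine lysine doublets its name promises.

A `snoridr` console script exposes the same stages as subcommands
(`simulate`, `rms-score`, `hps-score`, `compare`, `idr-scan`,
`chip-ratio`, `turboid-enrich`, `roi-stats`); every run writes a JSON
manifest with the resolved parameters and outputs.

## Layout

- `src/snoridr/` — the library: `synthetic` (generators), `end_profiles`
  (BED/SAM parsing, end and bond counting), `mod_scoring` (MethScore,
  NormUcount/PsiScore, comparisons), `idr_charge` (FCR/NCPR/NCPD, kappa,
  diagram of states, KKE/D detection, proteome scan), `quant_stats`
  (qPCR/iBAQ/ROI statistics), `cli`.
- `analysis/` — numbered drivers writing tables under `results/`.
- `tests/` — unit, property (hypothesis) and end-to-end acceptance tests.
- `docs/methods.md` — models, parameter choices and limitations.
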