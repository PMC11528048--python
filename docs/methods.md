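# Methods

## Read-end counting conventions

Bases are 1-based; internucleotide bond `i` joins bases `i` and `i+1`
(bonds `1..L−1`). A read at BED interval `(start, end)` contributes a
5'-end at base `start+1` and a 3'-end at base `end`; the combined cleavage
count of bond `i` is `c(i) = n3(i) + n5(i+1)`. Ends at the molecule
boundaries (5'-end at base 1, 3'-end at base `L`) belong to no internal
bond and are dropped by the bond profile. A 2'-O-methylation at base `n`
protects bond `n` — the bond 3' of the methylated ribose — so the scored
bond index equals the annotated base position. For HydraPsiSeq the counted
5'-end position is the cleaved uridine plus a configurable offset
(default 0); the simulator and the scorer share the setting, because the
protocol chemistry fixes the offset but published descriptions do not
state it.

Read selection follows the RiboMethSeq rule: only reads strictly shorter
than 40 nt enter RMS counting (both ends of a short fragment are exact);
HPS counting uses 5'-ends of all reads. Minus-strand alignments are
discarded with a logged count (the rRNA reference is a sense-strand
sequence), duplicates are counted rather than collapsed (cleavage
frequency is the signal), and SAM support is restricted to ungapped
primary alignments — gapped or clipped records have ambiguous fragment
ends and are rejected with a logged count.

## Scores

**MethScore (ScoreC2).** `score = clamp(1 − c_site/μ, 0, 1)` with `μ` the
mean of the two bonds on each side of the site bond, averaged between
sides. The score is undefined (NaN with reason code) when the ±2 window
leaves the reference or `μ = 0`. A distance-weighted neighbor mean
(1.0, 0.9 moving outward) is available behind the `weighted` flag; on
smooth profiles it differs negligibly from the plain mean.

**NormUcount / PsiScore.** For uridine `p`, `NormUcount(p)` divides the
5'-end count at `p` (plus offset) by the mean count over the non-U
positions in the 10-nt window centred on `p`; windows with fewer than
3 non-U positions expand symmetrically up to twice the nominal width,
beyond which the value is NaN. The PsiScore baseline is a skew-corrected
median of NormUcount over all uridines: `median × exp(s²/2)` with
`s = (ln Q75 − ln median)/0.6745`. The plain median is robust to the
(≤20%) modified uridines that contaminate the lower tail, but it is only
median-consistent: under multiplicative per-position cleavage bias the
NormUcount of an unmodified uridine is right-skewed, and a mean-consistent
baseline is required for the score ratio to estimate the modified
fraction without bias (MethScore's neighbour-mean μ is mean-consistent by
construction). The upper-quartile spread estimate is untouched by the
modified sites; on noise-free data the correction factor is ~1. The plain
median is available via `psi_score(..., skew_correction=False)`. The
baseline requires ≥10 uridines with defined NormUcount, and the modified
fraction of uridines must stay below 20% for the baseline to represent
the unmodified level — the simulator enforces the same limit.

**Replicates and comparisons.** Replicate scores are averaged per site
and condition; NaN replicates are dropped with a flag. Between-condition
tests use the unpaired two-sample Wilcoxon (Mann–Whitney) test: exact
null enumeration when both groups have ≤8 observations without ties,
otherwise the mid-rank normal approximation without continuity
correction (platform-reproducible). Box summaries report median,
quartiles and 1.5·IQR whiskers; stars follow * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001. "Highly modified" means score strictly
greater than 0.8.

## Synthetic read model

Every generator is a pure function of (inputs, seed); each stage derives
an independent stream from `(seed, salt)`, so outputs do not depend on
call order.

*RMS.* Bond `i` carries cleavage propensity `w_i = exp(N(0, σ))` with
σ = `propensity_sd` (default 0.5) — a multiplicative per-position bias,
the dominant artefact of real cleavage data — attenuated by `(1 − f)` at
a methylated site with fraction `f`. Fragments are bond pairs `(a, b)`
with uniform length in 20–39 nt, sampled with probability ∝ `w_a·w_b` by
vectorized rejection; the read count is Poisson with expectation
`depth·(L−1)/2`, so the expected combined end count per bond is `depth`.
The simulator emits its own end tallies, which the counting stage must
recover exactly. Note the per-replicate noise is drawn independently: the
model treats the cleavage bias as a property of the library preparation,
not of the sequence alone. Fully sequence-determined bias would not
average out across replicates and would put a σ-dependent floor under any
estimator; replicate averaging is effective exactly insofar as biases
vary between experiments.

*HPS.* Base `p` cleaves with propensity `u_rate·(1 − f_p)` at uridines
(`u_rate` default 10) and `bg_rate` (default 1) elsewhere, times the same
lognormal bias; cleavage positions are multinomial with Poisson total
`depth·L`. Only 5'-ends carry signal.

*Sites.* 55 Nm + 47 Ψ sites (the yeast rRNA tallies) are planted with
pairwise spacing ≥5 nt — no ±2 scoring window straddles two sites — and a
12-nt margin from the ends; true fractions are uniform on
`fraction_range` (default 0.5–1.0, the upper half of the scale where
annotated rRNA sites live). Ψ sites fall only on uridines.

*Proteome and fixtures.* Forty background proteins with yeast-like
residue frequencies; five carry a planted N- or C-terminal KKE/D-like
segment (a lysine-enriched lead-in free of KK doublets, then a block of
KK doublets spaced by 1–2 residues from {E, D, H, S} with E/D
dominating). The lead-in ends in a non-spacer pair so the planted doublet
count and coordinates round-trip exactly through the detector. qPCR
fixtures invert the ratio formula to plant known IP/Input ratios before
adding triplicate Ct noise (sd 0.12 cycles); iBAQ tables plant per-category
log2 enrichments with 20% missing control values; ROI tables plant a
focal maximum in half the cells.

What the generators do **not** emulate: sequence-dependent (replicate-
correlated) cleavage bias, ligation/adapter end biases, alignment errors
and multimapping, partial fragmentation near molecule termini, rRNA
secondary structure, and correlated modification of neighbouring sites.
Recovery results on synthetic data therefore demonstrate estimator
correctness under the stated noise model, not real-data accuracy.

## Charge patterning

Charges: K, R = +1; D, E = −1; H = 0 by default (configurable; H is
treated as a polar spacer, not a charged residue); X tolerated as neutral
with a warning. FCR = f⁺ + f⁻, NCPR = f⁺ − f⁻, NCPD = round(NCPR·L)
(= the exact integer net charge at unit charges).

**kappa.** For blob sizes g ∈ {5, 6}, the blob charge asymmetry is
σ = (f⁺ − f⁻)²/(f⁺ + f⁻) (0 for a chargeless blob), δ_g the mean squared
deviation of σ over all overlapping blobs from the whole-sequence σ, and
κ = mean_g(δ_g/δ_max,g) clamped to [0, 1]. δ_max,g is the largest δ over
the canonical maximally segregated rearrangements of the composition: the
positive and negative residues each contiguous, with the neutral residues
either split around the two adjacent charge blocks (every prefix/suffix
split, both block orders) or as a single block between them. This
construction is the field's standard normalizer, and the fully segregated
sequence attains κ = 1 by construction; it is not a proven maximum over
all permutations — for short compositions, non-blocky permutations can
exceed it (e.g. 4+/4−, blob 6: `++----++` beats `++++----`), which is why
the ratio is clamped. κ is undefined (NaN with reason) for sequences
shorter than 6 residues, without charges, or with a single charge sign;
blob sizes whose δ_max is 0 (no rearrangement changes anything, e.g.
blob = sequence length) are skipped.

**Diagram of states.** weak (FCR < 0.25), boundary (0.25 ≤ FCR ≤ 0.35),
strong polyampholyte (FCR > 0.35, |NCPR| ≤ 0.3), positive/negative strong
polyelectrolyte (FCR > 0.35, |NCPR| > 0.3). The polyelectrolyte boundary
0.3 matches the threshold used alongside the FCR rule in the snoRNP IDR
literature; the canonical 0.35 is available via `ncpr_boundary`.

**KKE/D repeats.** KK doublets are found greedily left to right without
overlap (KKK holds one doublet); consecutive doublets chain when
separated by 1–3 residues all from {E, D, H, S}; adjacent doublets (zero
spacer) are a lysine run, not a repeat, and do not chain; chains of ≥3
doublets are reported with their spacer composition. IDR extraction keeps
disorder segments strictly longer than 30 residues ("longer than 30"
read literally).

Because the native Cbf5 C-terminal IDR sequence is not bundled, examples
and tests that need a domain of that class use a hand-constructed
synthetic stand-in (`synthetic_sequences.SYNTHETIC_CBF5_LIKE_IDR`,
labelled as such) reproducing the described architecture: uncharged
linker, lysine-enriched region with alternating charge blocks, then a
KK-doublet block; its κ ≈ 0.28 sits in the 0.1–0.4 band reported for
KKE/D-class IDRs.

## Enrichment statistics

**qPCR.** Ct medians are taken per triplicate first, then
ΔCt = medCt_IP − (medCt_input − log2(1/dilution)) and
ratio = 2^−ΔCt. With the default 1-in-500 input dilution (10% chromatin
fraction, diluted 1:50), equal IP and input Cts give ratio = 1/500 — the
IP then holds exactly as much material as the diluted input. The
dilution-correction sign follows this physical identity; the formula as
sometimes printed (log2 of the fraction itself) would invert it.

**TurboID/iBAQ.** Each purification is divided by the median of its
nonzero values (zeros mean "not observed" and are preserved); missing
control values are imputed from a normal in log2 space down-shifted 1.8
SD with width 0.3 SD of the observed distribution (the Perseus
convention; parameters exposed), deterministically under a seed;
enrichment = log2(bait) − log2(control), NaN when the bait value is
absent. Category comparisons use Welch's unequal-variance t test with the
star convention above; categories are treated as non-overlapping labels.

**ROI.** Per-region max, log10(max), max/mean (1 for a flat region), and
the mean-intensity ratio between two regions when both are given.
Zero-mean denominators and empty regions are errors, not NaNs.

## Problem sizes and statistical design of the checks

Score recovery is checked at 55 Nm + 47 Ψ sites, depth 1000, three
replicates averaged per condition (the study's replicate structure):
mean |score − truth| ≤ 0.05 without propensity noise and ≤ 0.10 at
σ = 0.5. The differential check simulates 50 Nm sites (reference 800 nt,
depth 150, σ = 0.5) with a global 0.4 reduction and requires the Wilcoxon
test to reject at α = 0.05 in ≥90 of 100 seeded runs; the matched null —
same sites, independent noise — must reject in ≤10. The null is in fact
conservative (observed ~0/100): both conditions share the same planted
site fractions, so the two score samples are more similar than two
independent draws from the pooled distribution, exactly as in a real
design where the same annotated sites are scored in every strain.

## Known limitations

- δ_max is a canonical construction (see above); κ values are comparable
  within this package and with CIDER-style tools, but are not normalized
  by the true permutation maximum.
- The HPS offset convention (cleaved base → counted 5'-end) is a free
  parameter; scores are only meaningful when library preparation and
  scoring use the same value.
- MethScore windows never straddle two sites on synthetic data (spacing
  ≥5 enforced); on real annotations with closer sites, neighbour means
  would be biased by the adjacent site's protection.
- The Wilcoxon normal approximation is used above n = 8 even with few
  ties; exact enumeration is restricted to small tie-free samples.
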