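# Methods

`halopha` re-implements, as a tested library, the computational workflow
used to study polyhydroxyalkanoate (PHA) synthase paralogs in haloarchaea:
a proteome-wide paralog survey with identity-based classification and
phaE–phaC colocalization, efficiency-corrected RT-qPCR quantification, and
polymer-composition arithmetic from ¹H-NMR integrals. Because the original
measurements (proteome databases, qPCR plates, NMR spectra) are external,
every analysis is paired with a synthetic-data generator that plants known
parameters, so the whole chain can be validated by parameter recovery.

## Paralog survey

**Alignment.** Homology is assessed by Smith–Waterman local alignment with
affine gaps: BLOSUM62, gap open 11, gap extend 1 (a gap of length *k*
costs 11 + *k*), the standard protein–protein search defaults. The
dynamic program is executed by biotite's optimised engine; the test suite
checks it against an independent plain-Python Gotoh implementation on
hundreds of random pairs. Percent identity is computed over all alignment
columns including gaps (identical columns / alignment length × 100),
matching the BLAST tabular `pident`. Bit scores use the gapped
Karlin–Altschul constants for BLOSUM62/11/1 (λ = 0.267, K = 0.041);
E-values are parameterised by the total residue count of the searched
collection. E-values are reported for completeness only — classification
uses percent identity, so the database-size choice cannot change any call.

**Classification.** For each reference class (PhaC_Hme, PhaC1, PhaC2,
PhaC3, plus the PhaE subunit) the top 4 hits per species are retained
(`max_targets`, the `-max_target_seqs 4` convention), duplicate rows are
collapsed on a 7-field alignment-statistics key (sacc, pident, length,
mismatch, gapopen, evalue, bitscore), and one best unique hit per organism
and class is kept. The organism's best class is the one with the highest
percent identity; a call is *weak* when that identity is strictly below
65 % (exactly 65.0 is strong). Weak calls stay in the calls table but are
excluded from paralog tallies. Tie-breaks are not dictated by the
underlying workflow and are fixed here for determinism: within a class,
bitscore → pident → ascending subject accession; across classes at equal
identity, higher bitscore → the fixed order PhaC_Hme, PhaC1, PhaC2, PhaC3.

**Query coverage.** Alignment length as a percentage of the full reference
length (capped at 100). Coverage well below 100 flags terminally
truncated homologs, the signature of the PhaC2 class (which covers ~62 %
of the main-enzyme sequence).

**Colocalization.** Each phaE gene is paired with the phaC gene in the
same genome assembly minimising |start(phaC) − end(phaE)|, deliberately
without strand correction; a strand-aware variant exists behind a flag but
is off by default. Because no numeric definition of "vicinity" is
standard, a pair is called colocalized at distance ≤ 1000 bp on the same
replicon by default, and the raw distance is always reported so users can
re-threshold. `genome_id` uses an `assembly/replicon` convention: the
assembly groups candidates, the full id decides `same_replicon` (the
paralogs of interest genuinely sit on different replicons — chromosome and
megaplasmids — of one assembly).

## RT-qPCR quantification

**Standard curves.** Ct is regressed (OLS) on log10 relative template
quantity over a 10-fold dilution series (≥ 3 distinct points); the
amplification efficiency is E = 10^(−1/slope), ideal E = 2. QC warnings
(never hard failures) are raised when E leaves (1.8, 2.1) or r² < 0.98.

**Pfaffl ratio.** After averaging technical replicates (with a warning
when they diverge by > 0.5 cycles), the relative expression of a target
between a sample and a control condition is

    R = E_t^(ΔCt_t) / NF,   ΔCt = mean Ct(control) − mean Ct(sample),

where NF is the geometric mean over reference genes of E_r^(ΔCt_r)
(geNorm-style; a single reference is used as-is). The defaults use the
*tbp* and *ffs* housekeeping genes. Per-replicate spread (`ratio_sd`)
pairs each sample biological replicate against the control-condition mean;
an all-pairs alternative is available (`pairing="all_pairs"`). Group
p-values come from a two-sided, equal-variance unpaired t-test on
reference-normalised Ct values (Ct_target − mean Ct_references), the
variance-stabilised scale on which qPCR groups are conventionally
compared; Welch's variant is available behind a flag. A Shapiro–Wilk
check per group (n ≥ 3) flags non-normality and warns but never blocks
the test; groups of size 2 get a `None` flag.

A useful identity: when every efficiency is exactly 2, R reduces to
2^(ΔΔCt), and a uniform Ct shift applied to one condition (a plate
offset) cancels exactly. With unequal target/reference efficiencies the
cancellation is only approximate — this is inherent to
efficiency-corrected ratios, since the shift enters the numerator and
normalisation factor with different bases.

**Absolute proxies.** Q = 10^((Ct − intercept)/slope) converts a Ct to a
relative template quantity on its gene's standard-curve scale, enabling
cross-gene comparisons of transcript levels (each gene against its own
curve).

## Polymer composition

Each PHBV monomer contributes exactly one backbone methine (CH) proton, so
the 3-hydroxyvalerate mole percent is %3HV = 100 · I_V / (I_B + I_V) from
the 3HB and 3HV methine peak areas; %3HB + %3HV = 100 by construction.
Default assignment windows are 5.20–5.30 ppm (3HB) and 5.10–5.20 ppm
(3HV), half-open, following standard PHBV assignments in CDCl₃; they are
configurable and are only a labelling convenience — input is an already
integrated peak list, not a spectrum. PHA content is extracted polymer
mass over lyophilised cell dry weight, in percent.

**Medium C/N/P.** Elemental millimoles per litre are summed over nutrient
components (carbon sources, NH₄Cl, phosphates, trace vitamins; the Tris
buffer is flagged `counted: false`), then normalised to P = 1.0 on a molar
or mass basis. The shipped recipe fixtures (Hv-min, glycerol medium,
Hv-min + valeric acid) carry two atomic-mass sets: the IUPAC standard
masses and a "nominal" convention with a phosphorus reference mass of
32 g/mol. A brute-force scan over plausible phosphorus masses (kept as a
test) shows the recipes' nominal ratios (62.8 : 2.3 : 1.0,
83.6 : 2.3 : 1.0, 71.9 : 2.3 : 1.0) are mass ratios under the P = 32
convention — standard masses give ≈ 64.8 : 2.4 : 1.0 for Hv-min — so the
fixtures default to the nominal set and users can switch.

## Synthetic-data generators

All generators are driven by one integer seed through
`numpy.random.default_rng`; identical spec + seed produces byte-identical
files.

**Proteomes.** Homologs are planted by substituting residues of a
reference at randomly ordered positions with conservatively scoring
partners (BLOSUM62 score ≥ 0, weighted by exp(score)); the substitution
count starts at L·(1 − target/100) and is adjusted until the identity
*measured by the survey aligner itself* lands within ±3 points of the
planted target. Targets below 25 % are refused. Truncations remove
residues from both termini proportionally, emulating terminally clipped
paralogs. Decoys are background-frequency random sequences (150–450 aa),
rejected and redrawn until no reference aligns at ≥ 40 % identity. The
loci table places the phaE gene and its intended partner at the planted
signed distance. What this does *not* emulate: indels, domain shuffling,
compositional bias of real halophilic proteomes (which are strongly
acidic), or phylogenetic correlation between species — so recovery tests
demonstrate the pipeline's arithmetic and thresholds, not its behaviour on
borderline real homologs.

**qPCR.** Ct = baseline − log_E(template) + N(0, sd) per observation,
with per-gene efficiencies, planted fold changes between conditions
(reference genes stay flat), and dilution series generated from the same
efficiency. Noise is Gaussian on the cycle scale, the conventional qPCR
error model; there is no separate biological-replicate variance component,
so planted noise translates directly into measurement noise.

**NMR.** Two methine peaks with integrals proportional to the planted
mole fractions, multiplicative Gaussian integral noise, optional spurious
peaks. Baseline/phasing artefacts of real spectra are out of scope.

## Problem sizes and numerical choices

Recovery experiments use 4-species proteome sets with ~480-residue
references and 20 decoys per species, qPCR designs with 3 biological × 2
technical replicates and 5-point dilution series, and 200-seed noise
sweeps for the noisy-recovery property (median relative ratio error < 10 %
at ct noise sd 0.1) — sizes at which every planted effect is identifiable
and the full suite runs in well under a minute of alignment time.
Floating-point policy: `pident` is serialized to 3 decimals, bitscores to
1 decimal, E-values to 3-digit scientific notation, and hits are
canonicalised to that precision at construction so hit tables round-trip
bit-exactly. Degenerate inputs (empty FASTA, zero methine signal,
non-negative curve slopes, groups of fewer than 2 replicates) raise
located errors rather than returning partial results.

## Known limitations

* The survey classifies by percent identity only, faithfully mirroring the
  underlying workflow; it will misclassify chimeric or multi-domain
  proteins whose best-identity class differs from their best-scoring one.
* The colocalization cutoff (1000 bp) is a documented default, not a
  biological constant; operon membership is not modelled.
* The Pfaffl per-replicate spread depends on the chosen pairing
  convention; both conventions are provided but they are not equivalent.
* Real accession-based reference sets require network retrieval, which the
  package intentionally does not perform; the synthetic reference set is
  clearly labelled as such.
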