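# Methods

## Scope and model of the data

The pipeline treats every external resource as a file: a GWAS-style
association TSV, an LD proxy table, per-database target-site TSVs, 3'UTR
and miRNA FASTA, a VCF-like variant table, and eQTL/conservation tables.
All internal coordinates are 0-based half-open; file I/O uses each
format's native convention (VCF-like positions are 1-based). Minus-strand
genes are handled by mapping genomic positions through each site's
genomic↔UTR affine map and complementing alleles before substitution
into the sense-strand context.

## Thermodynamic model

Secondary-structure energies follow a loop-decomposition nearest-neighbor
model: Turner-style Watson–Crick stacking constants; class-averaged
values for wobble-containing stacks (one GU −1.3, two GU −0.5 kcal/mol);
tabulated hairpin/bulge/internal-loop initiation penalties with
Jacobson–Stockmayer logarithmic extrapolation; linear multibranch-loop
cost a + b·branches + c·unpaired (3.4, 0.4, 0.0 kcal/mol); kT = 0.6156
kcal/mol (37 °C); minimum hairpin loop 3 nt; interior/bulge loops capped
at 30 nt total (structures exceeding the cap are excluded from the
ensemble). Single-nucleotide-bulge stacking, terminal-AU penalties,
coaxial stacking, dangles and pseudoknots are deliberately omitted. The
constants are approximate by design: agreement with any particular
third-party folding tool is not promised; instead, both the partition
function and the duplex program are validated against exhaustive
Boltzmann enumeration of all structures (sequences ≤ 16 nt, including
multibranch cases) under the *same* energy function, to 1e-9.

A `unit` mode (constant energy per pair, no loop terms) exists solely to
make hand enumeration trivial in oracle tests.

### Partition function

Standard McCaskill inside recursions (qb/qm1/qm/q) give the partition
function in O(n³); pair probabilities come from an outside pass that
processes pairs in decreasing right-end order and uses two column
accumulators for the multibranch terms, keeping the whole computation
O(n³). Kernels are numba-compiled; a ~100-nt window folds in ~5 ms.
Partition-function values are used unscaled (double precision is ample
for the ≤ ~500-nt windows used here; very long windows would need
rescaling, a known limitation).

### Structure distance (d_max, empirical p)

d(I) over intervals I containing the SNP is monotone under interval
inclusion, so d_max is attained on the whole scanned window (100 nt
centred on the SNP by default, `window_len`); the reported interval is
the smallest one reaching (1 − 1e-6)·d_max, ties broken leftmost, with a
10-nt minimum. Significance comes from a seeded empirical null — the
original tool interpolates precomputed background tables by length and
GC, which are not reproducible offline — built from dinucleotide-
preserving shuffles (Altschul–Erickson random Eulerian walks) of the
wild-type window, each given one random substitution at a random
position and scored identically. p = (1 + #{null ≥ d_max}) / (1 + n_null)
(add-one rule, so p ∈ (0, 1] and identical alleles give p = 1); p < 0.2
is flagged significant, following the RNAsnp convention. Default
n_null = 500; the p-resolution is 1/(n_null+1), ample for a 0.2 cut.
Calibration: when the observed variant is itself drawn from the null
generator, p-values are uniform (KS-tested in the acceptance suite).

### Accessibility (Pu, ΔPu%)

Pu is the probability that *every* site position is simultaneously
unpaired: Z_constrained/Z with the site forced single-stranded, computed
on a single local fold of the context (site ± 50 nt, `acc_flank`) — no
multi-window averaging. ΔPu% = 100·(Pu_alt − Pu_wt), so negative values
mean the variant closes the site. Whole-site opening probabilities are
necessarily small for 15-nt sites; the metric is used for its sign and
relative magnitude, which is what the rank-based prioritization
consumes.

### Duplex stability (ΔG_hybrid, ΔΔG_hybrid)

Intermolecular-only duplex DP over antiparallel pairs: consecutive pairs
stack or are separated by bulge/internal loops capped at 15 nt per side;
a duplex-initiation term of +4.09 kcal/mol is included. No intramolecular
structure on either strand. If no pair is legal, or the optimum is
positive, the sentinel ΔG = 0 with a `no_hybrid` flag is reported.
ΔΔG = ΔG(ALT) − ΔG(WT) is exactly antisymmetric under allele swap and
zero for identical alleles. The pipeline hybridizes each miRNA against
the site ± 25-nt flank region of the context.

## Pipeline conventions

* Significance threshold p ≤ 1e-6 and LD threshold r² ≥ 0.6 are both
  inclusive. Blocks are one hop from the lead (no transitive chasing)
  and population-specific; a variant observed in several populations is
  one unique variant but several evidence rows.
* Triples are unique per (miRNA, gene, SNP); if a variant hits both a
  site and a flank of records sharing that key, the site-class hit wins.
  Only biallelic SNVs are scored; indels/multiallelics are logged and
  skipped. A disagreement between the UTR sequence and a variant's
  reference allele raises a `RefMismatchError` naming the rsid.
* Structure metrics depend only on (variant, site), so they are computed
  once per such group (seeded per group from the run seed via CRC32) and
  reused across that site's miRNAs; the duplex term is per-triple.
* Prioritization: candidates are site-located records with d_max
  p < 0.2. The source criteria name the evidence but no formula, so the
  composite is defined explicitly: the mean of the rank-normalized
  (ties averaged, rescaled to [0,1]) values of (1 − p), |ΔPu%| and
  |ΔΔG|, plus 0.5 if the SNP is an eQTL; ties broken by smaller p,
  larger |ΔΔG|, then rsid/miRNA lexically. eQTL status is a bonus, not a
  filter (prioritized sets in this literature contain non-eQTLs);
  conservation flags are pass-through annotations. The formula and all
  thresholds are recorded in the run manifest.
* Tallies report increased/decreased/**unchanged** explicitly so the
  three classes always sum to the total.

## Synthetic study design

The generator writes every pipeline input with known ground truth. Its
defaults are the package's study conditions: 18 transcripts × 2 sites
(15 nt) on both strands of two chromosomes; AU-rich background (35% GC)
as in real 3'UTRs; 2 miRNAs per site (the cognate reverse complement of
the site plus a seed-only matcher, mirroring multi-miRNA rows in target
databases); 7 trait categories × 2 significant leads plus 2
non-significant decoy leads; proxies at r² ~ U[0.6, 1], decoy proxies
below 0.6, and a geometric tail of extra neutral proxies per lead.

Planted variant classes (counts: 10/160/8/12):

* **disruptive_site** — the scientific signal. Twelve of the 36 sites
  are *conformational switches*: the GC-rich (75%) 3' arm of the site
  pairs its perfect reverse complement P1 just downstream (wild type,
  site occluded); a decoy partner P2 — a near-copy of the arm plus the
  reverse complement of the hairpin loop, weakened by one designed
  mismatch — waits further downstream. The planted substitution breaks
  the central arm:P1 pair and P1 deserts the arm for the now-stronger
  P1:P2 duplex: ~20 base pairs rearrange (large d_max) and the site
  opens (ΔPu > 0). The same substitution turns a Watson–Crick pair of
  the seed duplex into a mismatch (ΔΔG > 0). Arm candidates are screened
  against self-complementarity and any 5-mer complementarity with the
  surrounding sequence, and accepted only after folding confirms the
  wild-type register (≥ 0.88 occupancy), the variant switch (≥ 0.70),
  arm release (≤ 0.15 residual pairing) and site opening (Pu ≥ 0.02) —
  the in-silico analogue of sequence design in NUPACK-style tools. If no
  arm passes, the surrounding context (also synthetic) is redrawn.
  Planted disruptive variants are marked as eQTLs, consistent with the
  predominance of eQTLs among prioritized target-site SNPs.
* **benign_site** — background substitutions in the 24 plain
  (undesigned) sites; their windows are plain random sequence, so their
  empirical p-values are honestly ~uniform.
* **hairpin_flank** — substitutions in the P1 arm (within the 25-nt
  flank): structurally disruptive but outside the site, exercising the
  zone distinction.
* **neutral** — > 25 nt from any site; must produce no interactions.
* plus lead-in-site variants, r² < 0.6 decoy proxies (some deliberately
  inside sites) and proxies of non-significant leads, all of which must
  be filtered out upstream.

`expected_counts` re-derives, by a pure O(n·m) containment scan over the
emitted files, the exact triple/site/flank tallies the pipeline must
report. The candidate-*set* size itself depends on the stochastic
empirical p-values and is therefore bounded (site-zone triples), not
predicted exactly.

What the generator does **not** emulate: realistic LD (no coalescent),
overlapping genes, alternative UTR isoforms, non-SNV variants, miRNA
expression context, or the GC/length heterogeneity of real UTRs. Passing
the end-to-end tests therefore demonstrates correct mechanics and
faithful metric semantics under controlled thermodynamic ground truth —
not predictive accuracy on real transcriptomes.

## Problem sizes

Defaults were chosen for single-CPU desk-scale runs: fold windows
100 nt (distance) and site ± 50 nt (accessibility); n_null = 500 in the
library default and 200 in the acceptance script; the test suite uses
n_null = 100–200 and 40–60-nt windows for oracle and calibration work.
A full synthetic study (≈ 250 planted and control variants, ≈ 360
interactions) simulates in ~25 s (most of it fold-validating the
designed switches) and scores in a few minutes.

## Known limitations

Approximate energy constants (notably wobble stacks and loop tables);
no dangles/coaxial terms; whole-site Pu is conservative for long sites;
the empirical null assumes dinucleotide composition is the right
invariance class; duplex scoring ignores target intramolecular
structure (as RNAhybrid does) so ΔG values are optimistic for occluded
sites — the accessibility metric carries that information instead.
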