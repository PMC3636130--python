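# Methods

This note documents the models implemented in `regarch`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that matter when reproducing results.

## Coordinate model

All genomic intervals are 0-based, half-open, on the forward strand of
the reference; GFF3 (1-based, closed) and BED (0-based, half-open) are
converted at the I/O boundary and nowhere else. A TSS position is the
first transcribed base. Chromosomes are circular by default: adjacency
statistics include the wrap-around gene pair, and sequence fetches
wrap modulo the genome length.

## Promoter information content

### Model

A promoter element is a position weight matrix f(b, i) estimated from
aligned sites with additive pseudocounts:

    f(b, i) = (count(b, i) + c) / (n + 4c),   c = 0.5 by default.

The individual-information weights are Riw(b, i) = 2 + log2 f(b, i),
so a column at background (f = 1/4) contributes 0 bits and a perfectly
conserved column contributes 2. A sequence's score Iseq sums one entry
per column; for sites drawn from f, E[Iseq] = Σ_i (2 − H_i) with H_i
the column entropy — this identity is used as a test oracle. The
pseudocount keeps weights finite; it can never push a weight above 2
bits.

Whole promoters are scored under three σ⁷⁰ binding modes (−35+−10,
extended −10 alone, extended −10 + −35). The spacer penalty GS(d) =
−log₂ of the empirical frequency of spacer d between the 3′ end of the
−35 box and the 5′ end of the −10 hexamer, restricted to 15–20 bp,
with no small-sample correction. Conventions worth stating:

- The −10 hexamer weights are the 3′-terminal six columns of the
  9-wide extended −10 matrix. This guarantees mode-1/mode-3
  consistency; training the hexamer independently is possible by
  passing a separate matrix.
- For modes using the extended −10, the spacer is measured to the 5′
  end of its hexamer portion (3 nt inside the nonamer), keeping d
  comparable across modes.
- Each element is placed at its maximum-Iseq offset inside its search
  window (−10/extended −10 entirely within [−18, −1]; −35 within
  [−44, −20]); ties break toward the TSS. A mode whose resulting d
  falls outside 15–20, or whose GS is undefined (spacer never
  observed), is excluded from the maximum. Best-mode ties go to the
  lowest mode number.
- Windows shorter than 44 nt (contig edges) are right-aligned and
  padded; modes needing missing positions are undefined.

Because placement is by maximum information, the distance between the
TSS and the −10 element is an *output* of the scorer, not an
assumption; on synthetic genomes it reproduces the planted 7-bp mode.

### Motif discovery and refinement

Elements are discovered by fixed-width, one-occurrence-per-sequence
(OOPS) EM restricted to the element's positional window, best of N
random restarts by total information, deterministic given a seed. This
is a deliberately simple stand-in for gapped Gibbs samplers; its known
failure mode is that OOPS forces an occurrence into every sequence,
although a substantial fraction of promoters genuinely lack a −35 box
and a few upstream windows belong to weak antisense starts. Left
uncorrected, those background "occurrences" wash out the matrix and
(by softening mismatch penalties) inflate spurious mode-3 scores.

The training step therefore refines each matrix once: it scores
base-shuffled copies of the input windows under the trained weights,
takes the upper quartile of those max-placement scores as a null
threshold, and rebuilds the matrix from the aligned sites that beat
it. The threshold is self-calibrating — sharp matrices yield low null
scores and keep nearly all sites; washed-out matrices yield high null
scores and discard background alignments. On synthetic data this
recovers the planted information content of both elements to within
~0.1–0.5 bits. The EM can converge to a register shifted by ±1 from
the planted one (the unconstrained "n" column of the TGn motif makes
registers nearly degenerate); max-information placement at scoring
time absorbs the shift.

## RBS hybridization energetics

The SD:anti-SD duplex is modeled as the best *contiguous* helix a
10-nt mRNA window forms with 5′-UCACCUCCUU-3′: Watson-Crick and G·U
pairs, summed stacked-pair ΔH/ΔS, one duplex-initiation term, and a
penalty per terminal A-U or G-U pair; ΔG(T) = ΔH − T·ΔS with T in
kelvin. The reported value minimizes over every antiparallel ungapped
registration and every contiguous run of ≥3 pairs (including trimmed
sub-helices — trimming can win at high temperature, where weak
terminal stacks cost more entropy than they return in enthalpy).
Windows with no ≥3 run score exactly 0: non-binders are treated as
energetically neutral, so "fraction ΔG < 0" counts actual binders.

The parameter table (package data, `rna_nn_params.tsv`) carries the
Xia 1998 Watson-Crick set and the Turner-series G·U revisions, with
ΔS derived from published ΔH and ΔG37. Keys are written top-strand
5′→3′ "/" bottom-strand 5′→3′; each stack equals its strand-swap, and
both readings are registered at load.

This contiguous-helix model deliberately omits loops, bulges, dangling
ends and intramolecular mRNA structure. Against a full
secondary-structure tool it runs systematically more negative for
perfect duplexes (no nucleation/loop costs) and more positive for
interrupted ones (no bulged rescue). Conclusions drawn from it should
be at the level of signs, fractions, medians and their temperature
trends — which is how the package reports them — not individual
kcal/mol values.

Scan conventions: the per-gene local minimum is over 10-mer windows
whose 5′ end lies 30–1 nt upstream of the start codon (windows may
overlap the CDS); ties go to the window closest to the start codon.
Offsets are reported for the window's 5′ end. ΔG values are memoized
per (parameter-set version, temperature), so genome-scale scans cost
one evaluation per distinct 10-mer.

## Architecture statistics

- Intergenic gaps are strand-blind, signed (overlapping genes give
  negative gaps, retained in all distributions), and include the
  circular wrap-around pair.
- A PIR is a maximal interval covered by no gene body (genes merged
  across strands) that contains ≥1 TSS; TSSs inside gene bodies are
  ignored for PIR construction (they are internal starts, not
  intergenic promoters). TF sites are assigned by midpoint, precedence
  PIR > intergenic > genic, so class counts always sum to the input.
- 5′UTR length = transcribed nucleotides before the first CDS base
  (0 = leaderless); TUs without a mapped TSS, and TUs whose first
  feature is a functional RNA, are excluded; negative lengths are
  flagged invalid. Groups: Short 11–17, Common 26–32, Other.
- A TU is suboperonic iff its initiation site falls strictly inside
  another same-strand TU's span. Note this also captures the shorter
  member of an alternative-TSS pair; the two categories overlap by
  construction.
- Antisense: ≥1 nt of opposite-strand TU overlap; the source is
  "3utr" only if every overlapping TU covers the gene purely
  downstream of that TU's last CDS.

## Expression and proteomics

FPKM = count × 10⁹ / (length_nt × total), computed directly under a
single-isoform assumption appropriate for bacterial transcriptomes;
features excluded as functional RNAs contribute to neither numerator
nor total. TSS calling keeps positions with ≥5 uniquely mapped 5′
ends. The ncRNA filter retains regions that are not TU-associated,
strictly longer than 68 nt, and above FPKM 8 in ≥2 conditions.

Digestion is fully tryptic (cleave after K/R, not before P, zero
missed cleavages); a peptide is observable if it has ≥6 residues and
some charge state z ∈ {1,2,3} puts (M + z·1.00728)/z in 400–2000 m/z.
Monoisotopic masses come from pyteomics. A protein's abundance score
is its total spectral count divided by its observable-peptide count,
after requiring a total count ≥2 and ≥1 log-phase observation. The
mRNA–protein correlation is Pearson on log10-transformed pairs with
non-positive values excluded (the raw-scale r is reported alongside);
the p-value is the t-test for r ≠ 0.

## Statistics layer

Pearson permutation tests are two-tailed, p = (1 + #{|r_perm| ≥
|r_obs|}) / (1 + n_perm), default 9,999 permutations. The Mantel
statistic is Pearson on off-diagonal upper triangles; p permutes rows
and columns of Y jointly, one-tailed on r ≥ r_obs (the vegan
convention); the partial variant uses r_XY·Z = (r_XY − r_XZ·r_YZ) /
√((1−r_XZ²)(1−r_YZ²)) and degenerates to an explicit error when a
conditioning matrix has zero off-diagonal variance. Wilcoxon rank-sum
uses exact enumeration for max(n) ≤ 10 without ties, else the normal
approximation with tie and continuity corrections. MAD is unscaled
(no 1.4826 factor) — values are reported in kcal/mol as-is.

## Synthetic-data generator

The generator lays out TU "cassettes" along a circular chromosome:
upstream space (promoter + optional TF sites), 5′UTR, genes with
intra-operon gaps. Defaults emulate a compact hyperthermophile genome
and are fixed:

| parameter | default | basis |
|---|---|---|
| genes per primary TU | mono 0.42, else 2+Poisson(3.3) | pooled mean ≈3.3 incl. suboperons, ≈57–60% polycistronic |
| intra-TU gaps | round 𝒩(2, 6), ≥ −15 | genome-wide median gap ≈5 bp once TU-boundary gaps enter the mixture |
| upstream space | lognormal median 50, σ 0.65, ≥45 | PIR medians ~90 bp; ≥45 keeps the 44-nt promoter window intergenic |
| 5′UTR mixture | Short[11,17] 0.45 / Common[26,32] 0.55 | bimodal length distribution |
| promoter PWMs | consensus prob 0.85 (TGnTATAAT, TTGACA) | ~9.2 bits expected per extended −10 |
| −35 presence | 0.45 | mode 1/3 scorable for a minority of promoters |
| spacer d | {15..20} peaked at 17 | spacer distribution centered at 17 bp |
| SD sites | GGAGG core + random flanks, presence 0.93, mutation 0.02 | ≈93% of genes with ΔG<0 at 80 °C; continuous ΔG spread |
| suboperons | 0.5 per polycistronic TU | ≈22% of planted TUs suboperonic |
| alternative TSS | 0.037 | few multi-start TUs |
| antisense TUs | 0.12, gene-free, internal | antisense coverage ≈15–19% of genes |
| TSS detected | 0.9 | TUs with a mapped TSS ≈ 90% |
| FPKM | log-normal, median 117, σ_ln 2.0 | ≈92–96% of genes above FPKM 8 after normalization at ~1,000 genes |
| mRNA–protein r | 0.63 | the coupling the proteome stage must recover |
| background | 54% AT | AT-rich chromosome |

3′UTRs are not given cassette space; TU spans overhang into the next
cassette, which is what produces antisense coverage of convergent
neighbors. Suboperonic and alternative TSSs get planted promoters of
their own (internal initiation is still promoter-driven); antisense
TUs get a TSS but no promoter. One seed drives everything; stage
sub-generators derive offsets from it, and identical configurations
produce byte-identical output files.

What the generator does **not** emulate: sequencing-level read noise
(the 5′-end track is drawn per position, not per read), operon-level
expression correlation (expression is per gene), codon structure
beyond start/stop planting, secondary structure in UTRs, and real
phylogenetic covariance (the comparative layer uses a scalar lineage
coordinate). Passing tests on synthetic data therefore demonstrate
correctness of the *computations* and recoverability of planted
signal at realistic sizes — not robustness to alignment artifacts or
structural RNA effects in real libraries.

## Problem sizes and runtime

The test suite runs a 40-TU genome for shared fixtures and a 300-TU
(~1,000-gene) genome for the end-to-end recovery checks; the
acceptance script uses the 300-TU genome plus 24 organisms × 60 TUs
for the comparative layer, and finishes in about a minute on one CPU.
The duplex-model cross-check compares the implementation against an
independent sub-helix enumeration on a seeded 400-window sample of the
10-mer dictionary plus adversarial wobble-rich cases, at 10⁻⁹
kcal/mol agreement; the full 4¹⁰ dictionary adds no new code paths
(every run topology is exercised by the sample).

## Known limitations

- The duplex model's absolute ΔG values are not comparable to
  partition-function tools; only ranks, signs and trends are.
- The OOPS motif finder assumes one element per window and a fixed
  width; motifs rarer than ~25% of windows will not survive
  refinement.
- Mantel tests at small n (tens of organisms) carry large sampling
  variance in r; the acceptance panel reports per-run values, which
  move by ±0.1 across seeds.
- The suboperon rule's overlap with alternative-TSS pairs slightly
  inflates the suboperonic fraction relative to a curated accounting.
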