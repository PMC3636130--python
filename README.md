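# regarch

Quantitative analysis of bacterial genome organization: how much
sequence information a genome invests in its transcription and
translation initiation signals, and how its transcription-unit
architecture constrains regulation. The package was built around the
biology of compact, hyperthermophilic genomes — organisms that must
keep polymerase and ribosome contacts stable at 80 °C with almost no
intergenic space to spare — but every component takes ordinary FASTA /
GFF3 / TSV inputs and applies to any bacterium with mapped
transcription start sites (TSSs).

It is aimed at microbial genomics researchers who have TSS maps,
transcription-unit (TU) annotations, RNA-seq and shotgun-proteomics
tables, and want the genome-scale statistics those data support:
promoter strength distributions, ribosome-binding-site (RBS)
energetics across temperatures, 5′UTR and intergenic architecture, and
mRNA–protein coupling.

## What it computes

**Promoter information content.** Aligned promoter elements give
per-position base probabilities f(b, i); an individual sequence scores

    Iseq = Σ_i Riw(b_i, i),    Riw(b, i) = 2 + log2 f(b, i)   [bits]

A whole promoter is scored under the three σ⁷⁰ binding modes:

    mode 1 = Iseq(−10) + Iseq(−35) − GS(d)
    mode 2 = Iseq(extended −10)
    mode 3 = Iseq(extended −10) + Iseq(−35) − GS(d)

where GS(d) = −log₂ p(d) is the gap surprisal of the spacer length d
(restricted to 15–20 bp) between the −35 box and the −10 hexamer.
Higher bits ⇒ stronger relative binding free energy. Elements are
discovered de novo by windowed EM in the 44 nt upstream of each TSS
(−10/extended −10 searched in [−18, −1], −35 in [−44, −20]), then each
promoter is scored at its maximum-information placements and assigned
its best mode.

**RBS hybridization energetics.** The Shine-Dalgarno : anti-Shine-
Dalgarno interaction (anti-SD 5′-UCACCUCCUU-3′, the 16S rRNA 3′
terminus) is modeled with RNA nearest-neighbor thermodynamics
(Watson-Crick + G·U stacks, duplex initiation, terminal AU/GU
penalties; ΔG(T) = ΔH − T·ΔS). Each 10-nt mRNA window scores the
minimum ΔG over all ungapped antiparallel registrations and contiguous
helices of ≥3 bp; per gene the scan reports the local-minimum ΔG over
windows starting 30–1 nt upstream of the start codon. Summaries
(median, MAD, fraction ΔG<0) are computed per genome and per
temperature, and a permutation/Mantel statistics layer relates RBS
strength to optimal growth temperature across organisms.

**Architecture.** Intergenic gap distributions (signed; overlaps
retained), promoter-containing intergenic regions (PIRs), 5′UTR
lengths with the Short (11–17 nt) / Common (26–32 nt) grouping,
suboperons and alternative TSSs, antisense coverage with its
3′UTR-overhang vs internal source, and the spatial classification of
transcription-factor binding sites (within PIR / intergenic
non-promoter / genic).

**Expression & proteome.** TSS calling from 5′-end count tracks (≥5
uniquely mapped reads), FPKM with functional-RNA exclusion,
expressed-fraction curves, the putative-ncRNA filter (>68 nt, FPKM>8
in ≥2 conditions, not TU-associated), in-silico tryptic digestion
(fully tryptic, ≥6 residues, 400–2000 m/z at z ≤ 3), spectral-count
normalization by observable peptide count, and the log-log
mRNA–protein Pearson correlation.

**Synthetic data.** `regarch.simulate` generates circular genomes with
planted TUs, promoters sampled from configurable PWMs at
mode-consistent offsets, SD sites, 5′-end read tracks, expression
tables with a controlled mRNA–protein correlation, and spectral counts
— together with a truth record, so every stage of the pipeline has a
download-free, seed-reproducible test surface.

## Worked example

```python
from regarch.simulate import SimulationConfig, simulate_all
from regarch.report import promoter_stage, rbs_stage
from regarch.rbs import duplex_dg

ds = simulate_all(SimulationConfig(seed=42, n_tus=120))
print(f"genome: {ds.genome.length:,} bp, {len(ds.features)} genes, "
      f"{len(ds.tus)} TUs, {len(ds.tss_records)} TSSs")

r = duplex_dg("AAGGAGGTGA", 80.0)   # perfect anti-SD complement
print(f"perfect SD vs anti-SD at 80 C: dG = {r.dG:.2f} kcal/mol")

summary, table = promoter_stage(ds.genome, ds.tss_records, restarts=2, seed=1)
print(f"median promoter information: {summary['median_best_mode_bits']:.1f} bits")
print(f"extended -10 consensus: {summary['consensus_extended_minus10']}")

rbs = rbs_stage(ds.genome, ds.features, temps=(37.0, 80.0), profile_max_genes=0)
print(f"median RBS dG: {rbs['median_rbs_dg_37C']:.2f} (37 C) vs "
      f"{rbs['median_rbs_dg_80C']:.2f} kcal/mol (80 C)")
print(f"MAD: {rbs['mad_rbs_dg_37C']:.2f} -> {rbs['mad_rbs_dg_80C']:.2f} kcal/mol")
```

prints

```
genome: 397,443 bp, 413 genes, 170 TUs, 161 TSSs
perfect SD vs anti-SD at 80 C: dG = -5.38 kcal/mol
median promoter information: 10.5 bits
extended -10 consensus: TGCTATAAT
median RBS dG: -8.61 (37 C) vs -2.24 kcal/mol (80 C)
MAD: 1.60 -> 0.66 kcal/mol
```

Reading the output: the motif finder recovered the planted extended
−10 element (TGn + TATAAT; the third position is unconstrained), the
median promoter carries ~10 bits of σ⁷⁰ binding information, and RBS
duplexes weaken but remain thermodynamically favorable at 80 °C, with
the spread of strengths (MAD) compressing at high temperature —
exactly the qualitative signature a hyperthermophile's initiation
signals must show.

The same stages are available from a shell:

```bash
regarch simulate --seed 42 --n-tus 120 --out-dir sim/
regarch promoters --genome sim/genome.fasta --tss sim/tss.tsv --out scores.tsv
regarch rbs --genome sim/genome.fasta --gff sim/features.gff3 --temps 37,80 --out rbs.tsv
regarch mantel --x R.tsv --y T.tsv --perms 9999 --seed 1
regarch run --config config.yaml --out-dir report/
```

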