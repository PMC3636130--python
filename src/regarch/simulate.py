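"""Synthetic bacterial genomes with planted regulatory architecture.

The generator emulates the statistical structure of a compact,
AT-rich hyperthermophile genome: transcription units with a high mean
gene count and tiny intergenic gaps, a bimodal 5'UTR length mixture
(Short 11-17 nt / Common 26-32 nt), sigma-70 promoters sampled from
consensus-probability PWMs at mode-consistent offsets (the -10
hexamer's 3' end 7 bp upstream of the TSS, spacers 15-20 bp),
Shine-Dalgarno 10-mers planted upstream of start codons, a 5'-end
read-count track, per-condition log-normal expression, and spectral
counts coupled to mRNA with a configurable correlation.

Every planted quantity is recorded in a :class:`SyntheticTruth` so that
pipeline recovery can be scored without rerunning the generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GeneFeature, GenomeSequence, TFSite, TSSRecord,
                 TranscriptionUnit, revcomp, write_bed, write_features,
                 write_genome, write_tss_table, write_tu_table)
from .promoters import PWM, iseq

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_pwms",
    "simulate_genome_architecture",
    "simulate_tss_track",
    "simulate_expression_proteome",
    "simulate_all",
]

BASES = "ACGT"
CONDITIONS = ("log", "late_exp", "heat_shock", "h2_inhibition")

SD_CONSENSUS = "AAGGAGGTGA"  # DNA form of the perfect anti-SD complement
SD_CORE = "GGAGG"  # conserved core; flanks vary per gene


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int
    n_tus: int = 300
    # genes per TU: monocistronic with prob p_mono, else 2 + Poisson(lam)
    # primary TUs draw slightly above the target because suboperons
    # (gene-suffix TUs) enter the pooled genes-per-TU statistic
    p_monocistronic: float = 0.42
    poly_extra_lambda: float = 3.3  # pooled mean genes/TU ~ 3.3
    gene_length_mean: float = 950.0
    gene_length_sd: float = 250.0
    gene_length_min: int = 150
    # intergenic structure
    intra_tu_gap_mean: float = 2.0
    intra_tu_gap_sd: float = 6.0
    intra_tu_gap_min: int = -15
    inter_tu_gap_mean: float = 5.0
    inter_tu_gap_sd: float = 6.0
    upstream_space_log_median: float = 50.0
    upstream_space_log_sigma: float = 0.65
    upstream_space_min: int = 45  # keeps the 44-nt promoter window intergenic
    utr3_mean: float = 40.0
    utr3_sd: float = 20.0
    # 5'UTR mixture: two discrete windows + weights
    utr5_windows: tuple = ((11, 17), (26, 32))
    utr5_weights: tuple = (0.45, 0.55)
    # promoter model
    consensus_prob: float = 0.85
    minus35_presence_prob: float = 0.45  # promoters that carry a real -35 box
    spacer_probs: dict = field(default_factory=lambda: {
        15: 0.03, 16: 0.12, 17: 0.40, 18: 0.25, 19: 0.12, 20: 0.08})
    # SD planting: a conserved core with random flanks (natural SDs vary
    # mostly in how far complementarity extends beyond the core)
    sd_presence_prob: float = 0.93
    sd_mutation_rate: float = 0.02
    sd_offset: int = -14  # 5' end of the 10-mer relative to the start codon
    sd_offset_jitter: int = 1
    # architecture extras
    suboperon_prob: float = 0.5  # per polycistronic TU
    alt_tss_prob: float = 0.037
    antisense_tu_rate: float = 0.12  # gene-free opposite-strand transcripts
    tss_detected_prob: float = 0.9  # TUs whose TSS made it into the track
    # TF sites
    tf_site_width: int = 16
    tf_space_threshold: int = 90
    tf_lambda_scale: float = 150.0
    tf_genic_rate: float = 0.09  # extra sites planted inside gene bodies
    # background composition
    at_fraction: float = 0.54
    genome_length: int | None = None  # fixed length (error if layout exceeds)
    # TSS track
    tss_count_nb_n: float = 5.0
    tss_count_mean: float = 50.0
    tss_noise_rate: float = 5e-5  # noise positions per bp
    # expression / proteome
    fpkm_log_median: float = np.log(117.0)
    fpkm_log_sigma: float = 2.0
    condition_jitter: float = 0.3
    mrna_protein_r: float = 0.63
    abundance_log10_mean: float = 0.5
    abundance_log10_sd: float = 0.8
    spectral_depth: float = 3.0
    total_fragments: float = 2e6


@dataclass
class SyntheticTruth:
    tss_positions: list = field(default_factory=list)  # (pos, strand)
    element_offsets: dict = field(default_factory=dict)
    promoter_iseq: dict = field(default_factory=dict)  # tu_id -> sampled bits
    spacers: dict = field(default_factory=dict)  # tu_id -> planted d
    sd_windows: dict = field(default_factory=dict)  # gene -> (start, end, offset)
    sd_dg80: dict = field(default_factory=dict)
    utr5: dict = field(default_factory=dict)  # tu_id -> length
    utr5_component: dict = field(default_factory=dict)  # tu_id -> 0/1 mixture idx
    tu_members: dict = field(default_factory=dict)
    suboperonic: list = field(default_factory=list)
    alternative_groups: list = field(default_factory=list)
    tf_sites: dict = field(default_factory=dict)
    tf_sites_genic: list = field(default_factory=list)
    detected_tus: list = field(default_factory=list)
    antisense_tus: list = field(default_factory=list)
    expression: dict = field(default_factory=dict)  # gene -> target FPKM (log phase)
    abundance: dict = field(default_factory=dict)  # gene -> target abundance
    expected_promoter_bits: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class SyntheticDataset:
    genome: GenomeSequence
    features: list
    tus: list
    tss_records: list
    tf_sites: list
    truth: SyntheticTruth
    proteins: dict[str, str] = field(default_factory=dict)
    tss_track: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    spectral: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome([self.genome], out / "genome.fasta")
        write_features(self.features, out / "features.gff3", seqid=self.genome.id)
        write_tu_table(self.tus, out / "tus.tsv")
        write_tss_table(self.tss_records, out / "tss.tsv")
        write_bed([(s.start, s.end, s.site_id) for s in self.tf_sites],
                  out / "tf_sites.bed", chrom=self.genome.id)
        if self.tss_track is not None:
            self.tss_track.to_csv(out / "tss_track.tsv", sep="\t", index=False)
        if self.expression is not None:
            self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        if self.spectral is not None:
            self.spectral.to_csv(out / "spectral_counts.tsv", sep="\t", index=False)
        if self.proteins:
            with open(out / "proteins.fasta", "w") as fh:
                for pid, seq in self.proteins.items():
                    fh.write(f">{pid}\n{seq}\n")
        self.truth.to_json(out / "truth.json")


def default_pwms(consensus_prob: float = 0.85) -> dict[str, PWM]:
    """Consensus-probability sigma-70 PWMs.

    extended -10 = TG + n + TATAAT (the 'n' column is uniform); the -10
    hexamer weights are the nonamer's 3'-terminal six columns; -35 is
    TTGACA.
    """

    def column(base: str | None) -> np.ndarray:
        if base is None:
            return np.full(4, 0.25)
        col = np.full(4, (1 - consensus_prob) / 3)
        col[BASES.index(base)] = consensus_prob
        return col

    def matrix(spec: str) -> np.ndarray:
        return np.stack([column(None if b == "n" else b) for b in spec], axis=1)

    ext = PWM(element="extended_minus10", f=matrix("TGnTATAAT"),
              n_sites=0, pseudocount=0.0)
    m10 = PWM(element="minus10", f=ext.f[:, 3:], n_sites=0, pseudocount=0.0)
    m35 = PWM(element="minus35", f=matrix("TTGACA"), n_sites=0, pseudocount=0.0)
    return {"extended_minus10": ext, "minus10": m10, "minus35": m35}


def _rand_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for b in seq:
        if rng.random() < rate:
            out.append(BASES[rng.choice([i for i in range(4)
                                         if BASES[i] != b])])
        else:
            out.append(b)
    return "".join(out)


def _sample_gene_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if rng.random() < cfg.p_monocistronic:
        return 1
    return 2 + int(rng.poisson(cfg.poly_extra_lambda))


def simulate_genome_architecture(config: SimulationConfig) -> SyntheticDataset:
    """Lay out TUs on a circular genome and plant all sequence elements."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pwms = default_pwms(cfg.consensus_prob)
    ext_w = pwms["extended_minus10"].weights()
    spacer_ds = sorted(cfg.spacer_probs)
    spacer_p = np.array([cfg.spacer_probs[d] for d in spacer_ds])
    spacer_p = spacer_p / spacer_p.sum()

    chunks: list[str] = []
    pos = 0
    features: list[GeneFeature] = []
    tus: list[TranscriptionUnit] = []
    tss_records: list[TSSRecord] = []
    tf_sites: list[TFSite] = []
    truth = SyntheticTruth()
    gene_no = 0
    site_no = 0

    for tu_idx in range(cfg.n_tus):
        strand = "+" if rng.random() < 0.5 else "-"
        tu_id = f"TU{tu_idx:04d}"
        n_genes = _sample_gene_count(rng, cfg)

        # --- build the cassette in sense orientation -------------------
        upstream = max(cfg.upstream_space_min, int(round(
            cfg.upstream_space_log_median
            * np.exp(rng.normal(0.0, cfg.upstream_space_log_sigma)))))
        comp = int(rng.random() < cfg.utr5_weights[1])
        lo, hi = cfg.utr5_windows[comp]
        utr5 = int(rng.integers(lo, hi + 1))
        utr3 = max(0, int(round(rng.normal(cfg.utr3_mean, cfg.utr3_sd))))

        gene_lengths = []
        gaps = []
        for j in range(n_genes):
            gl = max(cfg.gene_length_min, int(round(
                rng.normal(cfg.gene_length_mean, cfg.gene_length_sd))))
            gene_lengths.append(gl - gl % 3)
            if j:
                gaps.append(max(cfg.intra_tu_gap_min, int(round(
                    rng.normal(cfg.intra_tu_gap_mean, cfg.intra_tu_gap_sd)))))

        body_len = sum(gene_lengths) + sum(gaps)
        # the 3'UTR is not given cassette space of its own: the TU span
        # overhangs into whatever lies downstream, which is how antisense
        # coverage of convergent neighbors arises
        cas_len = upstream + utr5 + body_len
        cas = list(_rand_seq(rng, cas_len, cfg.at_fraction))

        tss_rel = upstream  # sense-relative index of the first transcribed base

        def plant_promoter(rel: int, owner_id: str) -> int | None:
            """Plant ext -10 (5' end at -16; hexamer 3' end at -8) and,
            with the configured probability, a -35 box at spacer d."""
            ext_site = pwms["extended_minus10"].sample_sites(1, rng)[0]
            cas[rel - 16: rel - 7] = ext_site
            d = int(rng.choice(spacer_ds, p=spacer_p))
            planted_d = None
            if rng.random() < cfg.minus35_presence_prob:
                m35_site = pwms["minus35"].sample_sites(1, rng)[0]
                m35_5p = rel - 13 - d - 6  # hexamer-portion 5' end is -13
                if m35_5p >= 0:
                    cas[m35_5p: m35_5p + 6] = m35_site
                    planted_d = d
                    truth.spacers[owner_id] = d
            truth.promoter_iseq[owner_id] = iseq(ext_site, ext_w)
            return planted_d

        plant_promoter(tss_rel, tu_id)

        # genes + SD sites
        gene_rel = []  # (rel_start, rel_end, gene_id)
        cursor = tss_rel + utr5
        member_ids = []
        for j, gl in enumerate(gene_lengths):
            gid = f"gene{gene_no:04d}"
            gene_no += 1
            gene_rel.append((cursor, cursor + gl, gid))
            member_ids.append(gid)
            cas[cursor: cursor + 3] = "ATG"
            cas[cursor + gl - 3: cursor + gl] = "TAA"
            # SD 10-mer upstream of the start codon
            max_up = utr5 if j == 0 else min(30, cursor - tss_rel)
            off = cfg.sd_offset + int(rng.integers(-cfg.sd_offset_jitter,
                                                   cfg.sd_offset_jitter + 1))
            off = max(-max_up, min(-10, off))
            if rng.random() < cfg.sd_presence_prob and cursor + off >= 0:
                sd = (_rand_seq(rng, 3, cfg.at_fraction) + SD_CORE
                      + _rand_seq(rng, 2, cfg.at_fraction))
                sd = _mutate(rng, sd, cfg.sd_mutation_rate)
                cas[cursor + off: cursor + off + 10] = sd
                truth.sd_windows[gid] = (cursor + off, cursor + off + 10, off)
            cursor += gl
            if j < len(gaps):
                cursor += gaps[j]

        # internal (suboperonic) and alternative initiation is decided
        # before the sequence freezes so their promoters can be planted
        sub_plan = None
        if n_genes >= 2 and rng.random() < cfg.suboperon_prob:
            j = int(rng.integers(1, n_genes))
            sub_comp = int(rng.random() < cfg.utr5_weights[1])
            sub_utr = int(rng.integers(cfg.utr5_windows[sub_comp][0],
                                       cfg.utr5_windows[sub_comp][1] + 1))
            sub_rel_tss = gene_rel[j][0] - sub_utr
            if sub_rel_tss >= 44:
                plant_promoter(sub_rel_tss, f"{tu_id}s")
                sub_plan = (j, sub_comp, sub_utr, sub_rel_tss)
        alt_plan = None
        if rng.random() < cfg.alt_tss_prob and upstream >= 80:
            shift = int(rng.integers(10, 31))
            alt_rel = tss_rel - shift
            if alt_rel >= 44:
                plant_promoter(alt_rel, f"{tu_id}a")
                alt_plan = alt_rel

        # TF sites in the upstream space (more likely when it is long)
        site_rel = []
        free = upstream - 44 - cfg.tf_site_width
        if upstream >= cfg.tf_space_threshold and free > 0:
            k = int(rng.poisson(upstream / cfg.tf_lambda_scale))
            for _ in range(k):
                s = int(rng.integers(0, free))
                site_rel.append((s, s + cfg.tf_site_width))

        # --- place the cassette on the chromosome ---------------------
        c0 = pos
        if strand == "+":
            seq = "".join(cas)
        else:
            seq = revcomp("".join(cas))
        chunks.append(seq)
        pos += cas_len

        def to_genomic(rel_s: int, rel_e: int) -> tuple[int, int]:
            if strand == "+":
                return c0 + rel_s, c0 + rel_e
            return c0 + cas_len - rel_e, c0 + cas_len - rel_s

        g_feats = []
        for rel_s, rel_e, gid in gene_rel:
            gs, ge = to_genomic(rel_s, rel_e)
            g_feats.append(GeneFeature(feature_id=gid, start=gs, end=ge,
                                       strand=strand))
        if strand == "-":
            g_feats = g_feats[::-1]  # keep chromosome order in the list
        features.extend(g_feats)

        tss_pos = (c0 + tss_rel) if strand == "+" else (c0 + cas_len - 1 - tss_rel)
        tu_s, tu_e = to_genomic(tss_rel, cas_len + utr3)  # TSS .. 3'UTR end
        tss = TSSRecord(position=tss_pos, strand=strand)
        detected = rng.random() < cfg.tss_detected_prob
        tus.append(TranscriptionUnit(
            tu_id=tu_id, start=max(0, tu_s), end=tu_e, strand=strand,
            gene_ids=member_ids, tss=tss if detected else None))
        if detected:
            tss_records.append(tss)
            truth.tss_positions.append((tss_pos, strand))
            truth.detected_tus.append(tu_id)
        truth.tu_members[tu_id] = list(member_ids)
        truth.utr5[tu_id] = utr5
        truth.utr5_component[tu_id] = comp
        d_planted = truth.spacers.get(tu_id)
        truth.element_offsets[tu_id] = {
            "extended_minus10": -16, "minus10": -13,
            "minus35": (-19 - d_planted) if d_planted is not None else None}
        for s_rel, e_rel in site_rel:
            gs, ge = to_genomic(s_rel, e_rel)
            sid = f"site{site_no:04d}"
            site_no += 1
            tf_sites.append(TFSite(site_id=sid, regulator=f"TF{site_no % 7}",
                                   start=gs, end=ge))
            truth.tf_sites[sid] = (gs, ge)

        # --- suboperons, alternative TSSs, antisense transcripts ------
        if sub_plan is not None:
            j, sub_comp, sub_utr, sub_rel_tss = sub_plan
            sub_id = f"{tu_id}s"
            sub_pos = (c0 + sub_rel_tss) if strand == "+" \
                else (c0 + cas_len - 1 - sub_rel_tss)
            sub_tss = TSSRecord(position=sub_pos, strand=strand)
            s_s, s_e = to_genomic(sub_rel_tss, cas_len + utr3)
            tus.append(TranscriptionUnit(
                tu_id=sub_id, start=max(0, s_s), end=s_e, strand=strand,
                gene_ids=[g[2] for g in gene_rel[j:]], tss=sub_tss))
            tss_records.append(sub_tss)
            truth.tss_positions.append((sub_pos, strand))
            truth.detected_tus.append(sub_id)
            truth.suboperonic.append(sub_id)
            truth.tu_members[sub_id] = [g[2] for g in gene_rel[j:]]
            truth.utr5[sub_id] = sub_utr
            truth.utr5_component[sub_id] = sub_comp
        if alt_plan is not None:
            alt_rel = alt_plan
            alt_pos = (c0 + alt_rel) if strand == "+" \
                else (c0 + cas_len - 1 - alt_rel)
            alt_id = f"{tu_id}a"
            alt_tss = TSSRecord(position=alt_pos, strand=strand)
            a_s, a_e = to_genomic(alt_rel, cas_len + utr3)
            tus.append(TranscriptionUnit(
                tu_id=alt_id, start=max(0, a_s), end=a_e, strand=strand,
                gene_ids=list(member_ids), tss=alt_tss))
            tss_records.append(alt_tss)
            truth.tss_positions.append((alt_pos, strand))
            truth.detected_tus.append(alt_id)
            truth.alternative_groups.append([tu_id, alt_id])
            truth.tu_members[alt_id] = list(member_ids)
        if rng.random() < cfg.antisense_tu_rate and body_len >= 400:
            alen = int(rng.integers(150, min(600, body_len)))
            s0 = tss_rel + utr5 + int(rng.integers(0, body_len - alen))
            gs, ge = to_genomic(s0, s0 + alen)
            a_strand = "-" if strand == "+" else "+"
            a_pos = gs if a_strand == "+" else ge - 1
            a_tss = TSSRecord(position=a_pos, strand=a_strand)
            a_id = f"{tu_id}x"
            tus.append(TranscriptionUnit(
                tu_id=a_id, start=gs, end=ge, strand=a_strand,
                gene_ids=[], tss=a_tss))
            tss_records.append(a_tss)
            truth.tss_positions.append((a_pos, a_strand))
            truth.detected_tus.append(a_id)
            truth.antisense_tus.append(a_id)

        # inter-cassette gap
        gap = max(0, int(round(rng.normal(cfg.inter_tu_gap_mean,
                                          cfg.inter_tu_gap_sd))))
        if gap:
            chunks.append(_rand_seq(rng, gap, cfg.at_fraction))
            pos += gap

    seq = "".join(chunks)
    if cfg.genome_length is not None:
        if len(seq) > cfg.genome_length:
            raise ValueError(
                f"layout needs {len(seq)} bp > genome_length {cfg.genome_length}")
        seq += _rand_seq(rng, cfg.genome_length - len(seq), cfg.at_fraction)
    genome = GenomeSequence(id="synthetic", sequence=seq, topology="circular")

    # 3'UTR overhangs may run past the assembled sequence ends
    for tu in tus:
        tu.end = min(tu.end, genome.length)

    # a small fraction of TF sites sit inside gene bodies
    n_genic = int(round(cfg.tf_genic_rate * max(1, len(tf_sites))))
    for _ in range(n_genic):
        g = features[int(rng.integers(0, len(features)))]
        if g.length <= cfg.tf_site_width:
            continue
        s = g.start + int(rng.integers(0, g.length - cfg.tf_site_width))
        sid = f"site{site_no:04d}"
        site_no += 1
        tf_sites.append(TFSite(site_id=sid, regulator=f"TF{site_no % 7}",
                               start=s, end=s + cfg.tf_site_width))
        truth.tf_sites[sid] = (s, s + cfg.tf_site_width)
        truth.tf_sites_genic.append(sid)

    # expected per-promoter information for sites drawn from the PWM
    truth.expected_promoter_bits = pwms["extended_minus10"].expected_information()

    ds = SyntheticDataset(genome=genome, features=features, tus=tus,
                          tss_records=tss_records, tf_sites=tf_sites,
                          truth=truth)
    # planted SD dG at the reference temperature (80 C), genomic coords
    from .rbs import duplex_dg
    by_id = {f.feature_id: f for f in features}
    for gid, (_rs, _re, off) in list(truth.sd_windows.items()):
        f = by_id[gid]
        if f.strand == "+":
            win = genome.fetch(f.start + off, f.start + off + 10)
        else:
            win = revcomp(genome.fetch(f.end - off - 10, f.end - off))
        truth.sd_dg80[gid] = duplex_dg(win, 80.0).dG
        truth.sd_windows[gid] = off  # keep only the transcript-relative offset
    return ds


def simulate_tss_track(dataset: SyntheticDataset,
                       config: SimulationConfig) -> pd.DataFrame:
    """A per-position 5'-end count track: planted TSSs plus noise."""
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    n_param = cfg.tss_count_nb_n
    p_param = n_param / (n_param + (cfg.tss_count_mean - 0))
    rows = []
    planted = set()
    for pos, strand in dataset.truth.tss_positions:
        count = int(rng.negative_binomial(n_param, p_param))
        rows.append({"position": pos, "strand": strand, "count": count})
        planted.add((pos, strand))
    n_noise = int(cfg.tss_noise_rate * dataset.genome.length)
    for _ in range(n_noise):
        while True:
            p = int(rng.integers(0, dataset.genome.length))
            s = "+" if rng.random() < 0.5 else "-"
            if (p, s) not in planted:
                break
        rows.append({"position": p, "strand": s,
                     "count": 1 + int(rng.geometric(0.5))})
    track = pd.DataFrame(rows).groupby(
        ["position", "strand"], as_index=False)["count"].sum()
    dataset.tss_track = track
    return track


def simulate_expression_proteome(dataset: SyntheticDataset,
                                 config: SimulationConfig
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition fragment counts and spectral counts.

    Log-phase mRNA and protein abundance are drawn from a bivariate
    log-normal with the configured correlation; spectral counts are
    Poisson with mean abundance x observable-peptide count x depth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    genes = [f for f in dataset.features if f.kind == "CDS"]
    n = len(genes)

    zx = rng.standard_normal(n)
    zy = rng.standard_normal(n)
    rho = cfg.mrna_protein_r
    z_prot = rho * zx + np.sqrt(1 - rho ** 2) * zy
    log_fpkm = cfg.fpkm_log_median + cfg.fpkm_log_sigma * zx
    log10_ab = cfg.abundance_log10_mean + cfg.abundance_log10_sd * z_prot
    fpkm = np.exp(log_fpkm)
    abundance = 10.0 ** log10_ab

    # fragment counts per condition consistent with the target FPKM
    expr_rows = []
    for ci, cond in enumerate(CONDITIONS):
        jitter = np.exp(rng.normal(0.0, cfg.condition_jitter, size=n))
        for i, f in enumerate(genes):
            target = fpkm[i] * jitter[i]
            c = target * f.length * cfg.total_fragments / 1e9
            expr_rows.append({"feature_id": f.feature_id, "condition": cond,
                              "fragment_count": int(round(c))})
    expression = pd.DataFrame(expr_rows)

    # protein sequences (for tryptic-peptide normalization)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    aa_p = np.array([0.083, 0.014, 0.054, 0.067, 0.039, 0.071, 0.022, 0.059,
                     0.058, 0.097, 0.024, 0.040, 0.047, 0.038, 0.055, 0.066,
                     0.053, 0.069, 0.011, 0.033])
    aa_p = aa_p / aa_p.sum()
    proteins = {}
    for f in genes:
        plen = max(50, f.length // 3 - 1)
        proteins[f.feature_id] = "".join(
            aa[i] for i in rng.choice(20, size=plen, p=aa_p))
    dataset.proteins = proteins

    from .expression import count_tryptic_peptides
    spectral_rows = []
    for i, f in enumerate(genes):
        n_pep = count_tryptic_peptides(proteins[f.feature_id])
        lam = abundance[i] * max(1, n_pep) * cfg.spectral_depth
        total = int(rng.poisson(lam))
        split = rng.binomial(total, 0.6)
        spectral_rows.append({"protein_id": f.feature_id, "condition": "log",
                              "spectral_count": int(split)})
        spectral_rows.append({"protein_id": f.feature_id,
                              "condition": "late_exp",
                              "spectral_count": int(total - split)})
    spectral = pd.DataFrame(spectral_rows)

    dataset.truth.expression = {f.feature_id: float(fpkm[i])
                                for i, f in enumerate(genes)}
    dataset.truth.abundance = {f.feature_id: float(abundance[i])
                               for i, f in enumerate(genes)}
    dataset.expression = expression
    dataset.spectral = spectral
    return expression, spectral


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Genome architecture + TSS track + expression/proteome in one call."""
    ds = simulate_genome_architecture(config)
    simulate_tss_track(ds, config)
    simulate_expression_proteome(ds, config)
    return ds
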