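"""End-to-end orchestration: run all analysis stages and emit one report.

The report runs architecture -> promoters -> RBS -> expression ->
proteome on either simulated inputs (a ``simulation`` config block) or
files named in the config, and assembles a flat summary-metric table.
Stages with missing inputs are skipped; no stage mutates another
stage's outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import expression as expr
from . import promoters as prom
from . import rbs as rbs_mod
from .io import GenomeSequence, read_bed, read_features, read_genome, read_table
from .simulate import SimulationConfig, simulate_all
from .stats import mad, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_report", "train_promoter_model",
           "promoter_stage", "architecture_stage", "rbs_stage",
           "expression_stage"]

DEFAULT_TEMPS = (37.0, 65.0, 80.0, 90.0)


@dataclass
class ReportBundle:
    summary: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1, default=float)
        pd.Series(self.summary).to_csv(out / "summary.tsv", sep="\t",
                                       header=["value"])
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=True)


def architecture_stage(genome, features, tus, tss_records, tf_sites) -> dict:
    out: dict = {}
    gaps = arch.intergenic_gaps(features, genome)
    out["median_intergenic_gap_bp"] = float(np.median(gaps))
    coding_tus = [t for t in tus if t.gene_ids]
    n_genes = [len(t.gene_ids) for t in coding_tus]
    out["n_tus"] = len(tus)
    out["mean_genes_per_tu"] = float(np.mean(n_genes))
    out["pct_polycistronic"] = 100.0 * float(np.mean([k >= 2 for k in n_genes]))

    sub = arch.detect_suboperons(tus)
    sub_coding = [s for s in sub["suboperonic"]
                  if s in {t.tu_id for t in coding_tus}]
    out["pct_suboperonic"] = 100.0 * len(sub_coding) / len(coding_tus)
    out["n_alternative_tss_groups"] = len(sub["alternative_tss_groups"])

    utrs = [u for u in arch.utr_lengths(tus, features) if u.valid]
    if utrs:
        groups = pd.Series([u.group for u in utrs]).value_counts()
        n = len(utrs)
        for g in ("Short", "Common", "Other"):
            out[f"utr5_frac_{g.lower()}"] = float(groups.get(g, 0)) / n
        out["median_utr5_nt"] = float(np.median([u.utr5_length for u in utrs]))

    anti = arch.classify_antisense(tus, features)
    out["pct_genes_antisense"] = 100.0 * len(anti) / max(1, len(features))
    if anti:
        out["pct_antisense_from_3utr"] = 100.0 * float(
            np.mean([v == "3utr" for v in anti.values()]))

    pirs = arch.extract_pirs(features, tss_records, tf_sites, genome)
    out["n_pirs"] = len(pirs)
    if pirs:
        by_group = {"0": [], "1": [], "2+": []}
        for p in pirs:
            key = "0" if p.tf_site_count == 0 else (
                "1" if p.tf_site_count == 1 else "2+")
            by_group[key].append(p.length)
        for key, lens in by_group.items():
            if lens:
                out[f"median_pir_len_tf{key}"] = float(np.median(lens))
        if by_group["0"] and by_group["1"]:
            out["pir_tf1_vs_tf0_p"] = wilcoxon_rank_sum(
                by_group["1"], by_group["0"], alternative="greater").p_value
        if by_group["0"] and by_group["2+"]:
            out["pir_tf2_vs_tf0_p"] = wilcoxon_rank_sum(
                by_group["2+"], by_group["0"], alternative="greater").p_value
    classes = arch.map_tf_sites(tf_sites, pirs, features, genome)
    counts = pd.Series(list(classes.values())).value_counts()
    for cls in ("within_pir", "intergenic_non_promoter", "genic"):
        out[f"tf_sites_{cls}"] = int(counts.get(cls, 0))
    return out


def _refine_pwm(sites: list[str], seqs: list[str], element: str,
                window: tuple[int, int], pseudocount: float, seed: int):
    """PWM from EM-aligned sites, rebuilt from the confident ones.

    OOPS EM assigns one occurrence to every sequence, including those
    that carry no real element (not every promoter has a -35 box, and
    some windows are weak antisense starts), which washes out the
    matrix. The confidence threshold is self-calibrating: the upper
    quartile of max-placement scores on base-shuffled windows — what
    the alignment step would extract from pure background.
    """
    pwm, w = prom.build_pwm(sites, element, pseudocount)
    rng = np.random.default_rng(seed)
    null_max = []
    for s in seqs[:200]:
        arr = np.array(list(s))
        rng.shuffle(arr)
        placed = prom._best_placement("".join(arr), w, window)
        if placed is not None:
            null_max.append(placed[1])
    thr = float(np.quantile(null_max, 0.75)) if null_max else 0.0
    confident = [x for x in sites if prom.iseq(x, w) > thr]
    if len(confident) >= 10:
        pwm, _ = prom.build_pwm(confident, element, pseudocount)
    return pwm


def train_promoter_model(genome, tss_records, restarts: int = 3,
                         seed: int = 0, pseudocount: float = 0.5):
    """Discover promoter elements and build the scoring model.

    Runs windowed EM for the extended -10 nonamer and the -35 hexamer
    on the 44-nt upstream windows of all TSSs, refines each matrix on
    its confidently aligned sites; the -10 hexamer weights are the
    nonamer's 3'-terminal six columns. The spacer distribution comes
    from the max-information placements of the trained elements.
    """
    seqs = [prom.upstream_window(genome, t.position, t.strand)
            for t in tss_records]
    ext_sites = prom.discover_motifs(seqs, "extended_minus10",
                                     restarts=restarts, seed=seed)
    m35_sites = prom.discover_motifs(seqs, "minus35",
                                     restarts=restarts, seed=seed + 1)
    ext_pwm = _refine_pwm(ext_sites, seqs, "extended_minus10",
                          prom.PROX_WINDOW, pseudocount, seed + 2)
    m35_pwm = _refine_pwm(m35_sites, seqs, "minus35",
                          prom.DIST_WINDOW, pseudocount, seed + 3)
    m10_pwm = prom.PWM(element="minus10", f=ext_pwm.f[:, 3:],
                       n_sites=ext_pwm.n_sites, pseudocount=pseudocount)
    pwms = {"extended_minus10": ext_pwm, "minus10": m10_pwm,
            "minus35": m35_pwm}

    # empirical spacer distribution from per-promoter element placements
    w10 = m10_pwm.weights()
    w35 = m35_pwm.weights()
    counts: dict[int, int] = {}
    for s in seqs:
        p10 = prom._best_placement(s, w10, prom.PROX_WINDOW)
        p35 = prom._best_placement(s, w35, prom.DIST_WINDOW)
        if p10 is None or p35 is None:
            continue
        d = p10[0] - (p35[0] + 6)
        if prom.SPACER_RANGE[0] <= d <= prom.SPACER_RANGE[1]:
            counts[d] = counts.get(d, 0) + 1
    spacer_model = prom.gap_surprisal(counts)
    return pwms, spacer_model


def promoter_stage(genome, tss_records, restarts: int = 3,
                   seed: int = 0) -> tuple[dict, pd.DataFrame]:
    pwms, spacer_model = train_promoter_model(genome, tss_records,
                                              restarts=restarts, seed=seed)
    scores = prom.score_tss_set(genome, tss_records, pwms, spacer_model)
    df = pd.DataFrame([{
        "tss_id": s.tss_id, "mode1": s.mode1, "mode2": s.mode2,
        "mode3": s.mode3, "best_mode": s.best_mode, "best_bits": s.best_bits,
    } for s in scores])
    best = df["best_bits"].dropna()
    out = {
        "median_best_mode_bits": float(best.median()),
        "frac_promoters_positive_bits": float((best > 0).mean()),
        "consensus_extended_minus10": pwms["extended_minus10"].consensus(),
        "consensus_minus35": pwms["minus35"].consensus(),
        "spacer_mode_bp": int(max(spacer_model.counts,
                                  key=spacer_model.counts.get)),
    }
    for m in (1, 2, 3):
        share = float((df["best_mode"] == m).mean())
        out[f"best_mode{m}_share"] = share
    return out, df


def rbs_stage(genome, features, temps=DEFAULT_TEMPS,
              profile_flank: int = 100, profile_max_genes: int = 150) -> dict:
    cds = [f for f in features if f.kind == "CDS"]
    out: dict = {}
    mins = {}
    for T in temps:
        recs = [rbs_mod.rbs_scan(c, genome, T) for c in cds]
        v = np.array([r.local_min_dG for r in recs])
        mins[T] = v
        out[f"median_rbs_dg_{T:g}C"] = float(np.median(v))
        out[f"mad_rbs_dg_{T:g}C"] = mad(v)
        out[f"frac_rbs_dg_negative_{T:g}C"] = float(np.mean(v < 0))
    if profile_max_genes and len(cds) and profile_flank:
        sub = cds[:profile_max_genes]
        profile = rbs_mod.positional_profile(sub, genome, [temps[0]],
                                             flank=profile_flank)
        col = profile[temps[0]]
        out["rbs_profile_min_offset"] = int(col.idxmin())
    return out


def expression_stage(features, expression: pd.DataFrame,
                     spectral: pd.DataFrame | None,
                     proteins: dict[str, str] | None,
                     fpkm_threshold: float = 8.0) -> dict:
    out: dict = {}
    lengths = {f.feature_id: f.length for f in features}
    exclude = {f.feature_id for f in features if f.kind == "functional_RNA"}
    log_fpkm: dict[str, float] = {}
    for cond, grp in expression.groupby("condition"):
        counts = dict(zip(grp["feature_id"], grp["fragment_count"]))
        table = expr.compute_fpkm(counts, lengths, exclude)
        frac = expr.expressed_fraction(table["fpkm"], [fpkm_threshold])
        out[f"expressed_frac_{cond}"] = float(frac.iloc[0])
        if cond == "log":
            log_fpkm = dict(zip(table["feature_id"], table["fpkm"]))
    if spectral is not None and proteins and log_fpkm:
        abundances = expr.abundance_scores(spectral, proteins)
        out["n_quantified_proteins"] = len(abundances)
        res = expr.mrna_protein_correlation(log_fpkm, abundances)
        out["mrna_protein_pearson_r"] = res.value
        out["mrna_protein_pearson_p"] = res.p_value
    return out


def _load_inputs(cfg: dict):
    """Resolve inputs from a simulation block or from file paths."""
    if "simulation" in cfg:
        sim = dict(cfg["simulation"])
        sc = SimulationConfig(**sim)
        ds = simulate_all(sc)
        return dict(genome=ds.genome, features=ds.features, tus=ds.tus,
                    tss_records=ds.tss_records, tf_sites=ds.tf_sites,
                    expression=ds.expression, spectral=ds.spectral,
                    proteins=ds.proteins, dataset=ds)
    inputs: dict = {"dataset": None}
    paths = cfg.get("inputs", {})
    if "genome" in paths:
        inputs["genome"] = read_genome(paths["genome"])[0]
    if "features" in paths:
        inputs["features"] = read_features(paths["features"])
    if "tus" in paths:
        inputs["tus"] = read_table(paths["tus"], "tu")
    if "tss" in paths:
        inputs["tss_records"] = read_table(paths["tss"], "tss")
    if "tf_sites" in paths:
        inputs["tf_sites"] = read_bed(paths["tf_sites"])
    if "expression" in paths:
        inputs["expression"] = read_table(paths["expression"], "expression")
    return inputs


def run_report(config: dict | str | Path,
               out_dir: str | Path | None = None) -> ReportBundle:
    """Execute every feasible stage and assemble the summary table."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    inputs = _load_inputs(config)
    seed = int(config.get("seed", config.get("simulation", {}).get("seed", 0)))

    bundle = ReportBundle(provenance={
        "seed": seed,
        "simulated": "simulation" in config,
    })
    genome = inputs.get("genome")
    features = inputs.get("features")
    tus = inputs.get("tus")
    tss_records = inputs.get("tss_records")
    tf_sites = inputs.get("tf_sites", [])

    if genome is not None and features and tus and tss_records:
        bundle.summary.update(architecture_stage(
            genome, features, tus, tss_records, tf_sites))
    else:
        logger.info("architecture stage skipped (missing inputs)")

    if genome is not None and tss_records:
        prom_summary, prom_table = promoter_stage(
            genome, tss_records, restarts=int(config.get("restarts", 3)),
            seed=seed)
        bundle.summary.update(prom_summary)
        bundle.tables["promoter_scores"] = prom_table

    if genome is not None and features:
        temps = tuple(config.get("temperatures", DEFAULT_TEMPS))
        bundle.summary.update(rbs_stage(genome, features, temps=temps))

    if inputs.get("expression") is not None and features:
        bundle.summary.update(expression_stage(
            features, inputs["expression"], inputs.get("spectral"),
            inputs.get("proteins")))

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
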