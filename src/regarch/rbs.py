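"""Shine-Dalgarno : anti-Shine-Dalgarno hybridization energetics.

The ribosome binding site (RBS) is modelled as the best contiguous
helix a 10-nt mRNA window can form with the 16S rRNA 3'-terminal
anti-SD sequence 5'-UCACCUCCUU-3'. Duplex stability follows the RNA
nearest-neighbor model: a helix of stacked base pairs (Watson-Crick
plus G.U wobbles) contributes summed stack enthalpies and entropies,
plus a duplex-initiation term and a penalty for each terminal A-U or
G-U pair, giving

    dG(T) = dH_total - T_kelvin * dS_total.

The reported value for a window is the minimum dG over every
antiparallel ungapped registration against the anti-SD and every
contiguous complementary run of >= 3 pairs within it; windows that
cannot form such a run score dG = 0 (non-binders are treated as
energetically neutral). Loops, bulges, dangling ends and intramolecular
structure are outside this model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneFeature, GenomeSequence, revcomp

__all__ = [
    "ANTI_SD",
    "NNParameterSet",
    "DuplexResult",
    "RBSRecord",
    "load_nn_params",
    "duplex_dg",
    "rbs_scan",
    "positional_profile",
    "genome_rbs_summary",
]

ANTI_SD = "UCACCUCCUU"
MIN_HELIX = 3
T_RANGE = (20.0, 100.0)

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WEAK = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}  # terminal-penalty pairs


@dataclass
class NNParameterSet:
    """Stacked-pair dH/dS table plus initiation and terminal penalties."""

    stacks: dict[str, tuple[float, float]]  # key "XY/ZW" -> (dH, dS)
    init: tuple[float, float]
    terminal: tuple[float, float]
    version: str = "1"

    def stack(self, top: str, bottom: str) -> tuple[float, float]:
        return self.stacks[f"{top}/{bottom}"]


def load_nn_params() -> NNParameterSet:
    """The packaged RNA/RNA nearest-neighbor table (both strand readings)."""
    ref = importlib.resources.files("regarch.data") / "rna_nn_params.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    stacks: dict[str, tuple[float, float]] = {}
    init = terminal = None
    for r in df.itertuples(index=False):
        val = (float(r.dH), float(r.dS))
        if r.kind == "stack":
            top, bottom = r.key.split("/")
            stacks[f"{top}/{bottom}"] = val
            stacks.setdefault(f"{bottom}/{top}", val)  # strand-swap symmetry
        elif r.kind == "init":
            init = val
        elif r.kind == "terminal":
            terminal = val
    if init is None or terminal is None:
        raise ValueError("parameter table missing init/terminal entries")
    return NNParameterSet(stacks=stacks, init=init, terminal=terminal)


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_params() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_nn_params()
    return _DEFAULT_PARAMS


@dataclass
class DuplexResult:
    query: str
    dG: float  # kcal/mol at temperature T
    T: float  # degrees C
    span: tuple[int, int] | None = None  # query indices [start, end) of the helix


@dataclass
class RBSRecord:
    gene_id: str
    local_min_dG: float
    offset: int | None  # 5'-end of the minimizing window relative to the start codon
    truncated: bool = False


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# dG memo per (params version, T): {10-mer -> (dG, span)}
_dg_cache: dict[tuple[str, float], dict[str, tuple[float, tuple | None]]] = {}


def duplex_dg(window: str, T: float,
              params: NNParameterSet | None = None,
              anti_sd: str = ANTI_SD) -> DuplexResult:
    """Minimum hybridization dG of a 10-nt window against the anti-SD.

    ``window`` may be DNA or RNA (T is read as U). Raises for windows
    that are not 10 nt or temperatures outside 20-100 degrees C.
    """
    if params is None:
        params = default_params()
    q = _to_rna(window)
    if len(q) != 10:
        raise ValueError(f"window must be 10 nt, got {len(q)}")
    if not T_RANGE[0] <= T <= T_RANGE[1]:
        raise ValueError(f"temperature {T} outside {T_RANGE} degrees C")

    use_cache = anti_sd == ANTI_SD
    cache = _dg_cache.setdefault((params.version, float(T)), {}) if use_cache else None
    if cache is not None and q in cache:
        dg, span = cache[q]
        return DuplexResult(query=q, dG=dg, T=T, span=span)

    dg, span = _min_duplex(q, _to_rna(anti_sd), T, params)
    if cache is not None:
        cache[q] = (dg, span)
    return DuplexResult(query=q, dG=dg, T=T, span=span)


def _min_duplex(q: str, anti: str, T: float,
                params: NNParameterSet) -> tuple[float, tuple | None]:
    bad = set(q) - set("ACGU")
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)} in window {q!r}")
    t_k = T + 273.15
    nq, na = len(q), len(anti)
    best = 0.0
    best_span = None
    for k in range(nq + na - 1):  # q[i] pairs anti[k - i]
        i_lo, i_hi = max(0, k - na + 1), min(nq - 1, k)
        run: list[int] = []
        for i in range(i_lo, i_hi + 2):
            paired = i <= i_hi and (q[i], anti[k - i]) in _PAIRS
            if paired:
                run.append(i)
                continue
            if len(run) >= MIN_HELIX:
                got = _best_subhelix(q, anti, k, run, t_k, params)
                if got is not None and got[0] < best:
                    best, best_span = got
            run = []
    return best, best_span


def _best_subhelix(q: str, anti: str, k: int, run: list[int], t_k: float,
                   params: NNParameterSet) -> tuple[float, tuple] | None:
    """Min dG over all contiguous sub-runs of length >= MIN_HELIX."""
    a0 = run[0]
    m = len(run)
    # stack (i, i+1): top q[i]q[i+1], bottom (5'->3') anti[k-i-1]anti[k-i]
    sH = np.zeros(m - 1)
    sS = np.zeros(m - 1)
    for j in range(m - 1):
        i = a0 + j
        dH, dS = params.stack(q[i:i + 2], anti[k - i - 1:k - i + 1])
        sH[j], sS[j] = dH, dS
    cH = np.concatenate([[0.0], np.cumsum(sH)])
    cS = np.concatenate([[0.0], np.cumsum(sS)])
    tH, tS = params.terminal
    iH, iS = params.init
    best = None
    for a in range(m - MIN_HELIX + 1):
        for b in range(a + MIN_HELIX - 1, m):
            dH = iH + cH[b] - cH[a]
            dS = iS + cS[b] - cS[a]
            for end in (a0 + a, a0 + b):
                if (q[end], anti[k - end]) in _WEAK:
                    dH += tH
                    dS += tS
            dg = dH - t_k * dS / 1000.0
            if best is None or dg < best[0]:
                best = (dg, (a0 + a, a0 + b + 1))
    return best


# ---------------------------------------------------------------------------
# Genome-scale scans

def _sense_context(genome: GenomeSequence, cds: GeneFeature,
                   up: int, down: int) -> tuple[str, bool]:
    """Sense-strand sequence from -up to +down around the start codon.

    Returns (sequence, truncated). Missing positions on a linear contig
    are filled with N (windows touching them are skipped by callers).
    """
    L = genome.length
    if cds.strand == "+":
        s, e = cds.start - up, cds.start + down
    else:
        s, e = cds.end - down, cds.end + up
    truncated = False
    if genome.topology == "circular":
        seq = genome.fetch(s, e)
    else:
        pad_l, pad_r = max(0, -s), max(0, e - L)
        truncated = bool(pad_l or pad_r)
        seq = "N" * pad_l + genome.sequence[max(0, s):min(L, e)] + "N" * pad_r
    if cds.strand == "-":
        seq = revcomp(seq)
    return seq, truncated


def rbs_scan(cds: GeneFeature, genome: GenomeSequence, T: float,
             params: NNParameterSet | None = None) -> RBSRecord:
    """Local-minimum dG over 10-nt windows starting in [-30, -1].

    Offsets are the window's 5' end relative to the first CDS base
    (strand-aware); ties go to the window closest to the start codon.
    """
    ctx, truncated = _sense_context(genome, cds, up=30, down=9)
    best_dg = 0.0
    best_off: int | None = None
    for off in range(-30, 0):
        win = ctx[off + 30: off + 40]
        if "N" in win:
            continue
        dg = duplex_dg(win, T, params).dG
        if best_off is None or dg <= best_dg:
            best_dg, best_off = dg, off
    return RBSRecord(gene_id=cds.feature_id, local_min_dG=best_dg,
                     offset=best_off, truncated=truncated)


def positional_profile(cds_set: Sequence[GeneFeature], genome: GenomeSequence,
                       T_list: Sequence[float],
                       params: NNParameterSet | None = None,
                       flank: int = 100) -> pd.DataFrame:
    """Median dG of the 10-mer starting at each offset in [-flank, +flank].

    One column per temperature, indexed by offset (window 5' end
    relative to the first CDS base).
    """
    if not cds_set:
        raise ValueError("need at least one CDS")
    offsets = list(range(-flank, flank + 1))
    values = {T: [] for T in T_list}
    per_gene: dict[float, list[list[float]]] = {T: [] for T in T_list}
    for cds in cds_set:
        ctx, _ = _sense_context(genome, cds, up=flank, down=flank + 10)
        for T in T_list:
            row = []
            for off in offsets:
                win = ctx[off + flank: off + flank + 10]
                row.append(np.nan if "N" in win else duplex_dg(win, T, params).dG)
            per_gene[T].append(row)
    data = {T: np.nanmedian(np.array(per_gene[T]), axis=0) for T in T_list}
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


def genome_rbs_summary(genomes: Iterable[dict], T_eval: float,
                       params: NNParameterSet | None = None) -> pd.DataFrame:
    """Per-genome median / MAD / fraction-negative of local-min RBS dG.

    Each entry needs keys: name, genome (GenomeSequence), features
    (gene list; only CDS kind is scanned), ogt (degrees C or NaN).
    Genomes with zero CDS are excluded with a warning.
    """
    import logging

    from .stats import mad

    rows = []
    for g in genomes:
        cds = [f for f in g["features"] if f.kind == "CDS"]
        if not cds:
            logging.getLogger(__name__).warning(
                "genome %s has no CDS; excluded", g["name"])
            continue
        mins = np.array([rbs_scan(c, g["genome"], T_eval, params).local_min_dG
                         for c in cds])
        rows.append({
            "name": g["name"],
            "ogt": g.get("ogt", np.nan),
            "n_cds": len(cds),
            "median_dG": float(np.median(mins)),
            "mad_dG": mad(mins),
            "frac_negative": float(np.mean(mins < 0)),
        })
    return pd.DataFrame(rows)
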