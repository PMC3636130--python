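"""TSS calling, FPKM, ncRNA filtering, tryptic digestion, abundance scores.

The proteome side follows spectral-count normalization: a protein's
abundance score is its total spectral count divided by the number of
"observable" fully tryptic peptides — cleavage C-terminal to K/R except
before P, zero missed cleavages, length >= 6, and some charge state
z in {1,2,3} placing the peptide in the 400-2000 m/z window (hence a
maximum monoisotopic mass of ~6000 Da).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as pmass
from scipy import stats as sps

from .io import TSSRecord
from .stats import StatResult

logger = logging.getLogger(__name__)

__all__ = [
    "TranscribedRegion",
    "ProteinAbundance",
    "call_tss",
    "compute_fpkm",
    "expressed_fraction",
    "ncrna_candidates",
    "digest",
    "count_tryptic_peptides",
    "abundance_scores",
    "mrna_protein_correlation",
]

PROTON_MASS = 1.00728  # Da
MZ_RANGE = (400.0, 2000.0)
MAX_CHARGE = 3
MIN_RESIDUES = 6

NCRNA_MIN_LENGTH = 68  # strict: length must exceed this
NCRNA_FPKM_THRESHOLD = 8.0
NCRNA_MIN_CONDITIONS = 2

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


@dataclass
class TranscribedRegion:
    region_id: str
    start: int
    end: int
    strand: str
    fpkm: dict[str, float]
    tu_associated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProteinAbundance:
    protein_id: str
    total_spectral_count: int
    n_tryptic_peptides: int
    abundance_score: float


def call_tss(five_prime_counts, min_reads: int = 5) -> list[TSSRecord]:
    """Positions with >= min_reads uniquely mapped 5' ends become TSSs.

    ``five_prime_counts`` is a DataFrame with columns position, strand,
    count (a bedGraph-style per-position track) or an iterable of
    (position, strand, count) tuples. Output order is deterministic
    (by position then strand) regardless of input order.
    """
    if isinstance(five_prime_counts, pd.DataFrame):
        it = five_prime_counts[["position", "strand", "count"]].itertuples(index=False)
    else:
        it = five_prime_counts
    out = [
        TSSRecord(position=int(p), strand=str(s), read_count=int(c))
        for p, s, c in it if int(c) >= min_reads
    ]
    return sorted(out, key=lambda t: (t.position, t.strand))


def compute_fpkm(fragment_counts: dict[str, int], lengths: dict[str, int],
                 exclude: set[str] = frozenset()) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_nt * total counted fragments).

    Features in ``exclude`` (functional RNAs) contribute to neither the
    numerator nor the total.
    """
    kept = {f: c for f, c in fragment_counts.items() if f not in exclude}
    total = sum(kept.values())
    if total == 0:
        raise ValueError("zero total fragments after exclusions")
    rows = []
    for f, c in kept.items():
        ln = lengths[f]
        if ln <= 0:
            raise ValueError(f"non-positive length for {f}")
        rows.append({"feature_id": f, "fragment_count": c,
                     "fpkm": c * 1e9 / (ln * total)})
    return pd.DataFrame(rows)


def expressed_fraction(fpkm: pd.Series | np.ndarray,
                       thresholds) -> pd.Series:
    """Fraction of genes with FPKM >= t for each threshold t."""
    v = np.asarray(fpkm, dtype=float)
    th = np.asarray(list(thresholds), dtype=float)
    frac = [(v >= t).mean() for t in th]
    return pd.Series(frac, index=th, name="expressed_fraction")


def ncrna_candidates(regions: list[TranscribedRegion]) -> list[TranscribedRegion]:
    """Putative ncRNAs: not TU-associated, longer than 68 nt, and
    FPKM > 8 in at least two conditions. Pure filter, order preserved."""
    out = []
    for r in regions:
        if r.tu_associated:
            continue
        if r.length <= NCRNA_MIN_LENGTH:
            continue
        n_hot = sum(1 for v in r.fpkm.values() if v > NCRNA_FPKM_THRESHOLD)
        if n_hot >= NCRNA_MIN_CONDITIONS:
            out.append(r)
    return out


def digest(protein_seq: str) -> list[str]:
    """Fully tryptic fragments, in order; concatenation == input.

    Cleaves C-terminal to K or R except when the next residue is P;
    zero missed cleavages. Raises on non-standard residues.
    """
    seq = protein_seq.upper()
    for i, aa in enumerate(seq):
        if aa not in _STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
    return [p for p in _TRYPSIN.split(seq) if p]


def _mz_ok(mono_mass: float) -> bool:
    lo, hi = MZ_RANGE
    return any(lo <= (mono_mass + z * PROTON_MASS) / z <= hi
               for z in range(1, MAX_CHARGE + 1))


def count_tryptic_peptides(protein_seq: str) -> int:
    """Number of observable fully tryptic peptides of a protein."""
    n = 0
    for pep in digest(protein_seq):
        if len(pep) < MIN_RESIDUES:
            continue
        m = pmass.fast_mass(pep, ion_type="M", charge=0)
        if _mz_ok(m):
            n += 1
    return n


def abundance_scores(spectral_counts: pd.DataFrame,
                     proteins: dict[str, str],
                     log_condition: str = "log") -> list[ProteinAbundance]:
    """Normalized protein abundances from spectral counts.

    ``spectral_counts`` has columns protein_id, condition,
    spectral_count (redundant multi-protein peptides are assumed
    excluded upstream). Retains proteins with a total spectral count
    >= 2 across conditions and >= 1 observation under the log-phase
    condition; the score divides the total count by the protein's
    observable tryptic peptide count.
    """
    out = []
    grouped = spectral_counts.groupby("protein_id")
    for pid, grp in grouped:
        total = int(grp["spectral_count"].sum())
        if total < 2:
            continue
        log_count = int(
            grp.loc[grp["condition"] == log_condition, "spectral_count"].sum())
        if log_count < 1:
            continue
        seq = proteins.get(str(pid))
        if seq is None:
            logger.warning("no sequence for %s; excluded", pid)
            continue
        n_pep = count_tryptic_peptides(seq)
        if n_pep == 0:
            logger.warning("%s has no qualifying tryptic peptides; excluded", pid)
            continue
        out.append(ProteinAbundance(
            protein_id=str(pid), total_spectral_count=total,
            n_tryptic_peptides=n_pep, abundance_score=total / n_pep))
    return out


def mrna_protein_correlation(expression: dict[str, float],
                             abundances: list[ProteinAbundance]) -> StatResult:
    """Pearson r of log10(FPKM) vs log10(abundance score).

    Genes with either value <= 0 are excluded; the p-value is the
    t-test for r != 0. The raw-scale correlation is reported alongside.
    """
    pairs = [(expression[a.protein_id], a.abundance_score)
             for a in abundances if a.protein_id in expression]
    kept = [(x, y) for x, y in pairs if x > 0 and y > 0]
    if len(kept) < 3:
        raise ValueError("fewer than 3 complete mRNA/protein pairs")
    x = np.log10([p[0] for p in kept])
    y = np.log10([p[1] for p in kept])
    r, p = sps.pearsonr(x, y)
    raw_r = float(np.corrcoef([p_[0] for p_ in kept], [p_[1] for p_ in kept])[0, 1])
    return StatResult(name="mrna_protein_pearson", value=float(r),
                      p_value=float(p),
                      extra={"n": len(kept), "raw_r": raw_r})
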