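"""Sigma-70 promoter models: PWMs, individual information, gap surprisal.

The information content of an individual sequence under a motif model is

    Iseq = sum_i Riw(b_i, i),   Riw(b, i) = 2 + log2 f(b, i)   [bits]

where f(b, i) is the per-position base probability of the motif. A
whole promoter combines element scores under three sigma-70 binding
modes:

    mode 1 = Iseq(-10 hexamer) + Iseq(-35 hexamer) - GS(d)
    mode 2 = Iseq(extended -10 nonamer)
    mode 3 = Iseq(extended -10 nonamer) + Iseq(-35 hexamer) - GS(d)

GS(d) = -log2 p(d) is the gap surprisal of the spacer length d between
the 3' end of the -35 element and the 5' end of the -10 hexamer,
restricted to 15-20 bp. Higher bits mean stronger (more negative)
relative binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomeSequence, revcomp

__all__ = [
    "ELEMENT_WIDTHS",
    "PWM",
    "InformationWeights",
    "SpacerModel",
    "PromoterScore",
    "build_pwm",
    "iseq",
    "gap_surprisal",
    "score_promoter",
    "discover_motifs",
    "at_profile",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

ELEMENT_WIDTHS = {"minus35": 6, "minus10": 6, "extended_minus10": 9}

SPACER_RANGE = (15, 20)

# Element search windows, positions relative to the TSS (inclusive,
# -1 = base immediately 5' of the TSS). The -10 and extended -10 boxes
# live in [-18, -1]; the -35 box in [-44, -20].
PROX_WINDOW = (-18, -1)
DIST_WINDOW = (-44, -20)
UPSTREAM_LEN = 44


@dataclass
class PWM:
    """Per-position base probabilities f(b, i) of one promoter element."""

    element: str
    f: np.ndarray  # shape (4, width), rows in ACGT order
    n_sites: int
    pseudocount: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (ACGT)")
        if not np.allclose(self.f.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.f.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.f.argmax(axis=0))

    def weights(self) -> "InformationWeights":
        with np.errstate(divide="ignore"):
            riw = 2.0 + np.log2(self.f)
        return InformationWeights(element=self.element, riw=riw)

    def expected_information(self) -> float:
        """Sum over columns of 2 - H_i = E[Iseq] for sites drawn from f."""
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(self.f > 0, self.f * np.log2(self.f), 0.0).sum(axis=0)
        return float((2.0 - h).sum())

    def sample_sites(self, n: int, rng: np.random.Generator) -> list[str]:
        cols = [rng.choice(4, size=n, p=self.f[:, j]) for j in range(self.width)]
        return ["".join(BASES[cols[j][i]] for j in range(self.width))
                for i in range(n)]


@dataclass
class InformationWeights:
    element: str
    riw: np.ndarray  # 2 + log2 f, shape (4, width); -inf where f = 0

    @property
    def width(self) -> int:
        return self.riw.shape[1]


def build_pwm(aligned_sites: list[str], element: str,
              pseudocount: float = 0.5) -> tuple[PWM, InformationWeights]:
    """Estimate a PWM and its information weights from aligned sites.

    f(b,i) = (count(b,i) + pseudocount) / (n + 4 * pseudocount).
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least two sites")
    width = ELEMENT_WIDTHS.get(element)
    if width is None:
        width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError(f"sites must all have width {width} for {element!r}")
    counts = np.zeros((4, width))
    for s in aligned_sites:
        for i, b in enumerate(s.upper()):
            counts[_BASE_INDEX[b], i] += 1
    n = len(aligned_sites)
    f = (counts + pseudocount) / (n + 4 * pseudocount)
    pwm = PWM(element=element, f=f, n_sites=n, pseudocount=pseudocount)
    return pwm, pwm.weights()


def iseq(sequence: str, weights: InformationWeights) -> float:
    """Individual information of one sequence, in bits."""
    if len(sequence) != weights.width:
        raise ValueError(
            f"sequence length {len(sequence)} != motif width {weights.width}")
    return float(sum(weights.riw[_BASE_INDEX[b], i]
                     for i, b in enumerate(sequence.upper())))


@dataclass
class SpacerModel:
    """Empirical spacer-length distribution and its gap surprisal."""

    counts: dict[int, int]
    gs: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def surprisal(self, d: int) -> float | None:
        """GS(d) in bits, or None when d was never observed."""
        return self.gs.get(d)


def gap_surprisal(spacer_counts: dict[int, int]) -> SpacerModel:
    """GS(d) = -log2(count(d) / total), no small-sample correction."""
    lo, hi = SPACER_RANGE
    for d in spacer_counts:
        if not lo <= d <= hi:
            raise ValueError(f"spacer length {d} outside [{lo},{hi}]")
    total = sum(spacer_counts.values())
    if total <= 0:
        raise ValueError("total spacer count must be positive")
    gs = {d: float(-np.log2(c / total))
          for d, c in spacer_counts.items() if c > 0}
    return SpacerModel(counts=dict(spacer_counts), gs=gs)


@dataclass
class PromoterScore:
    tss_id: str
    iseq_minus10: float | None
    iseq_minus35: float | None
    iseq_extended: float | None
    mode1: float | None
    mode2: float | None
    mode3: float | None
    best_mode: int | None
    best_bits: float | None
    offsets: dict = field(default_factory=dict)


def _best_placement(seq44: str, weights: InformationWeights,
                    window: tuple[int, int]) -> tuple[int, float] | None:
    """Max-Iseq placement of an element inside its positional window.

    seq44 covers TSS-relative positions -44..-1 (index 0 = -44). The
    window gives the allowed inclusive TSS-relative positions of the
    element; placements must fit entirely inside it. Returns
    (element 5'-end position relative to TSS, Iseq); ties break toward
    the TSS. None when the window is absent from the provided sequence.
    """
    w = weights.width
    lo, hi = window  # e.g. (-18, -1)
    best: tuple[int, float] | None = None
    for start in range(lo, hi - w + 2):  # 5' position of the element
        idx = start + UPSTREAM_LEN  # index into seq44
        if idx < 0 or idx + w > len(seq44):
            continue
        sub = seq44[idx:idx + w]
        if "N" in sub:
            continue
        val = iseq(sub, weights)
        if best is None or val >= best[1]:  # >= : later (TSS-proximal) wins ties
            best = (start, val)
    return best


def score_promoter(upstream_seq: str,
                   pwms: dict[str, PWM],
                   spacer_model: SpacerModel,
                   tss_id: str = "") -> PromoterScore:
    """Score one promoter under the three sigma-70 binding modes.

    ``upstream_seq`` is the 44-nt window immediately 5' of the TSS
    (last character = position -1). Shorter windows (contig edge) are
    right-aligned; modes needing missing positions are undefined. Each
    element is placed at its maximum-Iseq offset inside its search
    window; a mode whose spacer d falls outside 15-20 bp, or whose
    GS(d) is undefined, is excluded. Ties in the best mode go to the
    lowest mode number.
    """
    seq = upstream_seq.upper()
    if len(seq) > UPSTREAM_LEN:
        raise ValueError("upstream window longer than 44 nt")
    if len(seq) < UPSTREAM_LEN:
        seq = "N" * (UPSTREAM_LEN - len(seq)) + seq  # right-align at -1

    w10 = pwms["minus10"].weights()
    w35 = pwms["minus35"].weights()
    wext = pwms["extended_minus10"].weights()

    p10 = _best_placement(seq, w10, PROX_WINDOW)
    pext = _best_placement(seq, wext, PROX_WINDOW)
    p35 = _best_placement(seq, w35, DIST_WINDOW)

    offsets: dict = {}
    i10 = iext = i35 = None
    if p10:
        i10 = p10[1]
        offsets["minus10"] = p10[0]
    if pext:
        iext = pext[1]
        offsets["extended_minus10"] = pext[0]
    if p35:
        i35 = p35[1]
        offsets["minus35"] = p35[0]

    lo, hi = SPACER_RANGE

    def spaced(hex5: int) -> float | None:
        """GS(d) for the -35 placement against a -10 hexamer 5' end."""
        if p35 is None:
            return None
        d = hex5 - (p35[0] + w35.width)
        offsets_d = d
        if not lo <= d <= hi:
            return None
        g = spacer_model.surprisal(d)
        if g is None:
            return None
        offsets.setdefault("d", offsets_d)
        return g

    mode1 = mode3 = None
    mode2 = iext
    if p10 is not None and p35 is not None:
        g = spaced(p10[0])
        if g is not None:
            mode1 = i10 + i35 - g
    if pext is not None and p35 is not None:
        # spacer measured to the 5' end of the hexamer portion of the
        # nonamer (3 nt inside it), keeping d comparable across modes
        g = spaced(pext[0] + 3)
        if g is not None:
            mode3 = iext + i35 - g

    modes = [(1, mode1), (2, mode2), (3, mode3)]
    defined = [(m, v) for m, v in modes if v is not None]
    if defined:
        best_mode, best_bits = max(defined, key=lambda t: (t[1], -t[0]))
    else:
        best_mode = best_bits = None
    return PromoterScore(
        tss_id=tss_id, iseq_minus10=i10, iseq_minus35=i35, iseq_extended=iext,
        mode1=mode1, mode2=mode2, mode3=mode3,
        best_mode=best_mode, best_bits=best_bits, offsets=offsets)


def upstream_window(genome: GenomeSequence, position: int, strand: str,
                    length: int = UPSTREAM_LEN) -> str:
    """The ``length`` bases immediately 5' of a TSS, in sense orientation."""
    if strand == "+":
        return genome.fetch(position - length, position)
    return revcomp(genome.fetch(position + 1, position + 1 + length))


def score_tss_set(genome: GenomeSequence, tss_list, pwms, spacer_model
                  ) -> list[PromoterScore]:
    out = []
    for k, t in enumerate(tss_list):
        seq = upstream_window(genome, t.position, t.strand)
        out.append(score_promoter(seq, pwms, spacer_model,
                                  tss_id=f"tss_{t.position}_{t.strand}"))
    return out


# ---------------------------------------------------------------------------
# Motif discovery: fixed-width, one-occurrence-per-sequence EM inside a
# positional window (a deliberately simple stand-in for a gapped
# Gibbs/EM motif finder; width and window are fixed by the element).

def discover_motifs(upstream_seqs: list[str], element: str,
                    window: tuple[int, int] | None = None,
                    restarts: int = 5, seed: int = 0,
                    n_iter: int = 60, pseudocount: float = 0.5) -> list[str]:
    """Recover one aligned site per sequence by windowed OOPS EM.

    ``window`` gives allowed TSS-relative 5'-end positions of the
    element (defaults to the element's search window); the input
    sequences are 44-nt upstream windows ending at position -1. Returns
    the aligned sites of the best restart (by total information),
    deterministically for a given seed.
    """
    width = ELEMENT_WIDTHS[element]
    if window is None:
        window = PROX_WINDOW if element != "minus35" else DIST_WINDOW
    lo, hi = window
    if hi - lo + 1 < width:
        raise ValueError("window narrower than motif width")

    L = max(len(s) for s in upstream_seqs)
    # candidate start indices within each (right-aligned) sequence
    enc = []
    starts_per_seq = []
    for s in upstream_seqs:
        s = s.upper()
        pad = UPSTREAM_LEN - len(s)
        arr = np.array([_BASE_INDEX.get(b, -1) for b in s])
        cand = []
        for start in range(lo, hi - width + 2):
            idx = start + UPSTREAM_LEN - pad
            if 0 <= idx <= len(s) - width and np.all(arr[idx:idx + width] >= 0):
                cand.append(idx)
        enc.append(arr)
        starts_per_seq.append(cand)

    usable = [i for i, c in enumerate(starts_per_seq) if c]
    if len(usable) < 2:
        raise ValueError("too few sequences with a scorable window")

    rng = np.random.default_rng(seed)
    best_sites: list[str] | None = None
    best_score = -np.inf
    for _ in range(max(1, restarts)):
        # init from random site picks
        f = np.full((4, width), 0.25)
        picks = {i: rng.choice(starts_per_seq[i]) for i in usable}
        counts = np.zeros((4, width))
        for i in usable:
            sub = enc[i][picks[i]:picks[i] + width]
            counts[sub, np.arange(width)] += 1
        f = (counts + pseudocount) / (len(usable) + 4 * pseudocount)

        for _ in range(n_iter):
            counts = np.zeros((4, width))
            logf = np.log(f) - np.log(0.25)
            for i in usable:
                scores = np.array([
                    logf[enc[i][p:p + width], np.arange(width)].sum()
                    for p in starts_per_seq[i]])
                w = np.exp(scores - scores.max())
                w /= w.sum()
                for p, wt in zip(starts_per_seq[i], w):
                    sub = enc[i][p:p + width]
                    counts[sub, np.arange(width)] += wt
            newf = (counts + pseudocount) / (len(usable) + 4 * pseudocount)
            if np.abs(newf - f).max() < 1e-6:
                f = newf
                break
            f = newf

        # hard assignment and total information
        sites = []
        logf = np.log(f) - np.log(0.25)
        for i in usable:
            scores = [logf[enc[i][p:p + width], np.arange(width)].sum()
                      for p in starts_per_seq[i]]
            p = starts_per_seq[i][int(np.argmax(scores))]
            sites.append("".join(BASES[b] for b in enc[i][p:p + width]))
        pwm, _ = build_pwm(sites, element, pseudocount)
        score = pwm.expected_information()
        if score > best_score:
            best_score, best_sites = score, sites
    return best_sites


def at_profile(genome: GenomeSequence, anchors: list[tuple[int, str]],
               flank: int = 300) -> np.ndarray:
    """AT fraction at each offset in [-flank, +flank] around anchors.

    Anchors are (position, strand) pairs (e.g. the 3' ends of -10
    elements); offsets run along the transcription direction. N bases
    and positions beyond a linear contig edge are excluded from the
    denominator.
    """
    at = np.zeros(2 * flank + 1)
    n = np.zeros(2 * flank + 1)
    L = genome.length
    circular = genome.topology == "circular"
    seq = genome.sequence
    for pos, strand in anchors:
        for k, off in enumerate(range(-flank, flank + 1)):
            p = pos + off if strand == "+" else pos - off
            if circular:
                p %= L
            elif not 0 <= p < L:
                continue
            b = seq[p]
            if b == "N":
                continue
            n[k] += 1
            if b in "AT":
                at[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, at / n, np.nan)
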