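"""Genome-organization statistics.

Intergenic gaps, promoter-containing intergenic regions (PIRs), 5'UTR
lengths and their Short/Common grouping, suboperons and alternative
start sites, antisense classification, and the spatial classification
of transcription-factor binding sites.

A PIR is an intergenic interval (between adjacent gene bodies, genes
merged across strands) that harbors at least one experimentally mapped
TSS; it is the unit on which TF-site statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import GeneFeature, GenomeSequence, TFSite, TSSRecord, TranscriptionUnit

logger = logging.getLogger(__name__)

__all__ = [
    "PIR",
    "UTRRecord",
    "intergenic_gaps",
    "intergenic_intervals",
    "extract_pirs",
    "utr_lengths",
    "detect_suboperons",
    "classify_antisense",
    "map_tf_sites",
    "utr_group",
]

SHORT_UTR = (11, 17)
COMMON_UTR = (26, 32)


@dataclass
class PIR:
    start: int
    end: int
    tss_records: list[TSSRecord] = field(default_factory=list)
    upstream_gene: str = ""
    downstream_gene: str = ""
    tf_site_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UTRRecord:
    tu_id: str
    utr5_length: int
    group: str  # Short / Common / Other
    valid: bool = True


def utr_group(length: int) -> str:
    if SHORT_UTR[0] <= length <= SHORT_UTR[1]:
        return "Short"
    if COMMON_UTR[0] <= length <= COMMON_UTR[1]:
        return "Common"
    return "Other"


def _sorted_features(features: list[GeneFeature]) -> list[GeneFeature]:
    if any(features[i].start > features[i + 1].start for i in range(len(features) - 1)):
        logger.warning("features not sorted by start; sorting")
        return sorted(features, key=lambda f: (f.start, f.end))
    return features


def intergenic_gaps(features: list[GeneFeature],
                    genome: GenomeSequence) -> list[int]:
    """Signed gap between each adjacent gene pair along the chromosome.

    Strand is ignored; overlapping genes give negative gaps, which are
    retained. Circular genomes include the wrap-around (last, first) pair.
    """
    if len(features) < 2:
        raise ValueError("need at least two features")
    feats = _sorted_features(features)
    gaps = [feats[i + 1].start - feats[i].end for i in range(len(feats) - 1)]
    if genome.topology == "circular":
        gaps.append(feats[0].start + genome.length - feats[-1].end)
    return gaps


def intergenic_intervals(features: list[GeneFeature],
                         genome: GenomeSequence) -> list[tuple[int, int, str, str]]:
    """Intervals of the genome covered by no gene body.

    Overlapping genes are merged irrespective of strand. Returns
    (start, end, upstream_gene_id, downstream_gene_id) tuples; on a
    circular genome the wrap-around interval is reported with
    end > genome length (coordinates taken modulo length by consumers).
    """
    feats = _sorted_features(features)
    # merged blocks: [start, end, first_gene_id, last_gene_id]
    merged: list[list] = []
    for f in feats:
        if merged and f.start < merged[-1][1]:
            if f.end > merged[-1][1]:
                merged[-1][1] = f.end
                merged[-1][3] = f.feature_id
        else:
            merged.append([f.start, f.end, f.feature_id, f.feature_id])
    out = []
    for i in range(len(merged) - 1):
        s, e = merged[i][1], merged[i + 1][0]
        if e > s:
            out.append((s, e, merged[i][3], merged[i + 1][2]))
    if genome.topology == "circular" and merged:
        s = merged[-1][1]
        e = merged[0][0] + genome.length
        if e > s:
            out.append((s, e, merged[-1][3], merged[0][2]))
    return out


def extract_pirs(features: list[GeneFeature], tss_list: list[TSSRecord],
                 tf_sites: list[TFSite], genome: GenomeSequence) -> list[PIR]:
    """Intergenic intervals containing at least one TSS.

    TSSs falling inside a gene body are ignored for PIR construction
    (logged). A TF site is counted for a PIR when its midpoint lies
    inside the interval.
    """
    intervals = intergenic_intervals(features, genome)
    n = genome.length

    def contains(s: int, e: int, pos: int) -> bool:
        if s <= pos < e:
            return True
        # wrap-around interval: e may exceed genome length
        return e > n and s <= pos + n < e

    in_gene = _GenicIndex(features)
    skipped = sum(1 for t in tss_list if in_gene(t.position))
    if skipped:
        logger.info("%d TSSs inside gene bodies ignored for PIR construction", skipped)

    pirs = []
    for (s, e, up, down) in intervals:
        inside = [t for t in tss_list
                  if not in_gene(t.position) and contains(s, e, t.position)]
        if not inside:
            continue
        count = sum(1 for site in tf_sites if contains(s, e, site.midpoint))
        pirs.append(PIR(start=s, end=e, tss_records=inside,
                        upstream_gene=up, downstream_gene=down,
                        tf_site_count=count))
    return pirs


class _GenicIndex:
    """Membership test: does a position fall inside any gene body?"""

    def __init__(self, features: list[GeneFeature]):
        merged: list[list[int]] = []
        for s, e in sorted((f.start, f.end) for f in features):
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._starts = [s for s, _ in merged]
        self._ends = [e for _, e in merged]

    def __call__(self, pos: int) -> bool:
        import bisect
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and self._ends[i] > pos


def utr_lengths(tus: list[TranscriptionUnit],
                features: list[GeneFeature]) -> list[UTRRecord]:
    """5'UTR length for every TU with a TSS and a CDS first feature.

    The length is the number of transcribed nucleotides preceding the
    first base of the first CDS (0 = leaderless). TUs whose first
    feature is a functional RNA are omitted; negative lengths (TSS
    downstream of the start codon) are flagged invalid.
    """
    by_id = {f.feature_id: f for f in features}
    out = []
    for tu in tus:
        if tu.tss is None or not tu.gene_ids:
            continue
        first = by_id.get(tu.gene_ids[0])
        if first is None or first.kind == "functional_RNA":
            continue
        if tu.strand == "+":
            length = first.start - tu.tss.position
        else:
            length = tu.tss.position - (first.end - 1)
        valid = length >= 0
        out.append(UTRRecord(tu_id=tu.tu_id, utr5_length=length,
                             group=utr_group(length) if valid else "Other",
                             valid=valid))
    return out


def detect_suboperons(tus: list[TranscriptionUnit]) -> dict:
    """Suboperonic TUs and alternative-TSS groups.

    A TU is suboperonic iff its initiation site lies strictly inside
    another same-strand TU's span. TUs with identical ordered gene sets
    but distinct TSS positions form alternative-TSS groups.
    """
    sub = set()
    for tu in tus:
        pos = tu.initiation_site()
        for other in tus:
            if other is tu or other.strand != tu.strand:
                continue
            if other.start < pos < other.end:
                sub.add(tu.tu_id)
                break
    groups: dict[tuple, list[TranscriptionUnit]] = {}
    for tu in tus:
        if tu.tss is None:
            continue
        groups.setdefault((tu.strand, tuple(tu.gene_ids)), []).append(tu)
    alt = [
        sorted(g.tu_id for g in grp)
        for grp in groups.values()
        if len({g.tss.position for g in grp}) >= 2
    ]
    return {"suboperonic": sorted(sub), "alternative_tss_groups": sorted(alt)}


def classify_antisense(tus: list[TranscriptionUnit],
                       features: list[GeneFeature]) -> dict[str, str]:
    """Per-gene antisense status.

    A gene is antisense-covered iff >= 1 nt of an opposite-strand TU
    overlaps it. The source is '3utr' when every overlapping portion
    lies downstream of the opposite TU's last CDS (a 3'UTR overhang),
    else 'internal'.
    """
    by_id = {f.feature_id: f for f in features}
    out: dict[str, str] = {}
    for gene in features:
        flags = []  # is_3utr per overlapping opposite-strand TU
        for tu in tus:
            if tu.strand == gene.strand:
                continue
            ov_s, ov_e = max(gene.start, tu.start), min(gene.end, tu.end)
            if ov_e <= ov_s:
                continue
            cds = [by_id[g] for g in tu.gene_ids
                   if g in by_id and by_id[g].kind == "CDS"]
            if cds:
                if tu.strand == "+":  # downstream of the 3'-most CDS end
                    is_3utr = ov_s >= max(m.end for m in cds)
                else:
                    is_3utr = ov_e <= min(m.start for m in cds)
            else:
                is_3utr = False
            flags.append(is_3utr)
        if flags:
            out[gene.feature_id] = "3utr" if all(flags) else "internal"
    return out


def map_tf_sites(tf_sites: list[TFSite], pirs: list[PIR],
                 features: list[GeneFeature],
                 genome: GenomeSequence) -> dict[str, str]:
    """Assign each TF site one spatial class by its midpoint.

    Classes: 'within_pir', 'intergenic_non_promoter', 'genic'.
    Precedence PIR > intergenic > genic, so class counts always sum to
    the number of input sites.
    """
    n = genome.length
    in_gene = _GenicIndex(features)
    out = {}
    for site in tf_sites:
        mid = site.midpoint
        if not (0 <= site.start and site.end <= n):
            raise ValueError(f"site {site.site_id} outside genome")
        in_pir = any(
            p.start <= mid < p.end or (p.end > n and p.start <= mid + n < p.end)
            for p in pirs
        )
        if in_pir:
            out[site.site_id] = "within_pir"
        elif not in_gene(mid):
            out[site.site_id] = "intergenic_non_promoter"
        else:
            out[site.site_id] = "genic"
    return out
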