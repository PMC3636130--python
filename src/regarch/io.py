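"""Readers and writers for the standard genomic formats.

Everything downstream of this module works in a single coordinate
convention: 0-based, half-open intervals on the forward strand of the
reference. GFF3 (1-based, closed) and BED (0-based, half-open) are
converted here and only here. TSS positions mark the first transcribed
base (0-based).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "GeneFeature",
    "TSSRecord",
    "TranscriptionUnit",
    "TFSite",
    "DistanceMatrix",
    "read_genome",
    "write_genome",
    "read_features",
    "write_features",
    "read_bed",
    "write_bed",
    "read_table",
    "write_tss_table",
    "write_tu_table",
]

_VALID_BASES = frozenset("ACGTN")

# GFF3 feature types mapped onto the two internal kinds
_FUNCTIONAL_RNA_TYPES = {
    "tRNA", "rRNA", "ncRNA", "tmRNA", "SRP_RNA", "RNase_P_RNA",
    "riboswitch", "functional_RNA", "misc_RNA",
}


@dataclass
class GenomeSequence:
    """A chromosome or contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str
    topology: str = "circular"  # bacterial default

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise ValueError(
                f"alphabet error: non-IUPAC character {self.sequence[pos]!r} "
                f"at position {pos} in {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps around the origin when circular."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if self.topology == "circular":
            return "".join(self.sequence[i % n] for i in range(start, end))
        raise IndexError(f"[{start},{end}) outside linear genome of length {n}")


@dataclass
class GeneFeature:
    feature_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"  # or "functional_RNA"
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval [{self.start},{self.end}) for {self.feature_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand error: {self.strand!r} for {self.feature_id}")
        if self.kind not in ("CDS", "functional_RNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """0-based position of the first base in transcription direction."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TSSRecord:
    position: int
    strand: str
    read_count: int = 0
    replicate_support: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if self.strand not in "+-":
            raise ValueError(f"strand error: {self.strand!r}")


@dataclass
class TranscriptionUnit:
    tu_id: str
    start: int
    end: int
    strand: str
    gene_ids: list[str] = field(default_factory=list)
    tss: TSSRecord | None = None
    terminator_end: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval for TU {self.tu_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand error: {self.strand!r}")

    def initiation_site(self) -> int:
        if self.tss is not None:
            return self.tss.position
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TFSite:
    site_id: str
    regulator: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval for site {self.site_id}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path, topology: str = "circular") -> list[GenomeSequence]:
    """Read a FASTA file; lowercase is uppercased and U is mapped to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        out.append(GenomeSequence(id=rec.id, sequence=seq, topology=topology))
    return out


def write_genome(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / tabular features

_GFF_COLS = ["seqid", "source", "type", "start", "end",
             "score", "strand", "phase", "attributes"]


def read_features(path: str | Path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or a 1-based closed tabular TSV.

    Both dialects carry 1-based closed coordinates in the file; internal
    records are 0-based half-open.
    """
    if dialect == "gff3":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_GFF_COLS, dtype={"start": int, "end": int})
        feats = []
        for i, row in df.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"feature_{i}")
            kind = "functional_RNA" if row.type in _FUNCTIONAL_RNA_TYPES else "CDS"
            if row.end < row.start:
                raise ValueError(f"malformed interval in GFF3 line {i + 1}")
            feats.append(GeneFeature(
                feature_id=fid, start=int(row.start) - 1, end=int(row.end),
                strand=str(row.strand), kind=kind,
                product=attrs.get("product", ""),
            ))
        return feats
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        _require(df, ["feature_id", "start", "end", "strand", "kind"], "feature table")
        return [
            GeneFeature(feature_id=str(r.feature_id), start=int(r.start) - 1,
                        end=int(r.end), strand=str(r.strand), kind=str(r.kind),
                        product=str(getattr(r, "product", "") or ""))
            for r in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_features(features: Sequence[GeneFeature], path: str | Path,
                   seqid: str = "chr", source: str = "regarch") -> None:
    """Write features as GFF3 (1-based closed)."""
    type_map = {"CDS": "CDS", "functional_RNA": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write("\t".join([
                seqid, source, type_map[f.kind], str(f.start + 1), str(f.end),
                ".", f.strand, ".", attrs,
            ]) + "\n")


def read_bed(path: str | Path) -> list[TFSite]:
    """BED intervals (0-based half-open) as TF sites; name column = site id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    sites = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"site_{i}"
        regulator = str(row[4]) if df.shape[1] > 4 else ""
        sites.append(TFSite(site_id=name, regulator=regulator,
                            start=int(row[1]), end=int(row[2])))
    return sites


def write_bed(intervals: Iterable[tuple], path: str | Path,
              chrom: str = "chr") -> None:
    """Write (start, end, name) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            name = iv[2] if len(iv) > 2 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Typed TSV tables

_TABLE_SCHEMAS = {
    "tss": ["position", "strand", "read_count"],
    "tu": ["tu_id", "start", "end", "strand", "gene_ids"],
    "tf_site": ["site_id", "regulator", "start", "end"],
    "expression": ["feature_id", "condition", "fragment_count"],
    "spectral": ["protein_id", "condition", "spectral_count"],
    "organism": ["name", "ogt"],
}


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_table(path: str | Path, kind: str):
    """Read one of the typed TSV tables.

    kinds: tss, tu, tf_site, expression, spectral, organism,
    distance_matrix. Coordinates in these tables are already 0-based
    half-open (they are written by this package's writers).
    """
    if kind == "distance_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in df.columns]
        if list(map(str, df.index)) != labels:
            raise ValueError("distance matrix row labels differ from column labels")
        return DistanceMatrix(labels=labels, values=df.to_numpy(dtype=float))

    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t")
    _require(df, _TABLE_SCHEMAS[kind], f"{kind} table")

    if kind == "tss":
        rep = df["replicate_support"] if "replicate_support" in df.columns else None
        return [
            TSSRecord(position=int(r.position), strand=str(r.strand),
                      read_count=int(r.read_count),
                      replicate_support=int(rep.iloc[i]) if rep is not None else 1)
            for i, r in enumerate(df.itertuples(index=False))
        ]
    if kind == "tu":
        tus = []
        for r in df.itertuples(index=False):
            tss = None
            tss_pos = getattr(r, "tss_position", None)
            if tss_pos is not None and not pd.isna(tss_pos):
                tss = TSSRecord(position=int(tss_pos), strand=str(r.strand))
            raw = r.gene_ids
            genes = [] if pd.isna(raw) else \
                [g for g in str(raw).split(",") if g]
            tus.append(TranscriptionUnit(
                tu_id=str(r.tu_id), start=int(r.start), end=int(r.end),
                strand=str(r.strand), gene_ids=genes, tss=tss))
        return tus
    if kind == "tf_site":
        return [
            TFSite(site_id=str(r.site_id), regulator=str(r.regulator),
                   start=int(r.start), end=int(r.end))
            for r in df.itertuples(index=False)
        ]
    if kind == "organism":
        bad = df[(df["ogt"] < 0) | (df["ogt"] > 110)]
        if len(bad):
            raise ValueError(f"organism table: OGT outside [0,110] for {list(bad['name'])}")
        return df
    return df  # expression / spectral: plain typed DataFrames


def write_tss_table(tss_list: Sequence[TSSRecord], path: str | Path) -> None:
    pd.DataFrame({
        "position": [t.position for t in tss_list],
        "strand": [t.strand for t in tss_list],
        "read_count": [t.read_count for t in tss_list],
        "replicate_support": [t.replicate_support for t in tss_list],
    }).to_csv(path, sep="\t", index=False)


def write_tu_table(tus: Sequence[TranscriptionUnit], path: str | Path) -> None:
    pd.DataFrame({
        "tu_id": [t.tu_id for t in tus],
        "start": [t.start for t in tus],
        "end": [t.end for t in tus],
        "strand": [t.strand for t in tus],
        "gene_ids": [",".join(t.gene_ids) for t in tus],
        "tss_position": [t.tss.position if t.tss else pd.NA for t in tus],
    }).to_csv(path, sep="\t", index=False)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
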