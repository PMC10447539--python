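"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; the 1-based inclusive
conventions of GFF3 and BLAST tabular output are converted at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Interval",
    "DnaSeq",
    "LocalHit",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_tsv",
    "read_tsv",
    "write_newick",
]

_GAP_RE = re.compile(r"N+")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with strand in {+, -, .}."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class DnaSeq:
    """A nucleotide sequence with pre-computed runs of ambiguous bases (N).

    ``gap_runs`` are maximal N-runs as 0-based half-open (start, end) pairs,
    sorted and non-overlapping; they mark assembly gaps.
    """

    id: str
    residues: str
    gap_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.gap_runs:
            self.gap_runs = [m.span() for m in _GAP_RE.finditer(self.residues)]
        last = 0
        for s, e in self.gap_runs:
            if not (last <= s < e <= len(self.residues)):
                raise ValueError(f"gap run ({s}, {e}) invalid for {self.id}")
            last = e

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def subseq(self, iv: Interval) -> str:
        if iv.end > len(self.residues):
            raise ValueError(f"interval {iv} outside sequence {self.id}")
        s = self.residues[iv.start : iv.end]
        return revcomp(s) if iv.strand == "-" else s


_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocalHit:
    """One local-similarity hit between a query and a subject sequence."""

    query_id: str
    subject_id: str
    query_interval: Interval
    subject_interval: Interval
    identity: float
    aligned_length: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, DnaSeq]:
    """Read a FASTA file into an ordered mapping of id -> DnaSeq.

    Residues are upper-cased and gap runs (maximal N-runs) computed.
    Duplicate IDs and empty files are hard errors.
    """
    records: dict[str, DnaSeq] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = DnaSeq(id=rec.id, residues=str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Mapping[str, DnaSeq] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    if isinstance(seqs, Mapping):
        items = [(s.id, s.residues) for s in seqs.values()]
    else:
        items = list(seqs)
    with open(path, "w") as fh:
        for name, residues in items:
            fh.write(f">{name}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6 dialect)

_HIT_COLS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> list[LocalHit]:
    """Read a 12-column tabular hit file (BLAST outfmt-6 dialect).

    Input coordinates are 1-based inclusive; sstart > send encodes a
    minus-strand subject interval. Output hits use internal 0-based
    half-open coordinates and fractional identity.
    """
    hits: list[LocalHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                bit = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if sstart > send:
                s_iv = Interval(s, send - 1, sstart, "-")
            else:
                s_iv = Interval(s, sstart - 1, send, "+")
            hits.append(
                LocalHit(
                    query_id=q,
                    subject_id=s,
                    query_interval=Interval(q, qstart - 1, qend, "+"),
                    subject_interval=s_iv,
                    identity=pident / 100.0,
                    aligned_length=length,
                    score=bit,
                )
            )
    return hits


def write_hit_table(hits: Iterable[LocalHit], path: str | Path) -> None:
    """Write hits back to the 12-column 1-based tabular dialect."""
    with open(path, "w") as fh:
        for h in hits:
            qi, si = h.query_interval, h.subject_interval
            if si.strand == "-":
                sstart, send = si.end, si.start + 1
            else:
                sstart, send = si.start + 1, si.end
            mism = round(h.aligned_length * (1 - h.identity))
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.identity * 100:.2f}",
                        str(h.aligned_length), str(mism), "0",
                        str(qi.start + 1), str(qi.end),
                        str(sstart), str(send), "0.0", f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED


@dataclass(frozen=True)
class Feature:
    """A generic annotated interval (GFF3/BED record)."""

    interval: Interval
    feature_id: str
    feature_type: str = "region"
    attributes: dict | None = None
    score: float | None = None


def write_gff3(features: Sequence[Feature], path: str | Path,
               seq_lengths: Mapping[str, int] | None = None,
               source: str = "paleoploid") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            if seq_lengths is not None:
                n = seq_lengths.get(iv.seq_id)
                if n is None or iv.end > n:
                    raise ValueError(f"interval {iv} outside sequence bounds")
            attrs = {"ID": f.feature_id, **(f.attributes or {})}
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            score = "." if f.score is None else f"{f.score:g}"
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                "\t".join(
                    [iv.seq_id, source, f.feature_type, str(iv.start + 1),
                     str(iv.end), score, strand, ".", attr_s]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.pop("ID", "")
            feats.append(
                Feature(
                    interval=Interval(cols[0], int(cols[3]) - 1, int(cols[4]),
                                      cols[6] if cols[6] in "+-" else "."),
                    feature_id=fid,
                    feature_type=cols[2],
                    attributes=attrs or None,
                    score=None if cols[5] == "." else float(cols[5]),
                )
            )
    return feats


def write_bed(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            score = 0 if f.score is None else f.score
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{f.feature_id}"
                f"\t{score:g}\t{iv.strand if iv.strand != '.' else '.'}\n"
            )


def read_bed(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[3] if len(cols) > 3 else ""
            score = float(cols[4]) if len(cols) > 4 else None
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            feats.append(
                Feature(
                    interval=Interval(cols[0], int(cols[1]), int(cols[2]), strand),
                    feature_id=name,
                    feature_type="region",
                    score=score,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# TSV / Newick


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_newick(tree, path: str | Path) -> None:
    """Write a Bio.Phylo tree (or anything with .format('newick')) as Newick."""
    from Bio import Phylo

    Phylo.write(tree, str(path), "newick")
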