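"""Readers and writers for the annotation formats the pipeline consumes.

All coordinates are 1-based inclusive throughout (the InterProScan / GFF3
convention) and are never converted.  Writers mirror readers exactly, so a
parsed table written back and re-parsed yields an equal in-memory
representation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_IPR_RE = re.compile(r"IPR\d{6}")

__all__ = [
    "DomainHit",
    "TopologyCall",
    "GeneLocus",
    "HitRecord",
    "MappingTables",
    "parse_interproscan_tsv",
    "write_interproscan_tsv",
    "parse_topology_tsv",
    "write_topology_tsv",
    "parse_gff3_loci",
    "write_gff3_loci",
    "parse_blast_tab",
    "write_blast_tab",
    "read_mapping_tsv",
    "write_mapping_tsv",
    "load_mapping_tables",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True, slots=True)
class DomainHit:
    """One annotated domain interval on a protein (one InterProScan TSV row)."""

    protein_id: str
    analysis: str
    signature_acc: str
    signature_desc: str
    start: int
    end: int
    seq_length: int
    score: float | None = None
    interpro_acc: str | None = None
    interpro_desc: str | None = None
    md5: str = "-"
    status: str = "T"
    date: str = "-"
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("DomainHit requires a non-empty protein_id")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid interval {self.start}-{self.end}"
            )
        if self.interpro_acc is not None and not _IPR_RE.fullmatch(self.interpro_acc):
            raise ValueError(
                f"{self.protein_id}: malformed InterPro accession {self.interpro_acc!r}"
            )

    @property
    def key(self) -> str:
        """Accession key: the InterPro accession, or ``analysis:signature``."""
        if self.interpro_acc is not None:
            return self.interpro_acc
        return f"{self.analysis}:{self.signature_acc}"


@dataclass(frozen=True, slots=True)
class TopologyCall:
    """Signal-peptide and transmembrane topology of one protein."""

    protein_id: str
    length: int
    has_signal_peptide: bool
    sp_end: int | None = None
    tm_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: non-positive length")
        prev_end = 0
        for s, e in self.tm_segments:
            if not (1 <= s <= e <= self.length):
                raise ValueError(
                    f"{self.protein_id}: TM segment {s}-{e} outside [1, {self.length}]"
                )
            if s <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: TM segments overlap or are unsorted"
                )
            prev_end = e
        if (
            self.has_signal_peptide
            and self.sp_end is not None
            and self.tm_segments
            and self.sp_end >= self.tm_segments[0][0]
        ):
            raise ValueError(
                f"{self.protein_id}: signal peptide extends into first TM segment"
            )


@dataclass(frozen=True, slots=True)
class GeneLocus:
    """A gene's genomic placement, with a per-scaffold ordinal rank."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One 12-column tabular homology hit (BLAST outfmt-6 semantics)."""

    query_id: str
    subject_id: str
    subject_taxon: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    extra: tuple[str, ...] = ()  # mismatches, gap opens, q/s coordinates — opaque

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")
        if self.bitscore < 0:
            raise ValueError(f"{self.query_id}: negative bitscore")


@dataclass
class MappingTables:
    """Partial gene-level mapping tables from external annotation sources."""

    kegg_ko: dict[str, str] = field(default_factory=dict)
    eggnog_og: dict[str, str] = field(default_factory=dict)
    orthomcl_og: dict[str, str] = field(default_factory=dict)
    swissprot_best: dict[str, str] = field(default_factory=dict)
    panther_family: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# InterProScan 5 TSV
# ---------------------------------------------------------------------------

def parse_interproscan_tsv(path: str | Path) -> list[DomainHit]:
    """Parse an InterProScan 5 TSV file into :class:`DomainHit` records.

    Rows carry 11-15 tab-separated columns; the InterPro accession column
    uses ``-`` as its absent placeholder.  An empty file yields an empty
    list; a malformed row rejects the whole file, naming the row.
    """
    hits: list[DomainHit] = []
    for lineno, row in _read_rows(path):
        if not 11 <= len(row) <= 15:
            raise ValueError(f"{path}: row {lineno}: expected 11-15 columns, got {len(row)}")
        try:
            start, end = int(row[6]), int(row[7])
            seq_length = int(row[2])
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: non-integer coordinate") from exc
        score = None if row[8] in {"-", ""} else float(row[8])
        ipr = row[11] if len(row) > 11 and row[11] != "-" else None
        ipr_desc = row[12] if len(row) > 12 and row[12] != "-" else None
        try:
            hits.append(
                DomainHit(
                    protein_id=row[0],
                    md5=row[1],
                    seq_length=seq_length,
                    analysis=row[3],
                    signature_acc=row[4],
                    signature_desc=row[5],
                    start=start,
                    end=end,
                    score=score,
                    status=row[9],
                    date=row[10],
                    interpro_acc=ipr,
                    interpro_desc=ipr_desc,
                    extra=tuple(row[13:]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def write_interproscan_tsv(path: str | Path, hits: Iterable[DomainHit]) -> None:
    lines = []
    for h in hits:
        row = [
            h.protein_id,
            h.md5,
            str(h.seq_length),
            h.analysis,
            h.signature_acc,
            h.signature_desc,
            str(h.start),
            str(h.end),
            "-" if h.score is None else _fmt_float(h.score),
            h.status,
            h.date,
            h.interpro_acc or "-",
            h.interpro_desc or "-",
            *h.extra,
        ]
        lines.append("\t".join(row))
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# topology TSV (Phobius-like semantics)
# ---------------------------------------------------------------------------

def parse_topology_tsv(path: str | Path) -> list[TopologyCall]:
    """Parse a topology TSV: protein_id, length, SP flag (Y/N), SP cleavage
    position (``-`` if none), and semicolon-delimited ``start-end`` TM
    intervals (empty field for no TM)."""
    calls: list[TopologyCall] = []
    for lineno, row in _read_rows(path):
        if len(row) != 5:
            raise ValueError(f"{path}: row {lineno}: expected 5 columns, got {len(row)}")
        pid, length_s, sp_flag, sp_end_s, tm_field = row
        try:
            length = int(length_s)
            sp_end = None if sp_end_s == "-" else int(sp_end_s)
            tm = tuple(
                (int(seg.split("-")[0]), int(seg.split("-")[1]))
                for seg in tm_field.split(";")
                if seg
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: row {lineno}: malformed field") from exc
        try:
            calls.append(
                TopologyCall(
                    protein_id=pid,
                    length=length,
                    has_signal_peptide=sp_flag == "Y",
                    sp_end=sp_end,
                    tm_segments=tm,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return calls


def write_topology_tsv(path: str | Path, calls: Iterable[TopologyCall]) -> None:
    lines = []
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.protein_id,
                    str(c.length),
                    "Y" if c.has_signal_peptide else "N",
                    "-" if c.sp_end is None else str(c.sp_end),
                    ";".join(f"{s}-{e}" for s, e in c.tm_segments),
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# GFF3 gene loci
# ---------------------------------------------------------------------------

def parse_gff3_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene features from GFF3 and assign per-scaffold ordinals.

    Ordinals rank genes along each scaffold by ascending start (ties broken
    by end, then gene id), so the result is stable under row permutation.
    Duplicate gene ids reject the file.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate IDs
        raise ValueError(f"{path}: {exc}") from exc
    raw = [
        (f.seqid, f.start, f.end, f.strand or ".", f.id)
        for f in db.features_of_type("gene")
    ]
    seen: set[str] = set()
    for *_, gid in raw:
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene id {gid}")
        seen.add(gid)
    loci: list[GeneLocus] = []
    by_scaffold: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for rec in raw:
        by_scaffold.setdefault(rec[0], []).append(rec)
    for scaffold in sorted(by_scaffold):
        ranked = sorted(by_scaffold[scaffold], key=lambda r: (r[1], r[2], r[4]))
        for ordinal, (seqid, start, end, strand, gid) in enumerate(ranked):
            loci.append(
                GeneLocus(
                    gene_id=gid,
                    scaffold=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    ordinal=ordinal,
                )
            )
    return loci


def write_gff3_loci(path: str | Path, loci: Iterable[GeneLocus]) -> None:
    lines = ["##gff-version 3"]
    for l in loci:
        lines.append(
            "\t".join(
                [
                    l.scaffold,
                    "placorep",
                    "gene",
                    str(l.start),
                    str(l.end),
                    ".",
                    l.strand,
                    ".",
                    f"ID={l.gene_id}",
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# tabular homology hits
# ---------------------------------------------------------------------------

def _taxon_pipe(subject_id: str) -> str:
    return subject_id.split("|", 1)[0]


def _taxon_underscore(subject_id: str) -> str:
    return subject_id.split("_", 1)[0]


TAXON_RULES: dict[str, Callable[[str], str]] = {
    "pipe": _taxon_pipe,
    "underscore": _taxon_underscore,
}


def parse_blast_tab(
    path: str | Path, taxon_rule: str | Callable[[str], str] = "pipe"
) -> list[HitRecord]:
    """Parse 12-column tabular homology hits (outfmt-6 semantics).

    ``taxon_rule`` extracts the subject taxon from the subject identifier:
    ``"pipe"`` takes the token before ``|`` (the generator's convention),
    ``"underscore"`` the token before ``_``; a callable may be supplied for
    foreign conventions.
    """
    rule = TAXON_RULES[taxon_rule] if isinstance(taxon_rule, str) else taxon_rule
    records: list[HitRecord] = []
    for lineno, row in _read_rows(path):
        if len(row) != 12:
            raise ValueError(f"{path}: row {lineno}: expected 12 columns, got {len(row)}")
        try:
            records.append(
                HitRecord(
                    query_id=row[0],
                    subject_id=row[1],
                    subject_taxon=rule(row[1]),
                    percent_identity=float(row[2]),
                    align_length=int(row[3]),
                    extra=tuple(row[4:10]),
                    evalue=float(row[10]),
                    bitscore=float(row[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return records


def write_blast_tab(path: str | Path, records: Iterable[HitRecord]) -> None:
    lines = []
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.query_id,
                    r.subject_id,
                    _fmt_float(r.percent_identity),
                    str(r.align_length),
                    *r.extra,
                    _fmt_float(r.evalue),
                    _fmt_float(r.bitscore),
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# plain mapping TSVs and FASTA
# ---------------------------------------------------------------------------

def read_mapping_tsv(path: str | Path) -> dict[str, str]:
    """Two-column gene_id -> value TSV; later rows override earlier ones."""
    mapping: dict[str, str] = {}
    for lineno, row in _read_rows(path):
        if len(row) != 2:
            raise ValueError(f"{path}: row {lineno}: expected 2 columns, got {len(row)}")
        mapping[row[0]] = row[1]
    return mapping


def write_mapping_tsv(path: str | Path, mapping: Mapping[str, str]) -> None:
    lines = [f"{k}\t{mapping[k]}" for k in sorted(mapping)]
    Path(path).write_text("".join(line + "\n" for line in lines))


_MAPPING_FILES = {
    "kegg_ko": "kegg_ko.tsv",
    "eggnog_og": "eggnog.tsv",
    "orthomcl_og": "orthomcl.tsv",
    "swissprot_best": "swissprot.tsv",
    "panther_family": "panther.tsv",
}


def load_mapping_tables(directory: str | Path) -> MappingTables:
    """Load whichever of the five mapping tables exist under ``directory``."""
    directory = Path(directory)
    kwargs = {}
    for attr, fname in _MAPPING_FILES.items():
        p = directory / fname
        kwargs[attr] = read_mapping_tsv(p) if p.exists() else {}
    return MappingTables(**kwargs)


def write_mapping_tables(directory: str | Path, tables: MappingTables) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _MAPPING_FILES.items():
        write_mapping_tsv(directory / fname, getattr(tables, attr))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by full record id (insertion order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------

def _read_rows(path: str | Path):
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _fmt_float(x: float) -> str:
    return f"{x:g}"
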