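"""Sequence and gene-model I/O and the shared coordinate conventions.

All coordinates are 0-based half-open in memory and 1-based inclusive on
disk; the conversion happens only here, at the I/O boundary.  Sequences are
upper-cased on read and, for nucleotide sets, U is mapped to T.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_CHARS = set("ACGTN")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY*X")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SeqIOError(ValueError):
    """Malformed sequence or gene-model input."""


@dataclass
class SequenceSet:
    """An ordered id -> sequence mapping with a declared alphabet."""

    records: dict[str, str]
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        allowed = _NT_CHARS if self.alphabet == NUCLEOTIDE else _AA_CHARS
        for rid, seq in self.records.items():
            if not seq:
                raise SeqIOError(f"empty sequence for id {rid!r}")
            bad = set(seq) - allowed
            if bad:
                pos = min(i for i, c in enumerate(seq) if c in bad)
                raise SeqIOError(
                    f"illegal {self.alphabet} character {seq[pos]!r} "
                    f"in {rid!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        return self.records[rid]

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()


@dataclass
class GeneModel:
    """A gene with exon structure and its coding sequence.

    ``start``/``end`` and the exon intervals are 0-based half-open on the
    forward genomic strand; exons are stored sorted 5'->3' on the coding
    strand (i.e. descending genomic order for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str = ""

    start: int = field(init=False)
    end: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SeqIOError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise SeqIOError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise SeqIOError(f"{self.gene_id}: empty exon ({s},{e})")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise SeqIOError(f"{self.gene_id}: overlapping exons")
        # canonical order: 5'->3' on the coding strand
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        self.start = genomic[0][0]
        self.end = genomic[-1][1]
        if self.cds_seq:
            total = sum(e - s for s, e in self.exons)
            if total != len(self.cds_seq):
                raise SeqIOError(
                    f"{self.gene_id}: exon span {total} != CDS length "
                    f"{len(self.cds_seq)}"
                )
            if len(self.cds_seq) % 3:
                raise SeqIOError(
                    f"{self.gene_id}: CDS length {len(self.cds_seq)} "
                    "not divisible by 3"
                )

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (order preserved)."""
    records: dict[str, str] = {}
    rid = None
    chunks: list[str] = []

    def _flush() -> None:
        if rid is None:
            return
        seq = "".join(chunks).upper()
        if alphabet == NUCLEOTIDE:
            seq = seq.replace("U", "T")
        records[rid] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                rid = line[1:].split()[0]
                if rid in records:
                    raise SeqIOError(f"duplicate FASTA id {rid!r}")
                chunks = []
            else:
                if rid is None:
                    raise SeqIOError("sequence data before first header")
                chunks.append(line)
        _flush()
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return SequenceSet(records, alphabet)


def write_fasta(seqs: SequenceSet | dict[str, str], path: str | Path,
                width: int = 70) -> None:
    records = seqs.records if isinstance(seqs, SequenceSet) else seqs
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene-model exon table (GFF-lite)
#
# TSV columns: gene_id, chrom, strand, exon_start, exon_end — one row per
# exon, coordinates 1-based inclusive on disk.

def read_gene_models(path: str | Path,
                     cds: SequenceSet | None = None) -> list[GeneModel]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                expected = ["gene_id", "chrom", "strand", "exon_start", "exon_end"]
                if parts != expected:
                    raise SeqIOError(
                        f"bad gene-model header {parts!r}; expected {expected!r}")
                continue
            gid, chrom, strand, s, e = parts
            start1, end1 = int(s), int(e)
            if start1 < 1 or end1 < start1:
                raise SeqIOError(f"{gid}: bad disk coordinates {start1}..{end1}")
            entry = rows.setdefault(gid, {"chrom": chrom, "strand": strand,
                                          "exons": []})
            entry["exons"].append((start1 - 1, end1))  # to 0-based half-open
    models = []
    for gid, entry in rows.items():
        seq = cds[gid] if cds is not None and gid in cds else ""
        models.append(GeneModel(gid, entry["chrom"], entry["strand"],
                                entry["exons"], seq))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texon_start\texon_end\n")
        for m in models:
            for s, e in sorted(m.exons):
                fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{s + 1}\t{e}\n")


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree with branch lengths and integer support labels."""
    out = tree.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
    Path(path).write_text(out)


def read_newick(path: str | Path,
                taxon_namespace: dendropy.TaxonNamespace | None = None
                ) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True,
                             taxon_namespace=taxon_namespace)


def newick_string(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return buf.getvalue().strip()
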