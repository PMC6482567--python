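"""Promoter extraction and IUPAC cis-element scanning.

Promoters are the 2000 bp immediately upstream of the translation start on
the coding strand (reverse-complemented for minus-strand genes; truncated
with a flag at contig edges).  Elements are matched as exact IUPAC
consensus strings on both strands; a palindromic consensus matching both
strands at the same coordinates is counted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import GeneModel, SequenceSet, reverse_complement, NUCLEOTIDE

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

DEFAULT_WINDOW = 2000


class PromoterError(ValueError):
    pass


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element: str
    category: str
    subcategory: str
    position: int    # 0-based offset of the match start in the promoter
    end: int         # half-open end offset
    strand: str


@dataclass
class ElementDictionary:
    """element -> (IUPAC consensus, category, subcategory)."""

    entries: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for name, (iupac, cat, sub) in self.entries.items():
            bad = set(iupac) - set(IUPAC)
            if bad:
                raise PromoterError(
                    f"element {name!r}: non-IUPAC characters {sorted(bad)}")
            if not cat or not sub:
                raise PromoterError(f"element {name!r}: missing category")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElementDictionary":
        entries = {}
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    continue
                name, iupac, cat, sub = parts
                if name in entries:
                    raise PromoterError(f"duplicate element {name!r}")
                entries[name] = (iupac.upper(), cat, sub)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("element\tiupac\tcategory\tsubcategory\n")
            for name, (iupac, cat, sub) in self.entries.items():
                fh.write(f"{name}\t{iupac}\t{cat}\t{sub}\n")

    @classmethod
    def packaged(cls) -> "ElementDictionary":
        """The element dictionary shipped with the package."""
        ref = resources.files("famevol") / "data" / "cis_elements.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def extract_promoters(genes: list[GeneModel], genome: dict[str, str],
                      window: int = DEFAULT_WINDOW) -> SequenceSet:
    """Upstream promoter windows on the coding strand for each gene."""
    out: dict[str, str] = {}
    for g in genes:
        contig = genome.get(g.chrom)
        if contig is None:
            raise PromoterError(f"{g.gene_id}: contig {g.chrom!r} not found")
        if g.strand == "+":
            start = max(0, g.start - window)
            prom = contig[start:g.start]
        else:
            end = min(len(contig), g.end + window)
            prom = reverse_complement(contig[g.end:end])
        if len(prom) < window:
            warnings.warn(f"{g.gene_id}: promoter truncated to {len(prom)} bp "
                          "at contig edge")
        if not prom:
            raise PromoterError(f"{g.gene_id}: empty promoter window")
        out[g.gene_id] = prom.upper()
    return SequenceSet(out, NUCLEOTIDE)


def _iupac_match(seq: str, start: int, consensus: str) -> bool:
    for i, c in enumerate(consensus):
        if seq[start + i] not in IUPAC[c]:
            return False
    return True


def scan_elements(promoters: SequenceSet,
                  dictionary: ElementDictionary) -> list[CisElementHit]:
    """Every IUPAC consensus match on both strands of every promoter.

    Positions are forward-strand offsets of the match start.  For each
    element the reverse-strand scan is done on the reverse complement and
    mapped back; a self-reverse-complementary match duplicated at the same
    coordinates is kept once (forward strand).
    """
    if not promoters.records:
        raise PromoterError("no promoters")
    hits: list[CisElementHit] = []
    for gid, seq in promoters.items():
        rc = reverse_complement(seq)
        n = len(seq)
        for name, (cons, cat, sub) in dictionary.entries.items():
            m = len(cons)
            if m > n:
                continue
            fwd = {i for i in range(n - m + 1) if _iupac_match(seq, i, cons)}
            rev = {n - m - i for i in range(n - m + 1)
                   if _iupac_match(rc, i, cons)}
            for pos in sorted(fwd):
                hits.append(CisElementHit(gid, name, cat, sub, pos, pos + m, "+"))
            for pos in sorted(rev - fwd if _self_rc(cons) else rev):
                hits.append(CisElementHit(gid, name, cat, sub, pos, pos + m, "-"))
    return hits


def _self_rc(consensus: str) -> bool:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return consensus == "".join(comp[c] for c in reversed(consensus))


@dataclass
class ElementSummary:
    counts: dict[str, int]                      # per element
    category_counts: dict[str, int]
    element_share: dict[str, float]             # % within its category
    subcategory_share: dict[tuple[str, str], float]


def summarize_elements(hits: list[CisElementHit],
                       dictionary: ElementDictionary) -> ElementSummary:
    """Per-element counts and within-category percentage shares (2 dp)."""
    counts = {name: 0 for name in dictionary.entries}
    for h in hits:
        counts[h.element] += 1
    cat_of = {n: c for n, (_, c, _) in dictionary.entries.items()}
    sub_of = {n: s for n, (_, _, s) in dictionary.entries.items()}
    cat_counts: dict[str, int] = {}
    for name, c in counts.items():
        cat_counts[cat_of[name]] = cat_counts.get(cat_of[name], 0) + c
    elem_share = {}
    sub_share: dict[tuple[str, str], float] = {}
    for name, c in counts.items():
        cat = cat_of[name]
        share = 100.0 * c / cat_counts[cat] if cat_counts[cat] else 0.0
        elem_share[name] = round(share, 2)
        key = (cat, sub_of[name])
        sub_share[key] = sub_share.get(key, 0.0) + share
    sub_share = {k: round(v, 2) for k, v in sub_share.items()}
    return ElementSummary(counts, cat_counts, elem_share, sub_share)


def write_hits(hits: list[CisElementHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: gene, start, end, element, category, subcategory, strand\n")
        fh.write("gene\tstart\tend\telement\tcategory\tsubcategory\tstrand\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.position}\t{h.end}\t{h.element}\t"
                     f"{h.category}\t{h.subcategory}\t{h.strand}\n")
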