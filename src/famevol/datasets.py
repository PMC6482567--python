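"""Loaders for the published PeTTF family tables shipped with the package.

These are the printed per-gene census of the 35 Moso bamboo trihelix genes,
the Ka/Ks estimates for the 12 duplicated pairs, and the published
paralog/ortholog pair lists.  They serve as fixed inputs for the dating,
selection-summary and census-summary analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("famevol") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def pettf_gene_census() -> pd.DataFrame:
    """Per-gene statistics of the 35 PeTTF genes (ORF/protein/MW/pI/exons)."""
    return _load("pettf_gene_census.tsv")


def pettf_duplicate_pairs() -> pd.DataFrame:
    """Published Ka and Ks for the 12 duplicated PeTTF pairs."""
    return _load("pettf_duplicate_pairs.tsv")


def pettf_homolog_pairs() -> pd.DataFrame:
    """Published paralog (Pe-Pe) and ortholog (Pe-Os) pair lists."""
    return _load("pettf_homolog_pairs.tsv")


def census_rows() -> list[dict]:
    """The published census as rows for :func:`famevol.census.summarize_rows`."""
    df = pettf_gene_census()
    return [{"gene_id": r.gene, "orf_len": int(r.orf_bp),
             "aa_len": int(r.aa_len), "mw": float(r.mw_da),
             "pi": float(r.pi), "exon_count": int(r.exons)}
            for r in df.itertuples()]
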