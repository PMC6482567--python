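"""Codon-aware alignment, Nei–Gojobori Ka/Ks, dating, and selection reports.

The estimator is the classical counting method: per-codon synonymous and
nonsynonymous site fractions under the standard genetic code, observed
differences averaged with equal weight over all minimal mutational pathways
(pathways crossing a stop codon are excluded), and a Jukes–Cantor multiple-
hit correction d = -(3/4)·ln(1 - (4/3)p).  Duplication age follows the
synonymous molecular clock T = Ks / (2λ) with λ = 6.5e-9 synonymous
substitutions per site per year by default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .census import GENETIC_CODE, STOP_CODONS, translate_orf

LAMBDA_SYN_PER_YEAR = 6.5e-9
GAP_CODON = "---"
_NTS = "ACGT"


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon-aware alignment (protein-guided)

@dataclass
class CodonAlignment:
    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise SelectionError("rows differ in codon-column count")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in zip(self.codons_a, self.codons_b)
                if a != GAP_CODON and b != GAP_CODON
                and set(a + b) <= set(_NTS)]


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    return al


def codon_align(id_a: str, cds_a: str, id_b: str, cds_b: str) -> CodonAlignment:
    """Global protein alignment back-threaded onto the source codons.

    Gaps therefore occur only as whole codons and the reading frame of both
    sequences is preserved in every column.
    """
    prot_a = translate_orf(cds_a)
    prot_b = translate_orf(cds_b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    ia, ib = aln.indices  # per-column residue index or -1 for a gap
    codons_a, codons_b = [], []
    for ca, cb in zip(ia, ib):
        codons_a.append(GAP_CODON if ca < 0 else cds_a[3 * ca: 3 * ca + 3])
        codons_b.append(GAP_CODON if cb < 0 else cds_b[3 * cb: 3 * cb + 3])
    return CodonAlignment(id_a, id_b, codons_a, codons_b)


# ---------------------------------------------------------------------------
# NG86 counting

def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous, so the two fractions always sum to 3.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways.

    All orderings of the differing positions are enumerated; a pathway that
    passes through a stop codon is discarded.  If every pathway is blocked
    (possible only for near-stop codon pairs) all pathways are used.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # degenerate fallback: ignore the stop rule
        for order in itertools.permutations(diff):
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    saturated: bool
    selection_class: str = field(init=False)
    t_my: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.selection_class = classify_selection(self.ratio)
        self.t_my = None if self.ks is None else divergence_time(self.ks)


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks over the ungapped columns of a codon alignment."""
    cols = aln.ungapped_columns()
    if not cols:
        raise SelectionError("no ungapped codon columns")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in cols:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise SelectionError(f"stop codon in alignment column ({ca},{cb})")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        d_s, d_n = codon_differences(ca, cb)
        sd += d_s; nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps) if s_sites > 0 else None
    ka = jukes_cantor(pn) if n_sites > 0 else None
    saturated = (s_sites > 0 and ks is None) or (n_sites > 0 and ka is None)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    elif ka == 0.0 and ks == 0.0:
        ratio = None
    return KaKsResult(ka, ks, ratio, n_sites, s_sites, nd, sd, saturated)


# ---------------------------------------------------------------------------
# Dating and classification

def divergence_time(ks: float, lam: float = LAMBDA_SYN_PER_YEAR) -> float:
    """Age in million years under the synonymous clock T = Ks/(2λ)."""
    if ks < 0 or not math.isfinite(ks):
        raise SelectionError(f"invalid Ks {ks}")
    return ks / (2.0 * lam) / 1e6


def classify_selection(ratio: float | None, tol: float = 1e-9) -> str:
    if ratio is None:
        return "undefined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


# ---------------------------------------------------------------------------
# Sliding window

def sliding_window(aln: CodonAlignment, window_bp: int = 150,
                   step_bp: int = 9) -> list[tuple[int, int, float | None]]:
    """Ka/Ks in codon-snapped windows over the ungapped alignment columns.

    Windows are ``window_bp`` wide and advance by ``step_bp`` (both must be
    codon-divisible).  Entries where Ka/Ks is undefined (saturation, zero
    synonymous sites or Ks = 0) are None.
    """
    if window_bp % 3 or step_bp % 3:
        raise SelectionError("window and step must be codon-divisible")
    cols = aln.ungapped_columns()
    w, st = window_bp // 3, step_bp // 3
    if len(cols) < w:
        warnings.warn("alignment shorter than one window; using whole alignment")
        sub = CodonAlignment(aln.id_a, aln.id_b,
                             [c[0] for c in cols], [c[1] for c in cols])
        return [(0, 3 * len(cols), kaks_ng86(sub).ratio)]
    track = []
    for i in range(0, len(cols) - w + 1, st):
        window = cols[i:i + w]
        sub = CodonAlignment(aln.id_a, aln.id_b,
                             [c[0] for c in window], [c[1] for c in window])
        res = kaks_ng86(sub)
        track.append((3 * i, 3 * (i + w), res.ratio))
    return track


# ---------------------------------------------------------------------------
# Ks-band grouping and the per-family selection report

def group_ks(ks_values: list[float], n_groups: int = 3) -> list[int]:
    """Single-linkage 1-D grouping: cut the (n_groups-1) largest gaps.

    Returns a group index per input value; groups are numbered 1..k by
    descending mean Ks (oldest band first).  Gap ties break leftmost.
    """
    if n_groups < 1 or n_groups > len(ks_values):
        raise SelectionError("n_groups out of range")
    order = sorted(range(len(ks_values)), key=lambda i: (ks_values[i], i))
    svals = [ks_values[i] for i in order]
    gaps = [(svals[i + 1] - svals[i], i) for i in range(len(svals) - 1)]
    cuts = sorted(i for _, i in sorted(gaps, key=lambda g: (-g[0], g[1]))
                  [: n_groups - 1])
    labels_sorted = []
    g = 0
    for i in range(len(svals)):
        labels_sorted.append(g)
        if i in cuts:
            g += 1
    # map back, then renumber by descending mean Ks
    raw = [0] * len(ks_values)
    for rank, idx in enumerate(order):
        raw[idx] = labels_sorted[rank]
    means = {}
    for lbl in set(raw):
        vals = [ks_values[i] for i in range(len(raw)) if raw[i] == lbl]
        means[lbl] = sum(vals) / len(vals)
    renum = {lbl: i + 1 for i, lbl in
             enumerate(sorted(means, key=lambda l: -means[l]))}
    return [renum[lbl] for lbl in raw]


def selection_report(pairs: list[tuple[str, float, float]],
                     lam: float = LAMBDA_SYN_PER_YEAR,
                     n_groups: int = 3,
                     recent_my: float = 12.0) -> dict:
    """Per-pair dating/selection table plus band summaries.

    ``pairs`` is (pair_name, Ka, Ks).  The returned dict holds the per-pair
    DataFrame (ratio to 4 decimals, T to 2), a per-group summary, the count
    of positive-selection pairs and the count of pairs younger than
    ``recent_my`` million years.
    """
    if not pairs:
        raise SelectionError("no pairs")
    names = [p[0] for p in pairs]
    kas = [p[1] for p in pairs]
    kss = [p[2] for p in pairs]
    ratios = [ka / ks if ks > 0 else None for ka, ks in zip(kas, kss)]
    times = [divergence_time(ks, lam) for ks in kss]
    groups = group_ks(kss, n_groups=min(n_groups, len(kss)))
    table = pd.DataFrame({
        "pair": names,
        "ka": kas,
        "ks": kss,
        "kaks": [None if r is None else round(r, 4) for r in ratios],
        "t_my": [round(t, 2) for t in times],
        "selection_class": [classify_selection(r) for r in ratios],
        "group": groups,
    })
    gsum = (pd.DataFrame({"group": groups, "ks": kss, "t_my": times})
            .groupby("group")
            .agg(n=("ks", "size"), mean_ks=("ks", "mean"), mean_t_my=("t_my", "mean"))
            .reset_index())
    gsum["mean_ks"] = gsum["mean_ks"].round(5)
    gsum["mean_t_my"] = gsum["mean_t_my"].round(2)
    n_positive = sum(1 for r in ratios if r is not None and r > 1.0)
    n_recent = sum(1 for t in times if t < recent_my)
    return {"table": table, "groups": gsum,
            "n_positive": n_positive, "n_recent": n_recent}
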