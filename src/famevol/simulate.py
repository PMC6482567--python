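"""Synthetic data with known ground truth for every pipeline stage.

The codon generator evolves duplicate copies by iterated single-nucleotide
substitutions: proposals hitting a stop codon are rejected, synonymous
changes are always accepted and nonsynonymous ones with relative
probability omega (inverted for omega > 1), until the accepted synonymous
count per synonymous site reaches the target Ks.  The realized counts, not
the targets, are recorded as truth, so recovery tests compare against what
actually happened in the simulation.  Everything is driven by an integer
seed through one numpy Generator per entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from .promoter import ElementDictionary, IUPAC, scan_elements
from .seqio import NUCLEOTIDE, PROTEIN, SequenceSet, reverse_complement

DEFAULT_CODON_LENGTH = 500
DEFAULT_CT_NOISE_SD = 0.15
QPCR_TIMEPOINTS = ("0h", "1h", "3h", "6h", "12h", "24h")
TISSUES = ("L", "P1", "P2", "R", "RH", "S1", "S2")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int
    codon_length: int = DEFAULT_CODON_LENGTH
    duplication_events: list[tuple[str, float, float]] = field(
        default_factory=list)           # (pair_id, target_Ks, omega)
    n_singletons: int = 0
    element_plants: list[tuple[str, int]] = field(default_factory=list)
    promoter_length: int = 2000
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD

    def __post_init__(self) -> None:
        for pid, ks, om in self.duplication_events:
            if ks < 0 or om <= 0:
                raise SimulationError(f"{pid}: need Ks >= 0 and omega > 0")
        for el, n in self.element_plants:
            if n < 0:
                raise SimulationError(f"{el}: negative plant count")


@dataclass
class PairTruth:
    pair_id: str
    id_a: str
    id_b: str
    ks_true: float       # accepted synonymous substitutions per syn site
    ka_true: float
    omega_true: float | None
    syn_subs: int
    nonsyn_subs: int


# ---------------------------------------------------------------------------
# Codon evolution

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random stop-free CDS starting with ATG."""
    codons = ["ATG"] + [SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    return "".join(codons)


def _site_counts(cds: str) -> tuple[float, float]:
    from .selection import codon_sites
    s = n = 0.0
    for i in range(len(cds) // 3):
        cs, cn = codon_sites(cds[3 * i: 3 * i + 3])
        s += cs
        n += cn
    return s, n


def evolve_cds(rng: np.random.Generator, cds: str, target_ks: float,
               omega: float) -> tuple[str, int, int]:
    """Evolve a copy until synonymous divergence reaches ``target_ks``.

    Returns (evolved sequence, accepted synonymous substitutions, accepted
    nonsynonymous substitutions).
    """
    if target_ks > 5.0:
        raise SimulationError(
            f"target Ks {target_ks} is beyond saturation; use a lower Ks")
    s_sites, _ = _site_counts(cds)
    if target_ks == 0.0:
        return cds, 0, 0
    seq = list(cds)
    syn = nonsyn = 0
    p_nonsyn = min(omega, 1.0)
    p_syn = min(1.0 / omega, 1.0)
    max_proposals = int(2000 * len(cds) * max(target_ks, 1.0))
    for _ in range(max_proposals):
        if syn / s_sites >= target_ks:
            return "".join(seq), syn, nonsyn
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        nt = "ACGT"[int(rng.integers(0, 4))]
        if nt == old:
            continue
        c0 = 3 * (pos // 3)
        codon = "".join(seq[c0:c0 + 3])
        new_codon = codon[: pos - c0] + nt + codon[pos - c0 + 1:]
        if new_codon in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[codon] == GENETIC_CODE[new_codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        seq[pos] = nt
        if synonymous:
            syn += 1
        else:
            nonsyn += 1
    raise SimulationError(
        f"target Ks {target_ks} unreachable within proposal budget; "
        "use a lower Ks")


def _pair_truth(pair_id: str, id_a: str, id_b: str, cds: str,
                syn: int, nonsyn: int) -> PairTruth:
    s_sites, n_sites = _site_counts(cds)
    ks = syn / s_sites
    ka = nonsyn / n_sites
    omega = ka / ks if ks > 0 else None
    return PairTruth(pair_id, id_a, id_b, ks, ka, omega, syn, nonsyn)


def simulate_family(config: SimulationConfig
                    ) -> tuple[SequenceSet, list[PairTruth]]:
    """A gene family of duplicate pairs plus unrelated singletons.

    Each duplication event gets an independent ancestor; gene ``<pair>a``
    is the unchanged ancestor, ``<pair>b`` the evolved copy.
    """
    rng = np.random.default_rng(config.seed)
    records: dict[str, str] = {}
    truths: list[PairTruth] = []
    for pid, ks, omega in config.duplication_events:
        anc = random_cds(rng, config.codon_length)
        copy, syn, nonsyn = evolve_cds(rng, anc, ks, omega)
        id_a, id_b = f"{pid}a", f"{pid}b"
        records[id_a] = anc
        records[id_b] = copy
        truths.append(_pair_truth(pid, id_a, id_b, anc, syn, nonsyn))
    for i in range(config.n_singletons):
        records[f"single{i + 1}"] = random_cds(rng, config.codon_length)
    return SequenceSet(records, NUCLEOTIDE), truths


def simulate_two_species(config: SimulationConfig, species_a: str = "Pe",
                         species_b: str = "Os", n_decoys: int = 0
                         ) -> tuple[SequenceSet, SequenceSet, list[PairTruth]]:
    """1:1 ortholog pairs: each species copy evolves Ks/2 from the ancestor."""
    rng = np.random.default_rng(config.seed)
    rec_a: dict[str, str] = {}
    rec_b: dict[str, str] = {}
    truths: list[PairTruth] = []
    for pid, ks, omega in config.duplication_events:
        anc = random_cds(rng, config.codon_length)
        ca, sa, na = evolve_cds(rng, anc, ks / 2.0, omega)
        cb, sb, nb = evolve_cds(rng, anc, ks / 2.0, omega)
        id_a, id_b = f"{species_a}{pid}", f"{species_b}{pid}"
        rec_a[id_a] = ca
        rec_b[id_b] = cb
        truths.append(_pair_truth(pid, id_a, id_b, anc, sa + sb, na + nb))
    for i in range(n_decoys):
        rec_a[f"{species_a}decoy{i + 1}"] = random_cds(rng, config.codon_length)
        rec_b[f"{species_b}decoy{i + 1}"] = random_cds(rng, config.codon_length)
    return (SequenceSet(rec_a, NUCLEOTIDE), SequenceSet(rec_b, NUCLEOTIDE),
            truths)


# ---------------------------------------------------------------------------
# Promoters with planted elements

def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    return "".join(IUPAC[c][int(rng.integers(0, len(IUPAC[c])))]
                   for c in consensus)


def simulate_promoters(config: SimulationConfig,
                       dictionary: ElementDictionary | None = None,
                       max_attempts: int = 200
                       ) -> tuple[SequenceSet, dict[str, list[tuple[int, str]]]]:
    """One promoter with the configured planted element counts.

    Background is i.i.d. uniform.  After planting, chance matches of the
    planted elements arising in the background are scrubbed by point
    mutations outside the planted intervals until a scan finds exactly the
    planted occurrences, so the recorded (position, strand) list is
    exhaustive truth.
    """
    dictionary = dictionary or ElementDictionary.packaged()
    for el, _ in config.element_plants:
        if el not in dictionary.entries:
            raise SimulationError(f"element {el!r} not in dictionary")
    total_bp = sum(len(dictionary.entries[el][0]) * n
                   for el, n in config.element_plants)
    if total_bp > config.promoter_length // 2:
        raise SimulationError("requested plants exceed promoter capacity")
    rng = np.random.default_rng(config.seed)
    wanted = {el: n for el, n in config.element_plants}
    sub = ElementDictionary({el: dictionary.entries[el] for el in wanted})
    for _ in range(max_attempts):
        seq = list("".join(
            "ACGT"[i] for i in
            rng.integers(0, 4, size=config.promoter_length)))
        placed: dict[str, list[tuple[int, str]]] = {el: [] for el in wanted}
        occupied: list[tuple[int, int]] = []
        ok = True
        for el, n in wanted.items():
            cons = dictionary.entries[el][0]
            m = len(cons)
            for _k in range(n):
                for _try in range(200):
                    pos = int(rng.integers(0, config.promoter_length - m + 1))
                    if all(pos + m <= s or pos >= e for s, e in occupied):
                        break
                else:
                    ok = False
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                inst = _instantiate(rng, cons)
                ins = inst if strand == "+" else reverse_complement(inst)
                seq[pos:pos + m] = ins
                occupied.append((pos, pos + m))
                placed[el].append((pos, strand))
            if not ok:
                break
        if not ok:
            continue

        def free(i: int) -> bool:
            return all(i < s or i >= e for s, e in occupied)

        truth_pos = {el: sorted(p for p, _ in placed[el]) for el in wanted}
        for _scrub in range(50):
            promoters = SequenceSet({"prom1": "".join(seq)}, NUCLEOTIDE)
            hits = scan_elements(promoters, sub)
            extra = [h for h in hits
                     if h.position not in truth_pos[h.element]]
            if not extra:
                found = {el: sorted(h.position for h in hits
                                    if h.element == el) for el in wanted}
                if all(found[el] == truth_pos[el] for el in wanted):
                    return promoters, placed
                break  # a planted site was duplicated exactly; resample
            mutated = False
            for h in extra:
                sites = [i for i in range(h.position, h.end) if free(i)]
                if not sites:
                    continue
                i = sites[int(rng.integers(0, len(sites)))]
                choices = [b for b in "ACGT" if b != seq[i]]
                seq[i] = choices[int(rng.integers(0, 3))]
                mutated = True
            if not mutated:
                break  # spurious match locked inside plants; resample
    raise SimulationError("could not realize exact planted counts; "
                          "reduce counts or enlarge the promoter")


# ---------------------------------------------------------------------------
# qPCR Ct tables

def simulate_ct(seed: int, true_folds: dict[str, dict[str, float]],
                reference: str = "TIP41", calibrator: str = "0h",
                conditions: tuple[str, ...] = QPCR_TIMEPOINTS,
                noise_sd: float = DEFAULT_CT_NOISE_SD,
                n_bio: int = 3, n_tech: int = 3,
                base_ct_target: float = 26.0, base_ct_ref: float = 22.0
                ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Ct table under the 2^-ddCt model with Gaussian cycle noise.

    ``true_folds`` maps gene -> condition -> fold relative to the
    calibrator; the calibrator fold is forced to 1.  Truth (the forced fold
    map) is returned alongside the table.
    """
    rng = np.random.default_rng(seed)
    truth = {g: dict(f, **{calibrator: 1.0}) for g, f in true_folds.items()}
    for g, folds in truth.items():
        if any(v <= 0 for v in folds.values()):
            raise SimulationError(f"{g}: true folds must be positive")
    rows = []
    genes = list(truth) + [reference]
    for gene in genes:
        for cond in conditions:
            if gene != reference and cond not in truth[gene]:
                raise SimulationError(f"{gene}: no true fold for {cond!r}")
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    if gene == reference:
                        ct = base_ct_ref
                    else:
                        ct = base_ct_target - np.log2(truth[gene][cond])
                    if noise_sd > 0:
                        ct += rng.normal(0.0, noise_sd)
                    rows.append((gene, cond, bio, tech, float(ct)))
    table = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep",
                                        "tech_rep", "ct"])
    return table, truth


# ---------------------------------------------------------------------------
# Tissue matrix with planted specificity

def simulate_tissue_matrix(seed: int, n_genes: int,
                           tissues: tuple[str, ...] = TISSUES,
                           effect_size: float = 8.0,
                           base_mean: float = 4.0
                           ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression matrix where each gene is dominant in one planted tissue."""
    rng = np.random.default_rng(seed)
    truth: dict[str, str] = {}
    data = {}
    for i in range(n_genes):
        gene = f"gene{i + 1:03d}"
        top = tissues[int(rng.integers(0, len(tissues)))]
        base = rng.lognormal(mean=np.log(base_mean), sigma=0.3, size=len(tissues))
        vals = dict(zip(tissues, base))
        vals[top] *= effect_size
        data[gene] = vals
        truth[gene] = top
    matrix = pd.DataFrame(data).T[list(tissues)]
    return matrix, truth


# ---------------------------------------------------------------------------
# Protein clades for phylogeny tests

_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_protein_clades(seed: int, n_clades: int, per_clade: int,
                            length: int = 120, between_p: float = 0.4,
                            within_p: float = 0.05
                            ) -> tuple[dict[str, str], dict[str, int]]:
    """Aligned protein families in well-separated clades.

    Each clade ancestor diverges from a common root by mutating a
    ``between_p`` fraction of sites; members mutate a further ``within_p``
    fraction.  Returns the gap-free MSA and the clade index of each leaf.
    """
    rng = np.random.default_rng(seed)

    def mutate(s: str, p: float) -> str:
        out = list(s)
        for i in range(len(out)):
            if rng.random() < p:
                out[i] = _AA[int(rng.integers(0, len(_AA)))]
        return "".join(out)

    root = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))
    msa: dict[str, str] = {}
    clade_of: dict[str, int] = {}
    for c in range(n_clades):
        anc = mutate(root, between_p)
        for m in range(per_clade):
            name = f"c{c + 1}m{m + 1}"
            msa[name] = mutate(anc, within_p)
            clade_of[name] = c + 1
    return msa, clade_of
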