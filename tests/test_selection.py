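import itertools
import math

import numpy as np
import pytest

from famevol import selection, simulate
from famevol.census import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from famevol.selection import CodonAlignment


def _aln(codons_a, codons_b):
    return CodonAlignment("a", "b", list(codons_a), list(codons_b))


# ---------------------------------------------------------------------------
# codon-aware alignment

def test_identical_cds_align_without_gaps():
    cds = "ATG" + "GCT" * 20 + "TAA"
    aln = selection.codon_align("a", cds, "b", cds)
    assert "---" not in aln.codons_a
    assert aln.codons_a == aln.codons_b


def test_internal_codon_deletion_gives_one_gap_codon():
    body = [SENSE_CODONS[i] for i in range(2, 32)]
    cds_a = "ATG" + "".join(body)
    cds_b = "ATG" + "".join(body[:10] + body[11:])
    aln = selection.codon_align("a", cds_a, "b", cds_b)
    assert aln.codons_b.count("---") == 1
    assert aln.codons_a.count("---") == 0


def test_back_translation_recovers_inputs():
    cds_a = "ATG" + "GCTCATAAG" * 10
    cds_b = "ATG" + "GCGCACAAA" * 10
    aln = selection.codon_align("a", cds_a, "b", cds_b)
    assert "".join(c for c in aln.codons_a if c != "---") == cds_a
    assert "".join(c for c in aln.codons_b if c != "---") == cds_b


# ---------------------------------------------------------------------------
# NG86 counting — hand cases and brute-force oracle

def test_identical_sequences_have_zero_ka_ks():
    aln = _aln(["ATG", "GCT"], ["ATG", "GCT"])
    res = selection.kaks_ng86(aln)
    assert res.ka == 0.0 and res.ks == 0.0


def test_single_synonymous_change_hand_counted():
    # GGG -> GGA: glycine either way, third position fourfold degenerate
    aln = _aln(["ATG", "GGG"], ["ATG", "GGA"])
    res = selection.kaks_ng86(aln)
    assert res.sd == 1.0 and res.nd == 0.0
    assert res.ka == 0.0
    # the toy pair has a single synonymous site, so pS = 1 is saturated
    assert res.ks is None and res.saturated


def test_site_fractions_sum_to_three_per_codon():
    for codon in SENSE_CODONS:
        s, n = selection.codon_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert 0.0 <= s <= 3.0


def test_kaks_symmetric_in_sequence_order():
    rng = np.random.default_rng(2)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=60)]
    other = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=60)]
    r1 = selection.kaks_ng86(_aln(codons, other))
    r2 = selection.kaks_ng86(_aln(other, codons))
    assert r1.sd == pytest.approx(r2.sd)
    assert r1.nd == pytest.approx(r2.nd)
    assert r1.s_sites == pytest.approx(r2.s_sites)


def _oracle_codon_diff(ca, cb):
    """Independent pathway enumeration (no shared code with the module)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        for order in itertools.permutations(diff):
            cur, sd, nd = ca, 0, 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                sd += GENETIC_CODE[cur] == GENETIC_CODE[nxt]
                nd += GENETIC_CODE[cur] != GENETIC_CODE[nxt]
                cur = nxt
            paths.append((sd, nd))
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def _oracle_sites(codon):
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt != codon[pos]:
                alt = codon[:pos] + nt + codon[pos + 1:]
                s += (GENETIC_CODE[alt] == aa) / 3.0
    return s


def test_counts_match_brute_force_oracle_on_random_pairs():
    """(Nd, Sd, N, S) equal independent enumeration, 50 seeded 300-codon pairs."""
    rng = np.random.default_rng(123)
    for _ in range(50):
        ca = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=300)]
        cb = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=300)]
        res = selection.kaks_ng86(_aln(ca, cb))
        sd = nd = 0.0
        for x, y in zip(ca, cb):
            s, n = _oracle_codon_diff(x, y)
            sd += s
            nd += n
        s_sites = (sum(map(_oracle_sites, ca)) + sum(map(_oracle_sites, cb))) / 2
        assert res.sd == pytest.approx(sd)
        assert res.nd == pytest.approx(nd)
        assert res.s_sites == pytest.approx(s_sites)
        assert res.n_sites == pytest.approx(900 - s_sites)


def test_saturation_flagged_for_extreme_divergence():
    # proportions at 3/4 or beyond are uncorrectable under Jukes-Cantor
    assert selection.jukes_cantor(0.75) is None
    assert selection.jukes_cantor(0.1) == pytest.approx(
        -0.75 * math.log(1 - 0.4 / 3))


def test_all_gap_alignment_is_error():
    with pytest.raises(selection.SelectionError):
        selection.kaks_ng86(_aln(["---"], ["---"]))


# ---------------------------------------------------------------------------
# dating and classification

@pytest.mark.parametrize("ks,expected_my", [(0.28456, 21.89),
                                            (1.33589, 102.76),
                                            (0.0, 0.0)])
def test_synonymous_clock_dating(ks, expected_my):
    assert round(selection.divergence_time(ks), 2) == expected_my


def test_dating_linear_in_ks():
    assert selection.divergence_time(0.5) == pytest.approx(
        2 * selection.divergence_time(0.25))


@pytest.mark.parametrize("ratio,cls", [(1.5346, "positive"),
                                       (0.2271, "purifying"),
                                       (1.0, "neutral"),
                                       (None, "undefined")])
def test_selection_classification(ratio, cls):
    assert selection.classify_selection(ratio) == cls


# ---------------------------------------------------------------------------
# sliding window

def _simulated_alignment(seed, n_codons, ks, omega):
    cfg = simulate.SimulationConfig(seed=seed, codon_length=n_codons,
                                    duplication_events=[("P", ks, omega)])
    seqs, truth = simulate.simulate_family(cfg)
    t = truth[0]
    return selection.codon_align(t.id_a, seqs[t.id_a], t.id_b, seqs[t.id_b])


def test_window_count_arithmetic():
    aln = _simulated_alignment(1, 200, 0.3, 0.3)
    track = selection.sliding_window(aln)
    aligned_bp = 3 * len(aln.ungapped_columns())
    assert len(track) == (aligned_bp - 150) // 9 + 1


def test_uniform_divergence_gives_flat_track():
    aln = _simulated_alignment(4, 400, 0.4, 0.5)
    values = [r for _, _, r in selection.sliding_window(aln) if r is not None]
    whole = selection.kaks_ng86(aln).ratio
    assert min(values) <= whole <= max(values)


def test_engineered_high_omega_block_localized():
    rng = np.random.default_rng(8)
    anc = simulate.random_cds(rng, 300)
    # low omega everywhere, then overwrite a middle block at high omega
    lo, _, _ = simulate.evolve_cds(rng, anc, 0.4, 0.05)
    hi_block, _, _ = simulate.evolve_cds(rng, anc[300:600], 0.4, 5.0)
    derived = lo[:300] + hi_block + lo[600:]
    aln = selection.codon_align("a", anc, "b", derived)
    track = selection.sliding_window(aln)
    defined = [(s, r) for s, _, r in track if r is not None]
    peak_start = max(defined, key=lambda x: x[1])[0]
    assert 150 <= peak_start <= 600  # window overlapping the planted block


def test_short_alignment_falls_back_to_single_window():
    aln = _simulated_alignment(2, 30, 0.2, 0.5)
    with pytest.warns(UserWarning, match="whole alignment"):
        track = selection.sliding_window(aln)
    assert len(track) == 1


# ---------------------------------------------------------------------------
# Ks grouping and report

def test_group_ks_splits_at_largest_gaps():
    values = [0.1, 0.12, 0.5, 0.55, 1.2, 1.25]
    groups = selection.group_ks(values, n_groups=3)
    # oldest band is group 1
    assert groups == [3, 3, 2, 2, 1, 1]


def test_group_ks_single_group():
    assert selection.group_ks([0.1, 0.2], n_groups=1) == [1, 1]


def test_report_counts_positive_and_recent_pairs():
    pairs = [("p1", 0.2, 0.1),   # ratio 2 (positive), 7.7 My (recent)
             ("p2", 0.05, 0.5),  # purifying, 38 My
             ("p3", 0.9, 0.6)]   # positive, 46 My
    rep = selection.selection_report(pairs, n_groups=2)
    assert rep["n_positive"] == 2
    assert rep["n_recent"] == 1
    assert list(rep["table"]["selection_class"]) == \
        ["positive", "purifying", "positive"]


# ---------------------------------------------------------------------------
# parameter recovery (quick single-seed check; the full sweep is in acceptance)

def test_simulated_pair_estimates_close_to_truth():
    aln = _simulated_alignment(10, 500, 0.3, 0.2)
    res = selection.kaks_ng86(aln)
    assert abs(res.ks - 0.3) / 0.3 < 0.25
    assert abs(res.ratio - 0.2) / 0.2 < 0.35
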