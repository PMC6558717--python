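"""NG86 Ka/Ks: site counts, pathway averaging, JC correction, windows."""

import itertools
import math
import warnings

import numpy as np
import pytest

from bbxkit.core_io import SeqRecord, translate_cds
from bbxkit.evolution import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    classify_duplication,
    classify_selection,
    codon_align,
    kaks,
    ng86_differences,
    ng86_sites,
    sliding_window,
)
from bbxkit.homology import align_global
from bbxkit.simulate import FULL_AA, evolve_pair, reverse_translate


# --- independent oracles (deliberately re-derived, not shared code) ---------

def oracle_sites(codon):
    """Synonymous site count by direct neighbor enumeration."""
    syn = 0.0
    for pos, ref in enumerate(codon):
        neighbors = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in "ACGT"
            if nt != ref
        ]
        legal = [n for n in neighbors if n not in STOP_CODONS]
        if legal:
            syn += sum(GENETIC_CODE[n] == GENETIC_CODE[codon] for n in legal) / len(legal)
    return syn


def oracle_differences(a, b):
    """Pathway averaging by explicit path construction over position orders."""
    positions = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in itertools.permutations(positions):
        path = [a]
        for pos in order:
            path.append(path[-1][:pos] + b[pos] + path[-1][pos + 1 :])
        if any(step in STOP_CODONS for step in path[1:]):
            continue
        syn = sum(
            GENETIC_CODE[x] == GENETIC_CODE[y] for x, y in zip(path, path[1:])
        )
        outcomes.append((syn, len(positions) - syn))
    if not outcomes:
        return None
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


def test_site_counts_match_enumeration_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = ng86_sites(codon)
        assert s == pytest.approx(oracle_sites(codon), abs=1e-12)
        assert s + n == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize(
    "codon,expected_syn", [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0), ("TGG", 0.0)]
)
def test_site_count_examples(codon, expected_syn):
    assert ng86_sites(codon)[0] == pytest.approx(expected_syn)


def test_sites_reject_stop_codons():
    with pytest.raises(ValueError):
        ng86_sites("TAA")


def test_pathway_differences_match_enumeration_for_all_codon_pairs():
    for a, b in itertools.product(SENSE_CODONS, repeat=2):
        got = ng86_differences(a, b)
        expected = oracle_differences(a, b)
        if expected is None:
            assert math.isnan(got[0]) and math.isnan(got[1])
        else:
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1] == pytest.approx(expected[1], abs=1e-12)


@pytest.mark.parametrize(
    "a,b,expected",
    [("TTT", "TTT", (0.0, 0.0)), ("TTT", "TTA", (0.0, 1.0)), ("TTT", "GTA", (0.5, 1.5))],
)
def test_pathway_difference_examples(a, b, expected):
    assert ng86_differences(a, b) == pytest.approx(expected)


def test_pathway_differences_symmetric():
    for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("AAA", "CCC"), ("TCA", "AGT")]:
        assert ng86_differences(a, b) == pytest.approx(ng86_differences(b, a))


def _ungapped(cds_a, cds_b):
    return CodonAlignment(
        None,
        [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)],
        [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)],
    )


def test_identical_sequences_give_zero_rates_undefined_ratio():
    cds = "ATGTTTGGGAAACCCGGGTTTAAACCCGGG"
    result = kaks(_ungapped(cds, cds))
    assert result.ka == 0.0 and result.ks == 0.0
    assert result.ratio is None
    assert result.selection_class == "undetermined"


def test_synonymous_only_evolution_gives_zero_ka(rng):
    protein = "".join(rng.choice(list(FULL_AA), size=300))
    anc = reverse_translate(rng, protein)
    cds_a, cds_b, _ = evolve_pair(anc, 0.4, 0.0, rng)
    assert translate_cds(cds_a) == translate_cds(cds_b)
    result = kaks(_ungapped(cds_a, cds_b))
    assert result.ka == 0.0
    assert result.ks > 0.2


def test_site_conservation_invariant(rng):
    codons = list(SENSE_CODONS)
    for _ in range(10):
        n = int(rng.integers(10, 60))
        a = "".join(rng.choice(codons, size=n))
        b = "".join(rng.choice(codons, size=n))
        result = kaks(_ungapped(a, b))
        per_seq_mean_sites = result.s_sites + result.n_sites
        assert per_seq_mean_sites == pytest.approx(3.0 * result.n_codons, abs=1e-9)


def test_kaks_symmetric_in_sequences(rng):
    protein = "".join(rng.choice(list(FULL_AA), size=200))
    anc = reverse_translate(rng, protein)
    a, b, _ = evolve_pair(anc, 0.5, 0.2, rng)
    fwd, rev = kaks(_ungapped(a, b)), kaks(_ungapped(b, a))
    assert fwd.ka == pytest.approx(rev.ka)
    assert fwd.ks == pytest.approx(rev.ks)


def test_kaks_cross_check_against_biopython_ng86(rng):
    """Biopython's NG86 is an independent implementation; Ka should agree
    closely and Ks within the site-counting convention difference (it
    handles mutations-to-stop site exclusion differently)."""
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(3):
            protein = "".join(rng.choice(list(FULL_AA), size=250))
            anc = reverse_translate(rng, protein)
            a, b, _ = evolve_pair(anc, 0.4, 0.1, rng)
            mine = kaks(_ungapped(a, b))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.ka == pytest.approx(dn, rel=0.05)
            assert mine.ks == pytest.approx(ds, rel=0.15)


def test_codon_align_round_trip(rng):
    protein = "".join(rng.choice(list(FULL_AA), size=120))
    anc = reverse_translate(rng, protein)
    a, b, _ = evolve_pair(anc, 0.3, 0.25, rng)
    aln = align_global(
        SeqRecord("a", translate_cds(a), "protein"),
        SeqRecord("b", translate_cds(b), "protein"),
    )
    caln = codon_align(a, b, aln)
    assert "".join(c for c in caln.codons_a if c != "---") == a
    assert "".join(c for c in caln.codons_b if c != "---") == b


def test_codon_align_places_gap_codons():
    from bbxkit.homology import AlignmentResult

    aln = AlignmentResult("a", "b", "MKV", "M-V", 0.0, 1.0, 1.0)
    caln = codon_align("ATGAAAGTT", "ATGGTT", aln)
    assert caln.codons_b == ["ATG", "---", "GTT"]


def test_codon_align_reports_discordant_codon():
    from bbxkit.homology import AlignmentResult

    aln = AlignmentResult("a", "b", "MK", "MK", 0.0, 1.0, 1.0)
    with pytest.raises(ValueError, match="codon 1"):
        codon_align("ATGAAA", "ATGCGC", aln)  # CGC codes R, aligned protein says K


def test_window_count_and_fallback(rng):
    protein = "".join(rng.choice(list(FULL_AA), size=100))
    anc = reverse_translate(rng, protein)
    a, b, _ = evolve_pair(anc, 0.2, 0.1, rng)
    profile = sliding_window(_ungapped(a, b))  # 300 bp
    assert len(profile.windows) == (300 - 150) // 9 + 1 == 17
    assert [w[0] for w in profile.windows] == [9 * i for i in range(17)]

    short = sliding_window(_ungapped(a[:120], b[:120]))
    assert short.whole_length_fallback and len(short.windows) == 1


def test_windows_fluctuate_around_global_ratio(rng):
    protein = "".join(rng.choice(list(FULL_AA), size=600))
    anc = reverse_translate(rng, protein)
    a, b, _ = evolve_pair(anc, 0.4, 0.12, rng)
    caln = _ungapped(a, b)
    overall = kaks(caln)
    profile = sliding_window(caln)
    ratios = [w[4] for w in profile.windows if w[4] is not None]
    assert ratios, "windows should produce defined ratios at this divergence"
    assert min(ratios) < overall.ratio < max(ratios)
    # no window saturates at this moderate divergence
    assert all(w[3] is not None for w in profile.windows)


@pytest.mark.parametrize(
    "ratio,expected_class,expected_bin",
    [
        (0.1, "strong_purifying", "<0.3"),
        (0.29999, "strong_purifying", "<0.3"),
        (0.3, "relaxed_purifying", "0.3-1"),
        (1.0, "relaxed_purifying", "0.3-1"),
        (1.2, "positive", ">1"),
        (None, "undetermined", "undefined"),
    ],
)
def test_selection_classification(ratio, expected_class, expected_bin):
    assert classify_selection(ratio) == (expected_class, expected_bin)


@pytest.mark.parametrize(
    "ks,expected",
    [(1.0658, "shared_WGD"), (1.4562, "shared_WGD"), (0.0433, "recent"),
     (0.0827, "recent"), (0.5, "other"), (None, "other")],
)
def test_duplication_age_classification(ks, expected):
    assert classify_duplication(ks) == expected


def test_family_kaks_matches_planted_structure(family, family_kaks):
    """Selection bins (9/7/1) and duplication ages recover the plant."""
    bins = {}
    for result in family_kaks.values():
        _, label = classify_selection(result.ratio)
        bins[label] = bins.get(label, 0) + 1
    assert bins == {"<0.3": 9, "0.3-1": 7, ">1": 1}

    targets = {(t["id_a"], t["id_b"]): t for t in family.truth["pairs"]}
    for key, result in family_kaks.items():
        target = targets[key]
        if target["relation"] == "paralog":
            expected_age = (
                "shared_WGD" if target["target_ks"] > 0.8 else "recent"
            )
            assert classify_duplication(result.ks) == expected_age
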