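"""Scanner: hairpin enumeration, pairing, planted recovery, dedup, collapse."""

import numpy as np
import pytest

from antarscan._alphabet import CANONICAL_PAIRS, revcomp_dna, rna_to_dna
from antarscan.io import GenomeRecord
from antarscan.motif import MotifConstraints, consensus_candidate, score_candidate
from antarscan.scan import (
    AntarMotifHit,
    Hairpin,
    collapse_identical,
    dedup_overlapping,
    enumerate_candidate_scores,
    find_hairpins,
    pair_hairpins,
    scan_genome,
)

from .conftest import random_rna


def brute_force_hairpins(seq, kmin=3, kmax=10):
    """Independent enumeration over all (loop position, stem depth) windows."""
    found = set()
    n = len(seq)
    for i in range(n):          # loop start
        loop = seq[i : i + 6]
        if len(loop) < 6 or "N" in loop:
            continue
        for bp in range(kmin, kmax + 1):
            lo, hi = i - bp, i + 6 + bp
            if lo < 0 or hi > n:
                continue
            ok = all(
                seq[lo + d] + seq[hi - 1 - d] in CANONICAL_PAIRS for d in range(bp)
            )
            if ok:
                found.add((lo, bp))
    return found


# ---------------------------------------------------------------------------
# hairpin enumeration


def test_single_constructed_hairpin():
    hps = find_hairpins("GCCACUGUUGGC")
    assert len(hps) == 1
    h = hps[0]
    assert h.stem_bp == 3 and h.loop_seq == "ACUGUU"
    assert h.outer_start == 0 and h.outer_end == 12


def test_no_complementarity_no_hairpins():
    assert find_hairpins("AAAAAAAAAAAA") == []


def test_hairpin_enumeration_matches_brute_force():
    rng = np.random.default_rng(7)
    seq = random_rna(rng, 60)
    got = {(h.outer_start, h.stem_bp) for h in find_hairpins(seq)}
    assert got == brute_force_hairpins(seq)


def test_hairpins_never_span_n():
    rng = np.random.default_rng(8)
    seq = list(random_rna(rng, 80))
    seq[40] = "N"
    seq = "".join(seq)
    for h in find_hairpins(seq):
        assert "N" not in seq[h.outer_start : h.outer_end]


def test_substems_emitted_down_to_minimum():
    # 5 contiguous pairs: depths 3, 4, 5 must all be reported at this loop
    seq = "GGGGG" + "ACUGUU" + "CCCCC"
    depths = sorted(h.stem_bp for h in find_hairpins(seq)
                    if h.loop_seq == "ACUGUU")
    assert depths == [3, 4, 5]


# ---------------------------------------------------------------------------
# hairpin pairing


def _hairpin_at(seq, outer_start, bp, seqid="s", strand="+"):
    loop = seq[outer_start + bp : outer_start + bp + 6]
    return Hairpin(seqid=seqid, strand=strand, outer_start=outer_start,
                   stem_bp=bp, loop_seq=loop)


@pytest.mark.parametrize("gap,expected", [(10, 1), (2, 1), (25, 1), (1, 0), (26, 0)])
def test_pair_hairpins_linker_bounds(gap, expected):
    hp1_seq = "GGGACUGUUCCC"
    hp2_seq = "CCCAGCGCAGGG"
    seq = hp1_seq + "A" * gap + hp2_seq
    h1 = _hairpin_at(seq, 0, 3)
    h2 = _hairpin_at(seq, 12 + gap, 3)
    cands = pair_hairpins([h1, h2], seq)
    assert len(cands) == expected
    if expected:
        assert len(cands[0].linker) == gap


# ---------------------------------------------------------------------------
# genome scanning


def plant(genome_seq: str, motif_dna: str, pos: int) -> str:
    return genome_seq[:pos] + motif_dna + genome_seq[pos + len(motif_dna):]


def test_planted_consensus_recovered_exactly(family_profile):
    rng = np.random.default_rng(11)
    background = "".join(
        rng.choice(list("ACGT"), size=12_000, p=[0.175, 0.325, 0.325, 0.175])
    )
    cons = consensus_candidate(family_profile, stem1_bp=5, stem2_bp=5)
    motif = rna_to_dna(cons.sequence)
    seq = plant(background, motif, 5000)
    genome = GenomeRecord(id="g", sequence=seq)
    hits = scan_genome(genome, family_profile, min_bits=20.0)
    spans = [(h.start, h.end, h.strand) for h in hits]
    assert (5000, 5000 + len(motif), "+") in spans


def test_strand_symmetry(family_profile):
    rng = np.random.default_rng(12)
    background = "".join(
        rng.choice(list("ACGT"), size=8_000, p=[0.175, 0.325, 0.325, 0.175])
    )
    cons = consensus_candidate(family_profile, stem1_bp=5, stem2_bp=5)
    motif = rna_to_dna(cons.sequence)
    fwd = GenomeRecord(id="g", sequence=plant(background, motif, 3000))
    rev = GenomeRecord(id="g", sequence=revcomp_dna(fwd.sequence))
    hits_f = scan_genome(fwd, family_profile, min_bits=20.0)
    hits_r = scan_genome(rev, family_profile, min_bits=20.0)
    L = fwd.length
    mirrored = sorted(
        (L - h.end, L - h.start, "-" if h.strand == "+" else "+", round(h.score, 6))
        for h in hits_r
    )
    original = sorted(
        (h.start, h.end, h.strand, round(h.score, 6)) for h in hits_f
    )
    assert mirrored == original


def test_planted_recovery_at_any_threshold_below_max(family_profile):
    """A verbatim consensus plant is recovered at threshold max_score - eps."""
    rng = np.random.default_rng(13)
    background = "".join(
        rng.choice(list("ACGT"), size=6_000, p=[0.175, 0.325, 0.325, 0.175])
    )
    cons = consensus_candidate(family_profile)  # full-depth argmax candidate
    motif = rna_to_dna(cons.sequence)
    genome = GenomeRecord(id="g", sequence=plant(background, motif, 2000))
    thr = family_profile.max_score - 1e-6
    hits = scan_genome(genome, family_profile, min_bits=thr)
    assert any(h.start == 2000 and h.score >= thr for h in hits)


def test_short_genome_yields_empty_result(family_profile):
    genome = GenomeRecord(id="tiny", sequence="ACGT" * 5)
    assert scan_genome(genome, family_profile, min_bits=0.0) == []


def test_single_strand_enumeration_matches_brute_force(family_profile):
    """On a short sequence the scanner equals an independent full enumeration
    of (hairpin1, linker, hairpin2) decompositions with identical filtering."""
    from antarscan.motif import CandidateMotif, count_curation_violations

    rng = np.random.default_rng(21)
    seq = random_rna(rng, 200)
    constraints = MotifConstraints()
    expected = []
    hp = brute_force_hairpins(seq)
    for (s1, bp1) in hp:
        for (s2, bp2) in hp:
            e1 = s1 + 2 * bp1 + 6
            gap = s2 - e1
            if not (2 <= gap <= 25):
                continue
            cand = CandidateMotif(
                stem1_pairs=tuple(
                    seq[s1 + d] + seq[e1 - 1 - d] for d in range(bp1)
                ),
                loop1=seq[s1 + bp1 : s1 + bp1 + 6],
                linker=seq[e1 : s2],
                loop2=seq[s2 + bp2 : s2 + bp2 + 6],
                stem2_pairs=tuple(
                    seq[s2 + d] + seq[s2 + 2 * bp2 + 6 - 1 - d] for d in range(bp2)
                ),
            )
            if len(count_curation_violations(cand, constraints)) > 1:
                continue
            expected.append(round(score_candidate(family_profile, cand), 9))
    got = [round(s, 9) for s in enumerate_candidate_scores(seq, family_profile)]
    assert sorted(got) == sorted(expected)


# ---------------------------------------------------------------------------
# dedup / collapse


def _hit(seqid="g", strand="+", start=0, end=40, score=10.0, seq=None, species=None):
    h1 = Hairpin(seqid, strand, start, 3, "ACUGUU")
    h2 = Hairpin(seqid, strand, end - 12, 3, "AGCGCA")
    return AntarMotifHit(
        seqid=seqid, strand=strand, start=start, end=end,
        flank_start=max(0, start - 10), flank_end=end + 10,
        hairpin1=h1, hairpin2=h2, linker_len=end - start - 24, score=score,
        curation_violations=0, sequence=seq or ("G" * (end - start)),
        species=species,
    )


def test_dedup_keeps_highest_scoring_of_nested_pair():
    a = _hit(start=100, end=140, score=18.0)
    b = _hit(start=102, end=138, score=15.0)
    kept = dedup_overlapping([a, b])
    assert kept == [a]


def test_dedup_keeps_disjoint_hits():
    a = _hit(start=0, end=40, score=12.0)
    b = _hit(start=100, end=140, score=11.0)
    assert len(dedup_overlapping([a, b])) == 2


def test_dedup_equal_scores_prefers_leftmost():
    a = _hit(start=100, end=160, score=12.0)
    b = _hit(start=124, end=184, score=12.0)  # 60% overlap of the shorter
    kept = dedup_overlapping([a, b])
    assert kept == [a]


def test_collapse_identical_within_species():
    hits = [
        _hit(seqid="s1", start=10, seq="GGAACC", species="spA"),
        _hit(seqid="s2", start=99, seq="GGAACC", species="spA"),
        _hit(seqid="s3", start=50, seq="GGAACC", species="spA"),
    ]
    reps = collapse_identical(hits)
    assert len(reps) == 1
    rep, mult = reps[0]
    assert rep.seqid == "s1" and mult == 3


def test_collapse_keeps_identical_sequences_of_different_species():
    hits = [
        _hit(seqid="s1", seq="GGAACC", species="spA"),
        _hit(seqid="s2", seq="GGAACC", species="spB"),
    ]
    assert len(collapse_identical(hits)) == 2


def test_collapse_does_not_merge_point_variants():
    hits = [
        _hit(seqid="s1", seq="GGAACC", species="spA"),
        _hit(seqid="s2", seq="GGAACU", species="spA"),
    ]
    assert len(collapse_identical(hits)) == 2
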