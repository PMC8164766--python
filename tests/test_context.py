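"""Context classification: RBS detection, category rules, altORFs, terminators."""

import numpy as np
import pytest

from antarscan._alphabet import revcomp_dna
from antarscan.context import (
    INSIDE_ORF,
    INTERGENIC,
    SEQUESTER,
    UNASSIGNED,
    category_tally,
    classify_context,
    classify_with_rescue,
    detect_rbs,
    find_alt_orfs,
    find_terminator,
)
from antarscan.io import GenomeRecord, OrfRecord
from antarscan.scan import AntarMotifHit, Hairpin

from .conftest import random_dna


def make_hit(seqid="g", strand="+", start=0, end=40, genome_length=10_000):
    bp = 3
    h1 = Hairpin(seqid, strand, start, bp, "ACUGUU")
    h2 = Hairpin(seqid, strand, end - (2 * bp + 6), bp, "AGCGCA")
    return AntarMotifHit(
        seqid=seqid, strand=strand, start=start, end=end,
        flank_start=max(0, start - 10), flank_end=min(genome_length, end + 10),
        hairpin1=h1, hairpin2=h2, linker_len=end - start - 24,
        score=20.0, curation_violations=0, sequence="G" * (end - start),
    )


def genome_with(seq_parts: dict[int, str], length=10_000, seed=0, seqid="g"):
    rng = np.random.default_rng(seed)
    seq = list(random_dna(rng, length, p=[0.25, 0.25, 0.25, 0.25]))
    for pos, s in seq_parts.items():
        seq[pos : pos + len(s)] = list(s)
    return GenomeRecord(id=seqid, sequence="".join(seq))


# ---------------------------------------------------------------------------
# RBS detection


def test_canonical_shine_dalgarno_detected():
    g = genome_with({979: "C" * 21, 1000 - 7 - 6: "AGGAGG", 1000: "ATG"}, seed=1)
    orf = OrfRecord("g", 1000, 1300, "+", "orf1")
    rbs = detect_rbs(g, orf)
    assert rbs is not None
    assert rbs.sequence == "AGGAGG" and rbs.spacer == 7
    assert (rbs.start, rbs.end) == (987, 993)


def test_all_pyrimidine_upstream_gives_none():
    g = genome_with({1000 - 21: "C" * 21, 1000: "ATG"}, seed=2)
    assert detect_rbs(g, OrfRecord("g", 1000, 1300, "+", "o")) is None


def test_one_non_purine_accepted():
    g = genome_with({1000 - 21: "C" * 21}, seed=3)
    g = genome_with({1000 - 21: "C" * 21, 1000 - 3 - 6: "AGCAGG"}, seed=3)
    rbs = detect_rbs(g, OrfRecord("g", 1000, 1300, "+", "o"))
    assert rbs is not None and rbs.sequence == "AGCAGG" and rbs.spacer == 3


def test_rbs_minus_strand():
    # ORF on minus strand starting at genomic end coordinate 2000
    site = revcomp_dna("AGGAGG")
    # G-scrub reads as pyrimidine C on the minus strand, so only the planted
    # site is purine-rich in the ORF's own orientation
    g = genome_with({2000: "G" * 30, 2000 + 5: site}, seed=4)
    orf = OrfRecord("g", 1700, 2000, "-", "o")
    rbs = detect_rbs(g, orf)
    assert rbs is not None and rbs.sequence == "AGGAGG" and rbs.spacer == 5


def test_rbs_contig_edge_returns_none():
    g = GenomeRecord(id="g", sequence="C" * 2 + "ATG" + "C" * 50)
    assert detect_rbs(g, OrfRecord("g", 2, 50, "+", "o")) is None


# ---------------------------------------------------------------------------
# classification rules (plus-strand examples forced by the thresholds)


@pytest.fixture
def plain_genome():
    # pyrimidine-only background so no spurious RBS windows appear
    return GenomeRecord(id="g", sequence="CT" * 5_000)


def test_intergenic_example(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=710, end=750)  # flanks [700, 760)
    call = classify_context(hit, [orf], plain_genome)
    assert call.category == INTERGENIC
    assert call.distance_to_start == -240


def test_sequester_start_codon_overlap(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=990, end=1004)
    call = classify_context(hit, [orf], plain_genome)
    assert call.category == SEQUESTER


def test_sequester_via_flank_only(plain_genome):
    # motif ends 5 nt before the start codon; only the flank overlaps it
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=955, end=995)
    call = classify_context(hit, [orf], plain_genome)
    assert call.category == SEQUESTER


def test_inside_orf_example(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=1020, end=1060)
    call = classify_context(hit, [orf], plain_genome)
    assert call.category == INSIDE_ORF
    assert call.distance_to_start == 20


def test_inside_orf_beyond_100nt_unassigned(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=1150, end=1190)
    assert classify_context(hit, [orf], plain_genome).category == UNASSIGNED


def test_gap_1_to_14_nt_is_unassigned(plain_genome):
    # flank ends 14 nt before the start and touches neither RBS nor codon
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    hit = make_hit(start=906, end=946)  # flank end 956, gap 44? no: 1000-956=44
    hit = make_hit(start=936, end=976)  # flank end 986, gap 14
    assert classify_context(hit, [orf], plain_genome).category == UNASSIGNED


def test_no_orfs_unassigned(plain_genome):
    hit = make_hit(start=100, end=140)
    call = classify_context(hit, [], plain_genome)
    assert call.category == UNASSIGNED and call.orf is None


def test_motif_only_flag_changes_boundary(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    # motif end 990: flank end 1000 -> gap 0 (flank-inclusive) but motif-only
    # gap is 10, still < 15 => both UNASSIGNED; use gap 20 instead
    hit = make_hit(start=940, end=980)  # flank end 990: flank gap 10, motif gap 20
    assert classify_context(hit, [orf], plain_genome).category == UNASSIGNED
    assert (
        classify_context(hit, [orf], plain_genome, flank_inclusive=False).category
        == INTERGENIC
    )


def test_strand_covariance_of_categories(plain_genome):
    """Mirroring genome and annotations leaves every category unchanged."""
    L = plain_genome.length
    mirrored = GenomeRecord(id="g", sequence=revcomp_dna(plain_genome.sequence))
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    orf_m = OrfRecord("g", L - 1400, L - 1000, "-", "o")
    for start, end in [(710, 750), (990, 1004), (1020, 1060), (1150, 1190)]:
        fwd = classify_context(make_hit(start=start, end=end), [orf], plain_genome)
        rev_hit = make_hit(strand="-", start=L - end, end=L - start)
        rev = classify_context(rev_hit, [orf_m], mirrored)
        assert fwd.category == rev.category
        assert fwd.distance_to_start == rev.distance_to_start


def test_nearest_same_strand_orf_selected(plain_genome):
    near = OrfRecord("g", 1000, 1400, "+", "near")
    far = OrfRecord("g", 3000, 3400, "+", "far")
    opposite = OrfRecord("g", 900, 1300, "-", "opp")
    hit = make_hit(start=710, end=750)
    call = classify_context(hit, [far, opposite, near], plain_genome)
    assert call.orf.orf_id == "near"


# ---------------------------------------------------------------------------
# alternate ORFs


def test_alt_orf_with_planted_rbs_found():
    parts = {2000: "ATG" + "GCA" * 30 + "TAA", 2000 - 8 - 6: "AGGAGG"}
    g = genome_with(parts, seed=5)
    alts = find_alt_orfs(g, (1900, 2100), "+")
    assert any(o.start == 2000 for o in alts)


def test_alt_orf_requires_rbs_spacer_within_15():
    pyr = GenomeRecord(
        id="g",
        sequence=("C" * 2000 + "ATG" + "GCA" * 30 + "TAA" + "C" * 500),
    )
    seq = list(pyr.sequence)
    seq[2000 - 20 - 6 : 2000 - 20] = list("AGGAGG")  # spacer 20: too far
    g = GenomeRecord(id="g", sequence="".join(seq))
    assert find_alt_orfs(g, (1900, 2100), "+") == []


def test_gtg_start_accepted():
    pyr = "C" * 2000 + "GTG" + "GCA" * 30 + "TAA" + "C" * 500
    seq = list(pyr)
    seq[2000 - 4 - 6 : 2000 - 4] = list("AGGAGG")
    g = GenomeRecord(id="g", sequence="".join(seq))
    alts = find_alt_orfs(g, (1900, 2100), "+")
    assert any(o.start == 2000 for o in alts)


def test_rescue_assigns_alt_orf_category():
    # no annotated ORFs; an altORF right after the motif rescues SEQUESTER
    base = "C" * 1000 + "ATG" + "GCA" * 40 + "TAA" + "C" * 500
    seq = list(base)
    seq[1000 - 8 - 6 : 1000 - 8] = list("AGGAGG")
    g = GenomeRecord(id="g", sequence="".join(seq))
    hit = make_hit(start=955, end=995, genome_length=g.length)
    call = classify_with_rescue(hit, [], g)
    assert call.category == SEQUESTER and call.alt_orf is not None


# ---------------------------------------------------------------------------
# terminator surrogate


def _terminator_genome(tail: str):
    hairpin = "GCGCGC" + "AAAA" + "GCGCGC"
    motif_start = 500
    # dual stem loop hit occupying [500, 540); terminator right after stem2
    seq = "C" * 500 + "T" * 40 + hairpin + tail
    seq = seq + "C" * 200
    return GenomeRecord(id="g", sequence=seq), make_hit(
        start=motif_start, end=540, genome_length=len(seq)
    )


def test_terminator_with_u_tail_found():
    g, hit = _terminator_genome("TTTTTTTT")
    site = find_terminator(g, hit)
    assert site is not None
    assert site.tail_end - site.tail_start <= 8


def test_terminator_requires_u_tail():
    g, hit = _terminator_genome("ACACACAC")
    assert find_terminator(g, hit) is None


def test_no_downstream_hairpin_gives_none():
    g = GenomeRecord(id="g", sequence="CT" * 400)
    hit = make_hit(start=100, end=140, genome_length=800)
    assert find_terminator(g, hit) is None


def test_terminator_overlapping_stem2_flagged():
    # place the terminator hairpin so its 5' arm begins inside stem2
    # stem2 occupies [528, 540); build hairpin starting at 536
    seq = "C" * 536 + "GCGCG" + "AAAA" + "CGCGC" + "TTTTTTTT" + "C" * 200
    g = GenomeRecord(id="g", sequence=seq)
    hit = make_hit(start=500, end=540, genome_length=g.length)
    site = find_terminator(g, hit)
    assert site is not None and site.overlaps_stem2


# ---------------------------------------------------------------------------
# tally


def test_category_tally_fractions(plain_genome):
    orf = OrfRecord("g", 1000, 1400, "+", "o")
    calls = []
    for start, end in [(710, 750)] * 4 + [(990, 1004)] * 4 + [(1020, 1060)] * 2:
        calls.append(classify_context(make_hit(start=start, end=end), [orf],
                                      plain_genome))
    df = category_tally(calls).set_index("category")
    assert df.loc[INTERGENIC, "count"] == 4
    assert df.loc[SEQUESTER, "fraction"] == pytest.approx(0.4)
    assert df.loc[INSIDE_ORF, "fraction"] == pytest.approx(0.2)


def test_category_tally_empty():
    df = category_tally([])
    assert (df["count"] == 0).all()
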