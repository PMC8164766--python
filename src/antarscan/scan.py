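"""Enumerate, score, curate and deduplicate dual stem-loop motif hits.

Hairpin enumeration is exhaustive: every window with a 6-nt loop and a
contiguous run of canonical pairs is reported at every stem depth from
``min_stem_bp`` up to its maximal extension, so the scorer — not the
enumerator — decides the stem extent.  Both strands are scanned; all reported
coordinates are on the + frame, 0-based half-open, while loop/linker sequences
stay strand-local (the RNA actually transcribed).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._alphabet import CANONICAL_PAIRS, dna_to_rna, revcomp_rna
from .io import GenomeRecord, OrfRecord
from .motif import (
    CandidateMotif,
    MotifConstraints,
    MotifProfile,
    count_curation_violations,
    score_candidate,
)

logger = logging.getLogger(__name__)

FLANK_NT = 10  # flanking region included in context arithmetic


@dataclass(frozen=True)
class Hairpin:
    """One stem-loop: contiguous canonical stem capping a 6-nt loop.

    ``outer_start``/``outer_end`` are coordinates on the scanned strand's
    local frame during enumeration; scan_genome resolves them to + frame.
    """

    seqid: str
    strand: str
    outer_start: int
    stem_bp: int
    loop_seq: str

    @property
    def outer_end(self) -> int:
        return self.outer_start + 2 * self.stem_bp + 6

    @property
    def loop_start(self) -> int:
        return self.outer_start + self.stem_bp

    @property
    def span(self) -> tuple[int, int]:
        return (self.outer_start, self.outer_end)


@dataclass(frozen=True)
class AntarMotifHit:
    """A scored, curated dual stem-loop occurrence on a genome (+ frame)."""

    seqid: str
    strand: str
    start: int
    end: int
    flank_start: int
    flank_end: int
    hairpin1: Hairpin  # 5' hairpin in transcript order
    hairpin2: Hairpin
    linker_len: int
    score: float
    curation_violations: int
    sequence: str  # strand-local RNA of the dual stem loop
    species: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# enumeration


def find_hairpins(
    seq: str, constraints: MotifConstraints | None = None, seqid: str = "", strand: str = "+"
) -> list[Hairpin]:
    """All hairpins with a 6-nt loop and stem depth in [min_stem_bp, max_stem_bp].

    Stems are extended outward greedily and every sub-stem down to min_stem_bp
    is emitted, one Hairpin per distinct (position, stem_bp).  No hairpin may
    span an N.
    """
    constraints = constraints or MotifConstraints()
    kmin, kmax = constraints.min_stem_bp, constraints.max_stem_bp
    n = len(seq)
    out: list[Hairpin] = []
    # i = loop start; pairs are (i-k, i+5+k)
    for i in range(kmin, n - 6 - kmin + 1):
        loop = seq[i : i + 6]
        if "N" in loop:
            continue
        k = 0
        while k < kmax:
            left, right = i - k - 1, i + 6 + k
            if left < 0 or right >= n:
                break
            if seq[left] + seq[right] not in CANONICAL_PAIRS:
                break
            k += 1
        for bp in range(kmin, k + 1):
            out.append(
                Hairpin(
                    seqid=seqid,
                    strand=strand,
                    outer_start=i - bp,
                    stem_bp=bp,
                    loop_seq=loop,
                )
            )
    out.sort(key=lambda h: (h.outer_start, h.stem_bp))
    return out


def _stem_pairs(seq: str, h: Hairpin) -> tuple[str, ...]:
    return tuple(
        seq[h.outer_start + d] + seq[h.outer_end - 1 - d] for d in range(h.stem_bp)
    )


def pair_hairpins(
    hairpins: Sequence[Hairpin],
    seq: str,
    constraints: MotifConstraints | None = None,
) -> list[CandidateMotif]:
    """All ordered hairpin pairs whose linker gap lies within bounds.

    ``hairpins`` must come from one seqid/strand of ``seq``.  The linker is
    the gap between hairpin1.outer_end and hairpin2.outer_start and may not
    contain N.
    """
    constraints = constraints or MotifConstraints()
    hp = sorted(hairpins, key=lambda h: (h.outer_start, h.stem_bp))
    starts = [h.outer_start for h in hp]
    out: list[CandidateMotif] = []
    for h1 in hp:
        lo = bisect_left(starts, h1.outer_end + constraints.linker_min)
        hi = bisect_right(starts, h1.outer_end + constraints.linker_max)
        for h2 in hp[lo:hi]:
            linker = seq[h1.outer_end : h2.outer_start]
            if "N" in linker:
                continue
            out.append(
                CandidateMotif(
                    stem1_pairs=_stem_pairs(seq, h1),
                    loop1=h1.loop_seq,
                    linker=linker,
                    loop2=h2.loop_seq,
                    stem2_pairs=_stem_pairs(seq, h2),
                    seqid=h1.seqid,
                    span=(h1.outer_start, h2.outer_end),
                    strand=h1.strand,
                )
            )
    return out


# ---------------------------------------------------------------------------
# scanning


def _candidate_to_hit(
    cand: CandidateMotif,
    genome_length: int,
    strand: str,
    seqid: str,
    score: float,
    violations: int,
) -> AntarMotifHit:
    """Resolve a strand-local candidate into a + frame hit."""
    s, e = cand.span
    bp1, bp2 = len(cand.stem1_pairs), len(cand.stem2_pairs)
    if strand == "+":
        start, end = s, e
        h1_start = s
        h2_start = e - (2 * bp2 + 6)
    else:
        start, end = genome_length - e, genome_length - s
        # hairpin1 (5' in transcript) sits at the right end of the + frame span
        h1_start = end - (2 * bp1 + 6)
        h2_start = start
    h1 = Hairpin(seqid=seqid, strand=strand, outer_start=h1_start, stem_bp=bp1,
                 loop_seq=cand.loop1)
    h2 = Hairpin(seqid=seqid, strand=strand, outer_start=h2_start, stem_bp=bp2,
                 loop_seq=cand.loop2)
    return AntarMotifHit(
        seqid=seqid,
        strand=strand,
        start=start,
        end=end,
        flank_start=max(0, start - FLANK_NT),
        flank_end=min(genome_length, end + FLANK_NT),
        hairpin1=h1,
        hairpin2=h2,
        linker_len=len(cand.linker),
        score=score,
        curation_violations=violations,
        sequence=cand.sequence,
    )


def _scan_strand(
    rna: str,
    genome_length: int,
    strand: str,
    seqid: str,
    profile: MotifProfile,
    constraints: MotifConstraints,
    min_bits: float,
    stats: dict | None = None,
) -> list[AntarMotifHit]:
    hairpins = find_hairpins(rna, constraints, seqid=seqid, strand=strand)
    # cheap pre-filter: a hairpin whose own loop already exceeds the motif-wide
    # violation budget can never appear in a passing candidate
    budget = constraints.max_conserved_position_violations
    admissible = []
    for h in hairpins:
        viol = sum(
            1 for pos, base in constraints.conserved_loop_positions
            if h.loop_seq[pos] != base
        )
        if viol <= budget:
            admissible.append((h, viol))
    viol_of = {(h.outer_start, h.stem_bp): v for h, v in admissible}
    candidates = pair_hairpins([h for h, _ in admissible], rna, constraints)
    hits = []
    n_curated = 0
    for cand in candidates:
        s, e = cand.span
        bp1, bp2 = len(cand.stem1_pairs), len(cand.stem2_pairs)
        v1 = viol_of[(s, bp1)]
        v2 = viol_of[(e - (2 * bp2 + 6), bp2)]
        if v1 + v2 > budget:
            continue
        n_curated += 1
        score = score_candidate(profile, cand)
        if score >= min_bits:
            hits.append(
                _candidate_to_hit(cand, genome_length, strand, seqid, score, v1 + v2)
            )
    if stats is not None:
        stats["candidates"] = stats.get("candidates", 0) + len(candidates)
        stats["curated"] = stats.get("curated", 0) + n_curated
        stats["thresholded"] = stats.get("thresholded", 0) + len(hits)
    return hits


def dedup_overlapping(hits: Sequence[AntarMotifHit]) -> list[AntarMotifHit]:
    """Among hits overlapping > 50% of the shorter span, keep the best.

    Best = highest score, ties broken by leftmost start, then + strand.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1))
    kept: list[AntarMotifHit] = []
    for h in order:
        redundant = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * min(h.length, k.length):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.seqid, h.start, -h.score))
    return kept


def scan_genome(
    genome: GenomeRecord,
    profile: MotifProfile,
    constraints: MotifConstraints | None = None,
    min_bits: float = 0.0,
    orfs: Sequence[OrfRecord] | None = None,
    stats: dict | None = None,
) -> list[AntarMotifHit]:
    """Scan both strands of a genome for curated dual stem-loop hits.

    Hits pass the curation filter, score at least ``min_bits`` and are
    deduplicated.  When ``orfs`` is given, only hits positioned 500 nt
    upstream to 100 nt downstream of the nearest same-strand ORF start are
    retained; without annotations that filter defers to the context module.
    """
    constraints = constraints or MotifConstraints()
    if genome.length < constraints.min_motif_length:
        logger.info(
            "genome %s (%d nt) is shorter than the minimal motif (%d nt); no scan",
            genome.id, genome.length, constraints.min_motif_length,
        )
        return []
    rna = genome.rna
    hits = _scan_strand(rna, genome.length, "+", genome.id, profile, constraints,
                        min_bits, stats)
    hits += _scan_strand(revcomp_rna(rna), genome.length, "-", genome.id, profile,
                         constraints, min_bits, stats)
    hits = dedup_overlapping(hits)
    if stats is not None:
        stats["deduped"] = stats.get("deduped", 0) + len(hits)
    if orfs is not None:
        from .context import near_orf_window

        hits = [h for h in hits if near_orf_window(h, orfs)]
        if stats is not None:
            stats["near_orf"] = stats.get("near_orf", 0) + len(hits)
    return hits


def enumerate_candidate_scores(
    seq: str,
    profile: MotifProfile,
    constraints: MotifConstraints | None = None,
    curated: bool = True,
) -> list[float]:
    """Scores of all (curation-passing) candidates on one strand of ``seq``.

    This is the scanner's enumeration applied to an isolated sequence (e.g. a
    shuffled negative control); the given strand only, as for an RNA.
    """
    constraints = constraints or MotifConstraints()
    rna = dna_to_rna(seq.upper())
    hairpins = find_hairpins(rna, constraints)
    candidates = pair_hairpins(hairpins, rna, constraints)
    scores = []
    for cand in candidates:
        if curated:
            ok = (
                len(count_curation_violations(cand, constraints))
                <= constraints.max_conserved_position_violations
            )
            if not ok:
                continue
        scores.append(score_candidate(profile, cand))
    return scores


# ---------------------------------------------------------------------------
# cross-genome deduplication


def collapse_identical(
    hits: Iterable[AntarMotifHit],
    species_of=None,
) -> list[tuple[AntarMotifHit, int]]:
    """Collapse identical motif sequences within a species to one representative.

    ``species_of`` maps a hit to its species label (defaults to the hit's
    ``species`` field, falling back to its seqid).  The representative is the
    hit with the lexicographically smallest (seqid, start); the returned
    multiplicity counts collapsed members.
    """
    if species_of is None:
        species_of = lambda h: h.species if h.species is not None else h.seqid
    groups: dict[tuple[str, str], list[AntarMotifHit]] = {}
    for h in hits:
        groups.setdefault((species_of(h), h.sequence), []).append(h)
    out = []
    for members in groups.values():
        members.sort(key=lambda h: (h.seqid, h.start))
        out.append((members[0], len(members)))
    out.sort(key=lambda pair: (pair[0].seqid, pair[0].start))
    return out
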