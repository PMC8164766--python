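"""Genomic-context classification of motif hits against ORF annotations.

Each hit is assigned to one of three categories relative to its nearest
same-strand ORF, using the flank-inclusive span (dual stem loop +-10 nt):

* ``SEQUESTER_RBS_OR_AUG`` — the flank-inclusive span overlaps the ORF's
  start codon or its detected ribosome-binding site;
* ``INSIDE_ORF`` — the motif's 5' end lies strictly after the ORF start and
  within 100 nt of it, with the motif contained in the ORF;
* ``INTERGENIC`` — the 3' flank end lies 15-500 nt upstream of the ORF start.

Precedence is SEQUESTER > INSIDE_ORF > INTERGENIC; anything else (including
hits 1-14 nt upstream touching neither RBS nor start codon) is UNASSIGNED.
Minus-strand geometry is handled by mirroring hit and annotations into the
plus frame, which makes the classification strand-covariant by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._alphabet import PURINES, revcomp_dna
from .io import GenomeRecord, OrfRecord
from .scan import AntarMotifHit

logger = logging.getLogger(__name__)

INTERGENIC = "INTERGENIC"
SEQUESTER = "SEQUESTER_RBS_OR_AUG"
INSIDE_ORF = "INSIDE_ORF"
UNASSIGNED = "UNASSIGNED"
CATEGORIES = (INTERGENIC, SEQUESTER, INSIDE_ORF)

UPSTREAM_MIN = 15
UPSTREAM_MAX = 500
INSIDE_MAX = 100
RBS_SPACER_MAX = 15
RBS_LEN_RANGE = (6, 5, 4)
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class RbsSite:
    """A purine-rich (AG-rich) 4-6 nt window 0-15 nt upstream of a start codon.

    Coordinates are 0-based half-open on the + frame of the genome.
    """

    start: int
    end: int
    sequence: str
    spacer: int


@dataclass(frozen=True)
class TerminatorSite:
    """A simplified intrinsic-terminator call: GC-rich hairpin + U tail."""

    arm5_start: int
    arm5_end: int
    arm3_start: int
    arm3_end: int
    tail_start: int
    tail_end: int
    overlaps_stem2: bool


@dataclass(frozen=True)
class ContextCall:
    hit: AntarMotifHit
    orf: OrfRecord | None
    category: str
    distance_to_start: int | None
    rbs: RbsSite | None = None
    alt_orf: OrfRecord | None = None
    terminator_overlap: bool = False


# ---------------------------------------------------------------------------
# mirroring helpers (strand-aware arithmetic is done in a local plus frame)


def _mirror_interval(start: int, end: int, length: int) -> tuple[int, int]:
    return length - end, length - start


def _is_purine_rich(window: str) -> bool:
    purines = sum(1 for ch in window if ch in PURINES)
    return purines >= 4 and (len(window) - purines) <= 1


def detect_rbs(genome: GenomeRecord, orf: OrfRecord) -> RbsSite | None:
    """Find the ribosome-binding site of an ORF.

    The longest AG-rich window (4-6 nt, at most one non-purine, >=4 purines)
    at a spacer of 0-15 nt upstream of the start codon; among equal-length
    windows the purest (most purines) wins, then the smallest spacer, so a
    planted AGGAGG beats its one-off sliding neighbours.
    """
    seq = genome.sequence
    L = genome.length
    if orf.strand == "+":
        upstream_available = orf.start
    else:
        upstream_available = L - orf.end
    if upstream_available < min(RBS_LEN_RANGE):
        logger.info("ORF %s at contig edge: no upstream sequence for RBS", orf.orf_id)
        return None
    for w in RBS_LEN_RANGE:
        best = None
        for spacer in range(0, RBS_SPACER_MAX + 1):
            if orf.strand == "+":
                end = orf.start - spacer
                start = end - w
                if start < 0:
                    continue
                window = seq[start:end]
            else:
                start = orf.end + spacer
                end = start + w
                if end > L:
                    continue
                window = revcomp_dna(seq[start:end])
            if _is_purine_rich(window):
                purines = sum(1 for ch in window if ch in PURINES)
                key = (-purines, spacer)
                if best is None or key < best[0]:
                    best = (key, RbsSite(start=start, end=end,
                                         sequence=window, spacer=spacer))
        if best is not None:
            return best[1]
    return None


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return min(a1, b1) - max(a0, b0)


def _hit_local_coords(hit: AntarMotifHit, length: int):
    """(motif_start, motif_end, flank_start, flank_end) in the hit's 5'->3' frame."""
    if hit.strand == "+":
        return hit.start, hit.end, hit.flank_start, hit.flank_end
    ms, me = _mirror_interval(hit.start, hit.end, length)
    fs, fe = _mirror_interval(hit.flank_start, hit.flank_end, length)
    return ms, me, fs, fe


def _orf_local_coords(orf: OrfRecord, length: int) -> tuple[int, int]:
    if orf.strand == "+":
        return orf.start, orf.end
    return _mirror_interval(orf.start, orf.end, length)


def _selection_distance(ms, me, fs, fe, os_, oe) -> int | None:
    """Signed distance used to pick the nearest ORF; None if outside the
    [-500 upstream, +100 inside] window."""
    if fe <= os_:  # hit entirely upstream of the start
        d = os_ - fe
        return d if d <= UPSTREAM_MAX else None
    if ms > os_:  # motif begins after the start codon position
        d = ms - os_
        return -d if d <= INSIDE_MAX else None
    return 0  # overlapping the start


def near_orf_window(hit: AntarMotifHit, orfs: Sequence[OrfRecord]) -> bool:
    """Retention filter: hit lies 500 nt upstream to 100 nt downstream of the
    start of some same-strand ORF on its seqid."""
    return _select_orf(hit, orfs) is not None


def _select_orf(hit: AntarMotifHit, orfs: Sequence[OrfRecord], length: int | None = None):
    """Nearest same-strand ORF within the retention window, with its local
    geometry; None if absent.  ``length`` fixes the mirror frame for minus
    strand hits; any value covering all coordinates yields the same geometry.
    """
    if length is None:
        L_needed = max((o.end for o in orfs if o.seqid == hit.seqid), default=0)
        length = max(hit.flank_end, L_needed)
    ms, me, fs, fe = _hit_local_coords(hit, length)
    best = None
    for orf in orfs:
        if orf.seqid != hit.seqid or orf.strand != hit.strand:
            continue
        os_, oe = _orf_local_coords(orf, length)
        d = _selection_distance(ms, me, fs, fe, os_, oe)
        if d is None:
            continue
        key = (abs(d), os_)
        if best is None or key < best[0]:
            best = (key, orf, os_, oe, d)
    if best is None:
        return None
    _, orf, os_, oe, d = best
    return orf, os_, oe, length


def classify_context(
    hit: AntarMotifHit,
    orfs: Sequence[OrfRecord],
    genome: GenomeRecord,
    flank_inclusive: bool = True,
) -> ContextCall:
    """Assign a hit to one of the three context categories (or UNASSIGNED).

    ``flank_inclusive`` controls whether the 15-500 nt intergenic distance is
    measured from the flank end (default) or the motif end.
    """
    sel = _select_orf(hit, orfs, length=genome.length)
    if sel is None:
        return ContextCall(hit=hit, orf=None, category=UNASSIGNED,
                           distance_to_start=None)
    orf, os_, oe, length = sel
    ms, me, fs, fe = _hit_local_coords(hit, length)

    rbs = detect_rbs(genome, orf)
    rbs_local = None
    if rbs is not None:
        if hit.strand == "+":
            rbs_local = (rbs.start, rbs.end)
        else:
            rbs_local = _mirror_interval(rbs.start, rbs.end, length)

    # precedence 1: flank-inclusive span covers start codon or RBS window
    if _overlap(fs, fe, os_, os_ + 3) > 0 or (
        rbs_local is not None and _overlap(fs, fe, *rbs_local) > 0
    ):
        return ContextCall(hit=hit, orf=orf, category=SEQUESTER,
                           distance_to_start=ms - os_, rbs=rbs)

    # precedence 2: motif 5' end strictly inside, within 100 nt of the start
    offset = ms - os_
    if 0 < offset <= INSIDE_MAX and me <= oe:
        return ContextCall(hit=hit, orf=orf, category=INSIDE_ORF,
                           distance_to_start=offset, rbs=rbs)

    # precedence 3: 3' end 15-500 nt upstream of the start
    edge = fe if flank_inclusive else me
    gap = os_ - edge
    if UPSTREAM_MIN <= gap <= UPSTREAM_MAX:
        return ContextCall(hit=hit, orf=orf, category=INTERGENIC,
                           distance_to_start=edge - os_, rbs=rbs)

    return ContextCall(hit=hit, orf=orf, category=UNASSIGNED,
                       distance_to_start=fe - os_ if fe <= os_ else ms - os_,
                       rbs=rbs)


# ---------------------------------------------------------------------------
# alternate ORFs


def find_alt_orfs(
    genome: GenomeRecord,
    window: tuple[int, int],
    strand: str,
    min_length: int = 60,
    seqid: str | None = None,
) -> list[OrfRecord]:
    """Alternate ORFs starting at ATG/GTG/TTG inside ``window`` (+ frame
    coordinates) on ``strand``, each at least ``min_length`` nt to an in-frame
    stop and carrying an RBS at a 0-15 nt spacer."""
    seqid = seqid or genome.id
    seq = genome.sequence if strand == "+" else revcomp_dna(genome.sequence)
    L = genome.length
    if strand == "+":
        lo, hi = window
    else:
        lo, hi = _mirror_interval(window[0], window[1], L)
    lo, hi = max(0, lo), min(L, hi)
    out = []
    for s in range(lo, hi):
        if seq[s : s + 3] not in START_CODONS:
            continue
        end = None
        for p in range(s + 3, L - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                end = p + 3
                break
        if end is None or end - s < min_length:
            continue
        if strand == "+":
            g_start, g_end = s, end
        else:
            g_start, g_end = _mirror_interval(s, end, L)
        orf = OrfRecord(seqid=seqid, start=g_start, end=g_end, strand=strand,
                        orf_id=f"alt_{g_start + 1}_{strand}")
        if detect_rbs(genome, orf) is None:
            continue
        out.append(orf)
    return out


ALT_ORF_WINDOW = 300


def classify_with_rescue(
    hit: AntarMotifHit,
    orfs: Sequence[OrfRecord],
    genome: GenomeRecord,
    flank_inclusive: bool = True,
) -> ContextCall:
    """classify_context, rescuing UNASSIGNED hits via alternate-ORF prediction.

    A rescued call keeps only the SEQUESTER or INSIDE_ORF outcomes (the
    categories alternate ORFs can evidence) and flags the supporting altORF.
    """
    call = classify_context(hit, orfs, genome, flank_inclusive)
    if call.category != UNASSIGNED:
        return call
    window = (hit.start - ALT_ORF_WINDOW, hit.end + ALT_ORF_WINDOW)
    alt = find_alt_orfs(genome, window, hit.strand, seqid=hit.seqid)
    if not alt:
        return call
    rescued = classify_context(hit, alt, genome, flank_inclusive)
    if rescued.category in (SEQUESTER, INSIDE_ORF):
        return ContextCall(hit=hit, orf=rescued.orf, category=rescued.category,
                           distance_to_start=rescued.distance_to_start,
                           rbs=rescued.rbs, alt_orf=rescued.orf,
                           terminator_overlap=rescued.terminator_overlap)
    return call


# ---------------------------------------------------------------------------
# simplified intrinsic-terminator surrogate

TERM_DOWNSTREAM = 40
TERM_MIN_STEM = 4
TERM_GC_FRACTION = 0.6
TERM_LOOP_RANGE = (3, 8)
TERM_TAIL_GAP = 2
TERM_TAIL_WINDOW = 8
TERM_TAIL_MIN_U = 4


def find_terminator(genome: GenomeRecord, hit: AntarMotifHit) -> TerminatorSite | None:
    """Search the hit's 3' region plus 40 nt downstream for a GC-rich hairpin
    (stem >= 4 bp, >= 60% G-C pairs, loop 3-8 nt) followed within 2 nt by a
    run of >= 4 U in the next 8 nt.  Returns the leftmost such site."""
    L = genome.length
    seq = genome.sequence if hit.strand == "+" else revcomp_dna(genome.sequence)
    ms, me, _, _ = _hit_local_coords(hit, L)
    if hit.strand == "+":
        stem2_lo, stem2_hi = hit.hairpin2.outer_start, hit.hairpin2.outer_end
    else:
        stem2_lo, stem2_hi = _mirror_interval(
            hit.hairpin2.outer_start, hit.hairpin2.outer_end, L
        )
    region_lo = stem2_lo
    region_hi = min(L, me + TERM_DOWNSTREAM)
    pairs = {"GC", "CG", "AT", "TA", "GT", "TG"}
    gc_pairs = {"GC", "CG"}
    for loop_len in range(TERM_LOOP_RANGE[0], TERM_LOOP_RANGE[1] + 1):
        for i in range(region_lo, region_hi - loop_len):
            # i = loop start; extend stem outward
            k = 0
            while True:
                left, right = i - k - 1, i + loop_len + k
                if left < region_lo or right >= region_hi:
                    break
                if seq[left] + seq[right] not in pairs:
                    break
                k += 1
            if k < TERM_MIN_STEM:
                continue
            stem = [seq[i - d - 1] + seq[i + loop_len + d] for d in range(k)]
            gc = sum(1 for p in stem if p in gc_pairs)
            if gc < TERM_GC_FRACTION * k:
                continue
            hp_end = i + loop_len + k
            tail_found = False
            for gap in range(0, TERM_TAIL_GAP + 1):
                window = seq[hp_end + gap : hp_end + gap + TERM_TAIL_WINDOW]
                if window.count("T") >= TERM_TAIL_MIN_U:
                    tail_start = hp_end + gap
                    tail_end = min(L, tail_start + TERM_TAIL_WINDOW)
                    tail_found = True
                    break
            if not tail_found:
                continue
            arm5 = (i - k, i)
            overlaps = _overlap(arm5[0], arm5[1], stem2_lo, stem2_hi) > 0
            if hit.strand == "-":
                arm5 = _mirror_interval(*arm5, L)
                arm3 = _mirror_interval(hp_end - k, hp_end, L)
                tail = _mirror_interval(tail_start, tail_end, L)
            else:
                arm3 = (hp_end - k, hp_end)
                tail = (tail_start, tail_end)
            return TerminatorSite(
                arm5_start=arm5[0], arm5_end=arm5[1],
                arm3_start=arm3[0], arm3_end=arm3[1],
                tail_start=tail[0], tail_end=tail[1],
                overlaps_stem2=overlaps,
            )
    return None


# ---------------------------------------------------------------------------
# reporting


def category_tally(calls: Sequence[ContextCall]) -> pd.DataFrame:
    """Counts and fractions per category, with altORF-rescued counts separate."""
    rows = []
    total = len(calls)
    for cat in CATEGORIES + (UNASSIGNED,):
        members = [c for c in calls if c.category == cat]
        rows.append(
            {
                "category": cat,
                "count": len(members),
                "fraction": len(members) / total if total else 0.0,
                "altorf_rescued": sum(1 for c in members if c.alt_orf is not None),
            }
        )
    return pd.DataFrame(rows, columns=["category", "count", "fraction", "altorf_rescued"])
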