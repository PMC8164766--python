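"""Synthetic high-GC genomes with planted dual stem-loop motifs and ORFs.

The simulator stands in for real actinobacterial genomes: an i.i.d. background
at a configurable GC fraction (default 0.65, typical of the phylum), annotated
ORFs with Shine-Dalgarno-like RBS elements, and motifs sampled from a seed
family and planted at geometries realizing each of the three genomic-context
categories.  Every placement is verified against the context classifier at
generation time, and full ground truth is emitted.

Family-divergence mutations preserve base pairing by default (compensatory
pair-type changes), matching how a structured RNA family diverges: pairing is
the conserved feature, sequence varies.  One-sided pair-breaking mutations are
available via ``compensatory_stem_mutations=False`` to stress the curation
filter and covariation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._alphabet import NUCLEOTIDES, PAIR_TYPES, revcomp_dna, rna_to_dna
from .context import CATEGORIES, INSIDE_ORF, INTERGENIC, SEQUESTER, classify_context
from .io import GenomeRecord, OrfRecord, SeedAlignment, make_seed_alignment
from .motif import CandidateMotif, MotifConstraints, MotifProfile, consensus_candidate
from .scan import FLANK_NT, AntarMotifHit, Hairpin
from .shuffles import _rng_for


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# seed family

# Family architecture used when no external seed alignment is supplied:
# 5-bp stems, hexanucleotide loops with the canonical A1/G4, GC-rich pairs.
SEED_LOOP1 = "ACUGCU"
SEED_LOOP2 = "AGCGUC"
SEED_STEM1 = ("GC", "CG", "GC", "UA", "GC")
SEED_STEM2 = ("CG", "GC", "GU", "CG", "GC")
SEED_LINKER_RANGE = (4, 12)
SEED_CONSERVED_RATE = 0.92   # A1/G4 loop positions
SEED_LOOP_RATE = 0.65        # other loop positions match consensus
SEED_STEM_RATE = 0.55        # pair type matches consensus


def make_synthetic_seed(n_rows: int = 30, seed: int = 0) -> SeedAlignment:
    """A synthetic 30-sequence seed alignment of the dual stem-loop family.

    Emulates the role of a curated seed set: strong A1/G4 conservation,
    moderate conservation elsewhere in the loops, covarying GC-rich stems and
    linkers of 4-12 nt (padded with gaps to a fixed alignment width).
    """
    rng = _rng_for(seed, "synthetic-seed")
    lmin, lmax = SEED_LINKER_RANGE
    linker_weights = np.array(
        [lmax - abs(l - (lmin + lmax) // 2) for l in range(lmin, lmax + 1)], float
    )
    linker_weights /= linker_weights.sum()
    rows = []
    for r in range(n_rows):
        loops = []
        for consensus in (SEED_LOOP1, SEED_LOOP2):
            loop = []
            for pos, base in enumerate(consensus):
                rate = SEED_CONSERVED_RATE if pos in (0, 3) else SEED_LOOP_RATE
                if rng.random() < rate:
                    loop.append(base)
                else:
                    loop.append(rng.choice([b for b in NUCLEOTIDES if b != base]))
            loops.append("".join(loop))
        stems = []
        for consensus_stem in (SEED_STEM1, SEED_STEM2):
            stem = []
            for pair in consensus_stem:
                if rng.random() < SEED_STEM_RATE:
                    stem.append(pair)
                else:
                    stem.append(rng.choice([p for p in PAIR_TYPES if p != pair]))
            stems.append(tuple(stem))
        linker_len = int(rng.choice(np.arange(lmin, lmax + 1), p=linker_weights))
        linker = "".join(
            rng.choice(list("ACGU"), p=[0.15, 0.35, 0.35, 0.15])
            for _ in range(linker_len)
        )
        linker_padded = linker + "-" * (lmax - linker_len)
        left1 = "".join(p[0] for p in stems[0])
        right1 = "".join(p[1] for p in reversed(stems[0]))
        left2 = "".join(p[0] for p in stems[1])
        right2 = "".join(p[1] for p in reversed(stems[1]))
        row = left1 + loops[0] + right1 + linker_padded + left2 + loops[1] + right2
        rows.append((f"seed{r:02d}", row))
    bp1, bp2 = len(SEED_STEM1), len(SEED_STEM2)
    ss = (
        "(" * bp1 + "." * 6 + ")" * bp1
        + "." * lmax
        + "(" * bp2 + "." * 6 + ")" * bp2
    )
    return make_seed_alignment(rows, ss)


# ---------------------------------------------------------------------------
# configuration & truth


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 200_000
    gc_fraction: float = 0.65
    n_motifs: int = 25
    n_orfs: int | None = None  # defaults to n_motifs
    loop_mutation_rate: float = 0.0
    stem_mutation_rate: float = 0.0
    compensatory_stem_mutations: bool = True
    #: fractions over (INTERGENIC, SEQUESTER_RBS_OR_AUG, INSIDE_ORF);
    #: default mirrors the observed category split of the family
    context_mix: tuple[float, float, float] = (0.39, 0.37, 0.24)
    orf_length: int = 300
    rbs_sequence: str = "AGGAGG"
    both_strands: bool = True
    #: stem depth of planted motifs (the seed family's architecture)
    stem1_bp: int = 5
    stem2_bp: int = 5
    linker_len: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must lie in (0, 1)")
        if abs(sum(self.context_mix) - 1.0) > 1e-6:
            raise ValueError("context_mix must sum to 1")
        for r in (self.loop_mutation_rate, self.stem_mutation_rate):
            if not (0 <= r <= 1):
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.orf_length % 3 or self.orf_length < 60:
            raise ValueError("orf_length must be a multiple of 3, >= 60")


@dataclass(frozen=True)
class PlantedMotif:
    seqid: str
    strand: str
    start: int
    end: int
    label: str
    orf_id: str
    sequence: str  # strand-local RNA
    stem1_bp: int
    stem2_bp: int
    linker_len: int


@dataclass(frozen=True)
class PlantedOrf:
    orf: OrfRecord
    has_rbs: bool


@dataclass(frozen=True)
class SyntheticTruth:
    motifs: tuple[PlantedMotif, ...]
    orfs: tuple[PlantedOrf, ...]
    config: SimulationConfig


def hit_from_planted(p: PlantedMotif, genome_length: int) -> AntarMotifHit:
    """Reconstruct a motif hit from planted ground truth (for classification)."""
    bp1, bp2 = p.stem1_bp, p.stem2_bp
    if p.strand == "+":
        h1_start, h2_start = p.start, p.end - (2 * bp2 + 6)
    else:
        h1_start, h2_start = p.end - (2 * bp1 + 6), p.start
    loop1 = p.sequence[bp1 : bp1 + 6]
    loop2 = p.sequence[-(bp2 + 6) : -bp2]
    h1 = Hairpin(seqid=p.seqid, strand=p.strand, outer_start=h1_start,
                 stem_bp=bp1, loop_seq=loop1)
    h2 = Hairpin(seqid=p.seqid, strand=p.strand, outer_start=h2_start,
                 stem_bp=bp2, loop_seq=loop2)
    return AntarMotifHit(
        seqid=p.seqid, strand=p.strand, start=p.start, end=p.end,
        flank_start=max(0, p.start - FLANK_NT),
        flank_end=min(genome_length, p.end + FLANK_NT),
        hairpin1=h1, hairpin2=h2, linker_len=p.linker_len,
        score=float("nan"), curation_violations=0, sequence=p.sequence,
    )


# ---------------------------------------------------------------------------
# generation


def generate_genome(config: SimulationConfig, seqid: str = "simgenome") -> GenomeRecord:
    """An i.i.d. background genome at the configured GC fraction."""
    rng = _rng_for(config.seed, f"genome:{seqid}")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length, p=probs))
    return GenomeRecord(id=seqid, sequence=seq)


def sample_motif(
    profile: MotifProfile,
    rng: np.random.Generator,
    loop_mutation_rate: float = 0.0,
    stem_mutation_rate: float = 0.0,
    compensatory: bool = True,
    stem1_bp: int | None = None,
    stem2_bp: int | None = None,
    linker_len: int | None = None,
) -> CandidateMotif:
    """Sample one motif instance: profile consensus plus controlled mutations.

    Loop positions mutate independently to a random other base.  Stem pairs
    mutate either to a random other canonical pair (compensatory, default) or
    by substituting the 3' base only, usually breaking the pair.
    """
    cons = consensus_candidate(
        profile, stem1_bp=stem1_bp, stem2_bp=stem2_bp, linker_len=linker_len
    )
    if linker_len is None:
        linker_len = len(cons.linker)
    linker = "".join(
        rng.choice(list("ACGU"), p=profile.background) for _ in range(linker_len)
    )

    def mutate_loop(loop: str) -> str:
        out = []
        for ch in loop:
            if rng.random() < loop_mutation_rate:
                out.append(rng.choice([b for b in NUCLEOTIDES if b != ch]))
            else:
                out.append(ch)
        return "".join(out)

    def mutate_stem(pairs: tuple[str, ...]) -> tuple[str, ...]:
        out = []
        for p in pairs:
            if rng.random() < stem_mutation_rate:
                if compensatory:
                    out.append(rng.choice([q for q in PAIR_TYPES if q != p]))
                else:
                    new3 = rng.choice([b for b in NUCLEOTIDES if b != p[1]])
                    out.append(p[0] + new3)
            else:
                out.append(p)
        return tuple(out)

    return CandidateMotif(
        stem1_pairs=mutate_stem(cons.stem1_pairs),
        loop1=mutate_loop(cons.loop1),
        linker=linker,
        loop2=mutate_loop(cons.loop2),
        stem2_pairs=mutate_stem(cons.stem2_pairs),
    )


def _allocate_labels(mix: tuple[float, float, float], n: int) -> list[str]:
    raw = [f * n for f in mix]
    counts = [int(x) for x in raw]
    while sum(counts) < n:
        frac = [r - c for r, c in zip(raw, counts)]
        counts[int(np.argmax(frac))] += 1
    labels = []
    for lab, c in zip(CATEGORIES, counts):
        labels.extend([lab] * c)
    return labels


_WINDOW_UP = 700    # nt of window kept upstream of the ORF start
_WINDOW_DOWN = 60   # nt kept downstream of the ORF stop


def plant_motifs_and_orfs(
    genome: GenomeRecord,
    config: SimulationConfig,
    profile: MotifProfile,
    constraints: MotifConstraints | None = None,
) -> tuple[GenomeRecord, list[OrfRecord], SyntheticTruth]:
    """Plant ORFs (with RBS) and motifs realizing the configured context mix.

    Every planted motif's intended label is verified against the context
    classifier on the emitted annotations; disagreement raises
    SimulationError.
    """
    constraints = constraints or profile.constraints
    rng = _rng_for(config.seed, "plant")
    n_orfs = config.n_orfs if config.n_orfs is not None else config.n_motifs
    n_slots = max(config.n_motifs, n_orfs)
    window_len = _WINDOW_UP + config.orf_length + _WINDOW_DOWN
    spacing = config.genome_length // (n_slots + 1)
    if spacing < window_len + 100:
        raise SimulationError(
            f"genome of {config.genome_length} nt cannot pack {n_slots} loci; "
            f"increase genome_length"
        )
    labels = _allocate_labels(config.context_mix, config.n_motifs)
    rng.shuffle(labels)

    seq = list(genome.sequence)
    orfs: list[OrfRecord] = []
    planted_orfs: list[PlantedOrf] = []
    planted: list[PlantedMotif] = []

    for i in range(n_slots):
        anchor = spacing * (i + 1)          # window start (+ frame)
        w0, w1 = anchor, anchor + window_len
        ls = _WINDOW_UP                     # ORF start, window-local
        le = ls + config.orf_length
        strand = "-" if (config.both_strands and i % 2 == 1) else "+"
        label = labels[i] if i < config.n_motifs else None

        window = list(genome.sequence[w0:w1])
        edits: list[tuple[int, str]] = [(ls, "ATG"), (le - 3, "TAA")]
        has_rbs = label != SEQUESTER
        if has_rbs:
            spacer = int(rng.integers(4, 11))
            edits.append((ls - spacer - len(config.rbs_sequence), config.rbs_sequence))

        motif_local = None
        if label is not None:
            cand = sample_motif(
                profile, rng,
                loop_mutation_rate=config.loop_mutation_rate,
                stem_mutation_rate=config.stem_mutation_rate,
                compensatory=config.compensatory_stem_mutations,
                stem1_bp=config.stem1_bp,
                stem2_bp=config.stem2_bp,
                linker_len=config.linker_len,
            )
            motif_dna = rna_to_dna(cand.sequence)
            mlen = len(motif_dna)
            if label == INTERGENIC:
                gap = int(rng.integers(30, 201))
                me = ls - gap - FLANK_NT
                msl = me - mlen
            elif label == SEQUESTER:
                me = ls - 5
                msl = me - mlen
            else:  # INSIDE_ORF
                offset = int(rng.integers(15, 91))
                msl = ls + offset
                me = msl + mlen
            edits.append((msl, motif_dna))
            motif_local = (msl, me, cand)

        for off, text in edits:
            window[off : off + len(text)] = list(text)
        window_str = "".join(window)
        if strand == "-":
            window_str = revcomp_dna(window_str)

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return w0 + a, w0 + b
            return w0 + (window_len - b), w0 + (window_len - a)

        seq[w0:w1] = list(window_str)
        g_orf = to_genomic(ls, le)
        orf = OrfRecord(seqid=genome.id, start=g_orf[0], end=g_orf[1],
                        strand=strand, orf_id=f"orf{i:03d}")
        orfs.append(orf)
        planted_orfs.append(PlantedOrf(orf=orf, has_rbs=has_rbs))

        if motif_local is not None:
            msl, me, cand = motif_local
            g_m = to_genomic(msl, me)
            planted.append(
                PlantedMotif(
                    seqid=genome.id, strand=strand, start=g_m[0], end=g_m[1],
                    label=label, orf_id=orf.orf_id, sequence=cand.sequence,
                    stem1_bp=len(cand.stem1_pairs), stem2_bp=len(cand.stem2_pairs),
                    linker_len=len(cand.linker),
                )
            )

    new_genome = GenomeRecord(id=genome.id, sequence="".join(seq))
    truth = SyntheticTruth(motifs=tuple(planted), orfs=tuple(planted_orfs),
                           config=config)
    for p in truth.motifs:
        call = classify_context(hit_from_planted(p, new_genome.length), orfs,
                                new_genome)
        if call.category != p.label:
            raise SimulationError(
                f"planted motif at {p.start} intended {p.label} but classifies "
                f"as {call.category}"
            )
    return new_genome, orfs, truth


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    precision: float
    n_planted: int
    n_hits: int
    n_recovered: int
    n_matched_hits: int


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    la, lb = a[1] - a[0], b[1] - b[0]
    return ov + tol >= 0.5 * la and ov + tol >= 0.5 * lb


def evaluate_recovery(
    truth: SyntheticTruth,
    hits: Sequence[AntarMotifHit],
    tolerance: int = 0,
) -> RecoveryReport:
    """Recall/precision of a hit set against planted ground truth.

    A planted motif is recovered when some hit on its seqid overlaps it by at
    least 50% reciprocally (within ``tolerance`` nt).
    """
    recovered = 0
    matched_hits: set[int] = set()
    for p in truth.motifs:
        found = False
        for idx, h in enumerate(hits):
            if h.seqid != p.seqid:
                continue
            if _reciprocal_overlap((p.start, p.end), (h.start, h.end), tolerance):
                matched_hits.add(idx)
                found = True
        if found:
            recovered += 1
    n_p, n_h = len(truth.motifs), len(hits)
    return RecoveryReport(
        recall=recovered / n_p if n_p else 1.0,
        precision=len(matched_hits) / n_h if n_h else 1.0,
        n_planted=n_p,
        n_hits=n_h,
        n_recovered=recovered,
        n_matched_hits=len(matched_hits),
    )


def context_confusion(
    truth: SyntheticTruth,
    calls: Sequence,
    tolerance: int = 0,
):
    """Confusion table between intended and called context labels."""
    import pandas as pd

    rows = []
    for p in truth.motifs:
        called = "UNDETECTED"
        for c in calls:
            h = c.hit
            if h.seqid == p.seqid and _reciprocal_overlap(
                (p.start, p.end), (h.start, h.end), tolerance
            ):
                called = c.category
                break
        rows.append({"intended": p.label, "called": called})
    df = pd.DataFrame(rows)
    return df.groupby(["intended", "called"]).size().unstack(fill_value=0)
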