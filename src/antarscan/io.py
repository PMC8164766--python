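"""Reading and writing of the standard formats the pipeline touches.

Coordinate contract
-------------------
Internal coordinates are 0-based half-open throughout the package.  GFF3 input
(1-based inclusive) is converted on read; TSV output is emitted 1-based
inclusive to match the convention of published supplementary tables.

Genomes are stored as DNA over {A, C, G, T, N}; U is converted to T on read.
Seed alignments are stored as gapped RNA with a dot-bracket consensus
structure that must describe exactly two hairpins, each capped by a
hexanucleotide loop and supported by at least three paired columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import DNA_ALPHABET, dna_to_rna


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomeRecord:
    """A genome (or contig) sequence over the DNA alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        """RNA view of the plus strand (T -> U)."""
        return dna_to_rna(self.sequence)

    def mononucleotide_frequencies(self) -> dict[str, float]:
        """ACGU frequencies of the plus strand, N excluded."""
        counts = {b: 0 for b in "ACGT"}
        for ch in self.sequence:
            if ch in counts:
                counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            return {b: 0.25 for b in "ACGU"}
        return {
            "A": counts["A"] / total,
            "C": counts["C"] / total,
            "G": counts["G"] / total,
            "U": counts["T"] / total,
        }


@dataclass(frozen=True)
class OrfRecord:
    """An annotated ORF. Coordinates are 0-based half-open on the + frame."""

    seqid: str
    start: int
    end: int
    strand: str
    orf_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"ORF {self.orf_id}: invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"ORF {self.orf_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class HairpinColumns:
    """Column indices of one consensus hairpin: stem pairs outer->inner plus loop."""

    pairs: tuple[tuple[int, int], ...]
    loop: tuple[int, ...]

    @property
    def outer_left(self) -> int:
        return self.pairs[0][0]

    @property
    def outer_right(self) -> int:
        return self.pairs[0][1]


@dataclass(frozen=True)
class SeedAlignment:
    """A gapped RNA alignment with a two-hairpin consensus structure."""

    rows: tuple[tuple[str, str], ...]
    ss_cons: str
    hairpin1: HairpinColumns = field(repr=False, default=None)  # type: ignore[assignment]
    hairpin2: HairpinColumns = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def columns(self) -> int:
        return len(self.ss_cons)

    @property
    def linker_columns(self) -> tuple[int, ...]:
        return tuple(range(self.hairpin1.outer_right + 1, self.hairpin2.outer_left))

    def degapped(self) -> list[tuple[str, str]]:
        return [(name, seq.replace("-", "")) for name, seq in self.rows]


# ---------------------------------------------------------------------------
# consensus-structure parsing

_OPEN = {"<": "(", "(": "(", "[": "("}
_CLOSE = {">": ")", ")": ")", "]": ")"}


def normalize_structure(ss: str) -> str:
    """Map bracket alphabets <>, (), [] to () and everything unpaired to '.'."""
    out = []
    for ch in ss:
        if ch in _OPEN:
            out.append("(")
        elif ch in _CLOSE:
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


def parse_pairs(ss: str) -> list[tuple[int, int]]:
    """Base-paired column pairs of a normalized dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(ss):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced structure at column {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise FormatError(f"unbalanced structure: {len(stack)} unclosed brackets")
    return sorted(pairs)


def parse_two_hairpins(ss: str) -> tuple[HairpinColumns, HairpinColumns]:
    """Split a normalized structure into exactly two hairpins.

    Each hairpin must have >= 3 paired columns and an unpaired loop of exactly
    6 columns inside its innermost pair; the two hairpins must not nest or
    cross.
    """
    ss = normalize_structure(ss)
    pairs = parse_pairs(ss)
    if not pairs:
        raise FormatError("consensus structure contains no base pairs")
    # group pairs into maximal non-nested components (hairpins)
    groups: list[list[tuple[int, int]]] = []
    for p in pairs:
        placed = False
        for g in groups:
            lo, hi = g[0]
            if lo <= p[0] and p[1] <= hi:
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])
    if len(groups) != 2:
        raise FormatError(
            f"consensus structure must contain exactly 2 hairpins, "
            f"parsed {len(groups)}: {[g[0] for g in groups]}"
        )
    hairpins = []
    for g in groups:
        g.sort()
        if len(g) < 3:
            raise FormatError(
                f"hairpin at columns {g[0]} has only {len(g)} paired columns (need >=3)"
            )
        inner_lo, inner_hi = g[-1]
        loop = tuple(range(inner_lo + 1, inner_hi))
        if len(loop) != 6:
            raise FormatError(
                f"hairpin at columns {g[0]} has a loop of {len(loop)} columns (need 6)"
            )
        hairpins.append(HairpinColumns(pairs=tuple(g), loop=loop))
    h1, h2 = sorted(hairpins, key=lambda h: h.outer_left)
    if h2.outer_left <= h1.outer_right:
        raise FormatError("hairpins overlap or nest in the consensus structure")
    return h1, h2


def make_seed_alignment(rows: Sequence[tuple[str, str]], ss_cons: str) -> SeedAlignment:
    """Validate and assemble a SeedAlignment from gapped rows and SS_cons."""
    if not rows:
        raise FormatError("seed alignment has no rows")
    ss = normalize_structure(ss_cons)
    ncol = len(ss)
    norm_rows = []
    for name, seq in rows:
        seq = seq.upper().replace("T", "U").replace(".", "-")
        if len(seq) != ncol:
            raise FormatError(
                f"row {name!r} has {len(seq)} columns, SS_cons has {ncol}"
            )
        bad = set(seq) - set("ACGU-N")
        if bad:
            raise FormatError(f"row {name!r} contains invalid characters {sorted(bad)}")
        norm_rows.append((name, seq))
    h1, h2 = parse_two_hairpins(ss)
    return SeedAlignment(rows=tuple(norm_rows), ss_cons=ss, hairpin1=h1, hairpin2=h2)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a DNA FASTA into GenomeRecords (uppercased, U -> T)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        for i, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise FormatError(
                    f"record {rec.id!r}: non-IUPAC character {ch!r} at position {i + 1}"
                )
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_gff3(
    path: str | Path, feature_types: Sequence[str] = ("CDS",)
) -> list[OrfRecord]:
    """Read ORF annotations from GFF3, converting to 0-based half-open."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    orfs = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if feat.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: feature {feat.id} has unsupported strand {feat.strand!r}"
                )
            if feat.start > feat.end:
                raise FormatError(
                    f"{path}: feature {feat.id} has start > end "
                    f"({feat.start} > {feat.end})"
                )
            orf_id = feat.attributes.get("ID", [feat.id])[0]
            orfs.append(
                OrfRecord(
                    seqid=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    orf_id=orf_id,
                )
            )
    orfs.sort(key=lambda o: (o.seqid, o.start, o.end))
    return orfs


def write_gff3(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """Write OrfRecords as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.seqid}\tantarscan\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.orf_id}\n"
            )


def read_stockholm(path: str | Path) -> SeedAlignment:
    """Read a Stockholm 1.0 seed alignment with a #=GC SS_cons line."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as Stockholm ({exc})") from exc
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise FormatError(f"{path}: missing #=GC SS_cons line")
    rows = [(rec.id, str(rec.seq)) for rec in aln]
    return make_seed_alignment(rows, ss)


def write_stockholm(seed: SeedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(name) for name, _ in seed.rows) + 2
        width = max(width, len("#=GC SS_cons") + 2)
        for name, seq in seed.rows:
            fh.write(f"{name:<{width}}{seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{seed.ss_cons}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# tabular output

HIT_COLUMNS = [
    "seqid",
    "start",
    "end",
    "strand",
    "score",
    "stem1_start",
    "stem1_bp",
    "loop1",
    "linker_len",
    "loop2",
    "stem2_start",
    "stem2_bp",
    "curation_violations",
    "flank_start",
    "flank_end",
    "sequence",
]

CONTEXT_COLUMNS = HIT_COLUMNS + [
    "category",
    "orf_id",
    "distance_to_start",
    "rbs_start",
    "rbs_end",
    "rbs_sequence",
    "alt_orf",
    "terminator_overlap",
]


def _hit_row(hit) -> dict:
    return {
        "seqid": hit.seqid,
        "start": hit.start + 1,
        "end": hit.end,
        "strand": hit.strand,
        "score": round(hit.score, 4),
        "stem1_start": hit.hairpin1.outer_start + 1,
        "stem1_bp": hit.hairpin1.stem_bp,
        "loop1": hit.hairpin1.loop_seq,
        "linker_len": hit.linker_len,
        "loop2": hit.hairpin2.loop_seq,
        "stem2_start": hit.hairpin2.outer_start + 1,
        "stem2_bp": hit.hairpin2.stem_bp,
        "curation_violations": hit.curation_violations,
        "flank_start": hit.flank_start + 1,
        "flank_end": hit.flank_end,
        "sequence": hit.sequence,
    }


def _context_row(call) -> dict:
    row = _hit_row(call.hit)
    row["category"] = call.category
    row["orf_id"] = call.orf.orf_id if call.orf is not None else ""
    row["distance_to_start"] = (
        call.distance_to_start if call.distance_to_start is not None else ""
    )
    if call.rbs is not None:
        row["rbs_start"] = call.rbs.start + 1
        row["rbs_end"] = call.rbs.end
        row["rbs_sequence"] = call.rbs.sequence
    else:
        row["rbs_start"] = row["rbs_end"] = row["rbs_sequence"] = ""
    row["alt_orf"] = call.alt_orf.orf_id if call.alt_orf is not None else ""
    row["terminator_overlap"] = call.terminator_overlap
    return row


def write_hits_tsv(hits: Sequence, path: str | Path) -> None:
    """Write motif hits or context calls as TSV (1-based inclusive coordinates).

    Rows are sorted by (seqid, start) with descending score as tiebreak, so the
    output is deterministic for identical inputs.
    """
    is_context = bool(hits) and hasattr(hits[0], "category")
    columns = CONTEXT_COLUMNS if is_context else HIT_COLUMNS
    rows = [(_context_row if is_context else _hit_row)(h) for h in hits]
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        df = df.sort_values(
            ["seqid", "start", "score"], ascending=[True, True, False]
        )
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list:
    """Read a hits TSV written by write_hits_tsv back into AntarMotifHit objects."""
    from .scan import AntarMotifHit, Hairpin

    df = pd.read_csv(path, sep="\t", dtype={"seqid": str})
    hits = []
    for row in df.itertuples(index=False):
        h1 = Hairpin(
            seqid=row.seqid,
            strand=row.strand,
            outer_start=int(row.stem1_start) - 1,
            stem_bp=int(row.stem1_bp),
            loop_seq=row.loop1,
        )
        h2 = Hairpin(
            seqid=row.seqid,
            strand=row.strand,
            outer_start=int(row.stem2_start) - 1,
            stem_bp=int(row.stem2_bp),
            loop_seq=row.loop2,
        )
        hits.append(
            AntarMotifHit(
                seqid=row.seqid,
                strand=row.strand,
                start=int(row.start) - 1,
                end=int(row.end),
                flank_start=int(row.flank_start) - 1,
                flank_end=int(row.flank_end),
                hairpin1=h1,
                hairpin2=h2,
                linker_len=int(row.linker_len),
                score=float(row.score),
                curation_violations=int(row.curation_violations),
                sequence=row.sequence,
            )
        )
    return hits


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
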