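"""Probabilistic model of the ANTAR-target dual stem-loop RNA family.

The family consists of two hairpins separated by a short linker.  Each hairpin
carries a hexanucleotide loop whose first and fourth positions are conserved as
adenine (A1) and guanine (G4); each stem has at least three canonical base
pairs (wobble G-U included); the linker spans 2-25 nt.

A :class:`MotifProfile` is estimated from a seed alignment and scores
candidates in bits: the sum of per-position loop log-odds, per-pair stem
log-odds (pooled across stem positions), and a linker-length log-odds term
against a uniform length prior.  The scale is this package's own; it plays the
filtering role of a covariance-model bit score but is not comparable to one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from ._alphabet import CANONICAL_PAIRS, NT_INDEX, NUCLEOTIDES, PAIR_TYPES
from .io import SeedAlignment

PROFILE_SCHEMA = "antarscan-profile/1"

LINKER_MIN_DEFAULT = 2
LINKER_MAX_DEFAULT = 25


class ContractError(ValueError):
    """A candidate handed to the scorer violated the structural contract."""


@dataclass(frozen=True)
class MotifConstraints:
    """Hard structural/curation rules for the dual stem-loop motif."""

    loop_length: int = 6
    min_stem_bp: int = 3
    max_stem_bp: int = 10
    linker_min: int = LINKER_MIN_DEFAULT
    linker_max: int = LINKER_MAX_DEFAULT
    #: (0-based position within each loop, required base)
    conserved_loop_positions: tuple[tuple[int, str], ...] = ((0, "A"), (3, "G"))
    #: allowed mismatches over all conserved loop positions, per motif
    max_conserved_position_violations: int = 1

    def __post_init__(self) -> None:
        if self.loop_length != 6:
            raise ValueError("loop_length is fixed at 6 nt for this family")
        if self.min_stem_bp < 3:
            raise ValueError("min_stem_bp must be >= 3")
        if self.max_stem_bp < self.min_stem_bp:
            raise ValueError("max_stem_bp must be >= min_stem_bp")
        if not (self.linker_min >= 2 and self.linker_max <= 25):
            raise ValueError("linker bounds must lie within [2, 25]")

    @property
    def min_motif_length(self) -> int:
        return 2 * (2 * self.min_stem_bp + self.loop_length) + self.linker_min


@dataclass(frozen=True)
class CandidateMotif:
    """One structural decomposition: stem1/loop1/linker/loop2/stem2.

    Stem pairs are 2-character strings (5' base + 3' base), ordered outer to
    inner.  ``span`` is the (start, end) of the dual stem loop on the named
    sequence, 0-based half-open, in the frame the candidate was found in.
    """

    stem1_pairs: tuple[str, ...]
    loop1: str
    linker: str
    loop2: str
    stem2_pairs: tuple[str, ...]
    seqid: str = ""
    span: tuple[int, int] = (0, 0)
    strand: str = "+"

    @property
    def sequence(self) -> str:
        left1 = "".join(p[0] for p in self.stem1_pairs)
        right1 = "".join(p[1] for p in reversed(self.stem1_pairs))
        left2 = "".join(p[0] for p in self.stem2_pairs)
        right2 = "".join(p[1] for p in reversed(self.stem2_pairs))
        return left1 + self.loop1 + right1 + self.linker + left2 + self.loop2 + right2

    @property
    def length(self) -> int:
        return (
            2 * len(self.stem1_pairs)
            + 2 * len(self.stem2_pairs)
            + 12
            + len(self.linker)
        )


def validate_candidate(cand: CandidateMotif, constraints: MotifConstraints) -> None:
    """Raise ContractError unless the candidate satisfies structural bounds."""
    for label, pairs in (("stem1", cand.stem1_pairs), ("stem2", cand.stem2_pairs)):
        if not (constraints.min_stem_bp <= len(pairs) <= constraints.max_stem_bp):
            raise ContractError(f"{label} has {len(pairs)} bp, outside bounds")
        for p in pairs:
            if p not in CANONICAL_PAIRS:
                raise ContractError(f"{label} contains non-canonical pair {p!r}")
    for label, loop in (("loop1", cand.loop1), ("loop2", cand.loop2)):
        if len(loop) != constraints.loop_length:
            raise ContractError(f"{label} has length {len(loop)}, expected 6")
        if set(loop) - set(NUCLEOTIDES):
            raise ContractError(f"{label} contains non-ACGU characters")
    if not (constraints.linker_min <= len(cand.linker) <= constraints.linker_max):
        raise ContractError(f"linker length {len(cand.linker)} outside bounds")


def count_curation_violations(
    cand: CandidateMotif, constraints: MotifConstraints
) -> list[str]:
    """Violated conserved-loop-position rules (A1/G4 in both loops)."""
    reasons = []
    for loop_name, loop in (("loop1", cand.loop1), ("loop2", cand.loop2)):
        for pos, base in constraints.conserved_loop_positions:
            if loop[pos] != base:
                reasons.append(
                    f"{loop_name} position {pos + 1}: expected {base}, found {loop[pos]}"
                )
    return reasons


def curation_filter(
    cand: CandidateMotif, constraints: MotifConstraints | None = None
) -> tuple[bool, list[str]]:
    """Apply the hard curation rule: at most ``max_conserved_position_violations``
    mismatches over the four conserved loop positions, per motif."""
    constraints = constraints or MotifConstraints()
    reasons = count_curation_violations(cand, constraints)
    return len(reasons) <= constraints.max_conserved_position_violations, reasons


# ---------------------------------------------------------------------------
# profile


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    if isinstance(background, dict):
        background = [background[b] for b in NUCLEOTIDES]
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.all(bg > 0):
        raise ValueError("background must be 4 positive frequencies over ACGU")
    return bg / bg.sum()


def _pair_background(bg: np.ndarray) -> np.ndarray:
    """Background distribution over the 6 canonical pair types."""
    raw = np.array([bg[NT_INDEX[p[0]]] * bg[NT_INDEX[p[1]]] for p in PAIR_TYPES])
    return raw / raw.sum()


@dataclass(frozen=True)
class MotifProfile:
    """Log-odds description of the family, all terms in bits.

    ``loop_logodds``: two (6, 4) tables over ACGU.  ``stem_pair_logodds``: two
    length-6 vectors over PAIR_TYPES, pooled across stem positions.
    ``linker_length_logprob``: log2 probabilities over lengths 2..25.
    """

    loop_logodds: tuple[np.ndarray, np.ndarray]
    stem_pair_logodds: tuple[np.ndarray, np.ndarray]
    #: per-stem log2 probabilities over stem depths [min_stem_bp..max_stem_bp]
    stem_length_logprob: tuple[np.ndarray, np.ndarray]
    linker_length_logprob: np.ndarray
    background: np.ndarray
    constraints: MotifConstraints = field(default_factory=MotifConstraints)

    @property
    def linker_lengths(self) -> range:
        return range(self.constraints.linker_min, self.constraints.linker_max + 1)

    @property
    def stem_depths(self) -> range:
        return range(self.constraints.min_stem_bp, self.constraints.max_stem_bp + 1)

    def linker_term(self, length: int) -> float:
        """log2(P(linker length) / uniform over the allowed range)."""
        n_lengths = len(self.linker_lengths)
        idx = length - self.constraints.linker_min
        return float(self.linker_length_logprob[idx] + math.log2(n_lengths))

    def stem_length_term(self, which: int, depth: int) -> float:
        """log2(P(stem depth) / uniform over the allowed range)."""
        n_depths = len(self.stem_depths)
        idx = depth - self.constraints.min_stem_bp
        return float(self.stem_length_logprob[which][idx] + math.log2(n_depths))

    def _best_stem(self, which: int) -> tuple[int, float]:
        """(depth, total stem term) maximizing depth * best-pair + length term."""
        m = float(self.stem_pair_logodds[which].max())
        best = None
        for k in self.stem_depths:
            total = k * m + self.stem_length_term(which, k)
            if best is None or total > best[1]:
                best = (k, total)
        return best

    @property
    def max_score(self) -> float:
        total = 0.0
        for table in self.loop_logodds:
            total += float(table.max(axis=1).sum())
        for which in (0, 1):
            total += self._best_stem(which)[1]
        total += max(self.linker_term(ln) for ln in self.linker_lengths)
        return total

    # -- consensus -----------------------------------------------------------

    def consensus_loops(self) -> tuple[str, str]:
        return tuple(
            "".join(NUCLEOTIDES[int(i)] for i in table.argmax(axis=1))
            for table in self.loop_logodds
        )

    def consensus_stem_pairs(self, which: int, stem_bp: int | None = None) -> tuple[str, ...]:
        vec = self.stem_pair_logodds[which]
        best = PAIR_TYPES[int(vec.argmax())]
        if stem_bp is None:
            stem_bp = self._best_stem(which)[0]
        return tuple([best] * stem_bp)

    def consensus_linker_length(self) -> int:
        return int(self.linker_length_logprob.argmax()) + self.constraints.linker_min

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": PROFILE_SCHEMA,
            "loop_logodds": [t.tolist() for t in self.loop_logodds],
            "stem_pair_logodds": [v.tolist() for v in self.stem_pair_logodds],
            "stem_length_logprob": [v.tolist() for v in self.stem_length_logprob],
            "linker_length_logprob": self.linker_length_logprob.tolist(),
            "background": self.background.tolist(),
            "constraints": {
                "loop_length": self.constraints.loop_length,
                "min_stem_bp": self.constraints.min_stem_bp,
                "max_stem_bp": self.constraints.max_stem_bp,
                "linker_min": self.constraints.linker_min,
                "linker_max": self.constraints.linker_max,
                "conserved_loop_positions": [
                    list(p) for p in self.constraints.conserved_loop_positions
                ],
                "max_conserved_position_violations": (
                    self.constraints.max_conserved_position_violations
                ),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MotifProfile":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != PROFILE_SCHEMA:
            raise ValueError(f"unsupported profile schema {payload.get('schema')!r}")
        c = payload["constraints"]
        constraints = MotifConstraints(
            loop_length=c["loop_length"],
            min_stem_bp=c["min_stem_bp"],
            max_stem_bp=c["max_stem_bp"],
            linker_min=c["linker_min"],
            linker_max=c["linker_max"],
            conserved_loop_positions=tuple(
                (int(p), str(b)) for p, b in c["conserved_loop_positions"]
            ),
            max_conserved_position_violations=c["max_conserved_position_violations"],
        )
        return cls(
            loop_logodds=tuple(np.array(t) for t in payload["loop_logodds"]),
            stem_pair_logodds=tuple(np.array(v) for v in payload["stem_pair_logodds"]),
            stem_length_logprob=tuple(
                np.array(v) for v in payload["stem_length_logprob"]
            ),
            linker_length_logprob=np.array(payload["linker_length_logprob"]),
            background=np.array(payload["background"]),
            constraints=constraints,
        )


def build_profile(
    seed: SeedAlignment,
    background=None,
    pseudocount: float = 1.0,
    constraints: MotifConstraints | None = None,
) -> MotifProfile:
    """Estimate a MotifProfile from a validated seed alignment.

    Loop tables come from per-column counts with a background-weighted Laplace
    pseudocount; stem tables from the canonical pairs observed in paired
    columns, pooled within each stem; the linker-length distribution from the
    observed (ungapped) linker lengths of each row.
    """
    if len(seed.rows) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    constraints = constraints or MotifConstraints()
    bg = _as_background(background)
    pair_bg = _pair_background(bg)

    loop_tables = []
    for hp in (seed.hairpin1, seed.hairpin2):
        table = np.zeros((6, 4))
        for k, col in enumerate(hp.loop):
            counts = np.zeros(4)
            for _, row in seed.rows:
                ch = row[col]
                if ch in NT_INDEX:
                    counts[NT_INDEX[ch]] += 1
            freqs = (counts + pseudocount * bg) / (counts.sum() + pseudocount)
            table[k] = np.log2(freqs / bg)
        loop_tables.append(table)

    stem_vectors = []
    stem_len_vectors = []
    n_depths = constraints.max_stem_bp - constraints.min_stem_bp + 1
    for hp in (seed.hairpin1, seed.hairpin2):
        counts = np.zeros(6)
        row_depth = {name: 0 for name, _ in seed.rows}
        for i, j in hp.pairs:
            col_hits = 0
            for name, row in seed.rows:
                pair = row[i] + row[j]
                if pair in CANONICAL_PAIRS:
                    counts[PAIR_TYPES.index(pair)] += 1
                    row_depth[name] += 1
                    col_hits += 1
            if col_hits == 0:
                raise ValueError(
                    f"paired columns ({i}, {j}) have no canonical pair in any row"
                )
        freqs = (counts + pseudocount * pair_bg) / (counts.sum() + pseudocount)
        stem_vectors.append(np.log2(freqs / pair_bg))
        # per-row pairable depth -> stem-depth distribution, clipped to bounds
        dcounts = np.zeros(n_depths)
        for depth in row_depth.values():
            depth = min(max(depth, constraints.min_stem_bp), constraints.max_stem_bp)
            dcounts[depth - constraints.min_stem_bp] += 1
        dprobs = (dcounts + pseudocount / n_depths) / (dcounts.sum() + pseudocount)
        stem_len_vectors.append(np.log2(dprobs))

    linker_cols = seed.linker_columns
    n_lengths = constraints.linker_max - constraints.linker_min + 1
    lcounts = np.zeros(n_lengths)
    for name, row in seed.rows:
        length = sum(1 for c in linker_cols if row[c] != "-")
        if not (constraints.linker_min <= length <= constraints.linker_max):
            raise ValueError(
                f"row {name!r} has linker length {length}, outside "
                f"[{constraints.linker_min}, {constraints.linker_max}]"
            )
        lcounts[length - constraints.linker_min] += 1
    lprobs = (lcounts + pseudocount / n_lengths) / (lcounts.sum() + pseudocount)

    return MotifProfile(
        loop_logodds=(loop_tables[0], loop_tables[1]),
        stem_pair_logodds=(stem_vectors[0], stem_vectors[1]),
        stem_length_logprob=(stem_len_vectors[0], stem_len_vectors[1]),
        linker_length_logprob=np.log2(lprobs),
        background=bg,
        constraints=constraints,
    )


def score_candidate(profile: MotifProfile, cand: CandidateMotif) -> float:
    """Bit score of a structurally valid candidate against the profile.

    Sum of per-position loop log-odds, per-pair stem log-odds, per-stem depth
    log-odds and the linker-length log-odds, all against the background model.
    """
    validate_candidate(cand, profile.constraints)
    total = 0.0
    for table, loop in zip(profile.loop_logodds, (cand.loop1, cand.loop2)):
        for k, ch in enumerate(loop):
            total += float(table[k, NT_INDEX[ch]])
    for which, pairs in enumerate((cand.stem1_pairs, cand.stem2_pairs)):
        vec = profile.stem_pair_logodds[which]
        for p in pairs:
            total += float(vec[PAIR_TYPES.index(p)])
        total += profile.stem_length_term(which, len(pairs))
    total += profile.linker_term(len(cand.linker))
    return total


def consensus_candidate(
    profile: MotifProfile,
    stem1_bp: int | None = None,
    stem2_bp: int | None = None,
    linker_len: int | None = None,
    linker_seq: str | None = None,
) -> CandidateMotif:
    """The argmax candidate of the profile (linker content is unscored filler)."""
    loop1, loop2 = profile.consensus_loops()
    s1 = profile.consensus_stem_pairs(0, stem1_bp)
    s2 = profile.consensus_stem_pairs(1, stem2_bp)
    if linker_len is None:
        linker_len = profile.consensus_linker_length()
    if linker_seq is None:
        filler = NUCLEOTIDES[int(profile.background.argmax())]
        linker_seq = filler * linker_len
    if len(linker_seq) != linker_len:
        raise ValueError("linker_seq length disagrees with linker_len")
    return CandidateMotif(
        stem1_pairs=s1, loop1=loop1, linker=linker_seq, loop2=loop2, stem2_pairs=s2
    )


def with_lenient_curation(constraints: MotifConstraints) -> MotifConstraints:
    """The per-loop reading of "a single point variation": up to 2 per motif."""
    return replace(constraints, max_conserved_position_violations=2)
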