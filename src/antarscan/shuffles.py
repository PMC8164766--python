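"""Composition-preserving shuffles, null calibration and false-positive assay.

Mononucleotide shuffles are uniform permutations.  Dinucleotide shuffles use
the Eulerian-trail construction: the sequence is a trail in the multigraph
whose edges are its dinucleotides; sampling a uniformly random trail with the
same endpoints preserves the full dinucleotide count vector exactly (and the
first and last residues).  Uniformity comes from rejection-sampling a random
last-edge arborescence into the end vertex and randomizing the remaining edge
orders.

Score thresholds are calibrated as a quantile of the null candidate-score
distribution obtained by running the scanner's candidate enumeration over
every shuffled sequence.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motif import MotifConstraints, MotifProfile
from .scan import enumerate_candidate_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShuffleSet:
    source_id: str
    mode: str
    n: int
    seed: int
    sequences: tuple[str, ...]


@dataclass(frozen=True)
class FpAssayResult:
    n_sequences: int
    n_sequences_with_hit: int
    n_hits_total: int

    @property
    def rate(self) -> float:
        return self.n_sequences_with_hit / self.n_sequences if self.n_sequences else 0.0


def _rng_for(seed: int, source_id: str, stream: int = 0) -> np.random.Generator:
    """Stable per-source RNG stream derived by hashing (seed, source_id, stream)."""
    digest = hashlib.sha256(f"{seed}:{source_id}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def shuffle_mono(seq: str, n: int, seed: int = 0, source_id: str = "") -> ShuffleSet:
    """n independent uniform permutations of the sequence."""
    if len(seq) < 2:
        raise ValueError("sequence too short to shuffle")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng_for(seed, source_id or seq[:16])
    chars = np.array(list(seq))
    out = ["".join(chars[rng.permutation(len(chars))]) for _ in range(n)]
    return ShuffleSet(source_id=source_id, mode="mono", n=n, seed=seed,
                      sequences=tuple(out))


def _dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def _euler_shuffle_once(seq: str, rng: np.random.Generator) -> str:
    """One uniform Eulerian-trail shuffle preserving dinucleotide counts."""
    n = len(seq)
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    start, end = seq[0], seq[-1]
    vertices = sorted(adj)
    interior = [v for v in vertices if v != end]
    if not interior:
        # all edges leave the end vertex (e.g. homopolymer): single-trail cases
        interior = []
    # sample a last-edge per interior vertex until they form an arborescence
    # rooted at the end vertex
    for _ in range(10000):
        last = {v: adj[v][rng.integers(len(adj[v]))] for v in interior}
        ok = True
        for v in interior:
            seen = {v}
            cur = v
            while cur != end:
                cur = last.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - cannot happen for trails derived from a sequence
        raise RuntimeError("failed to sample an Eulerian arborescence")
    order: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v in last:
            edges.remove(last[v])
        perm = [edges[i] for i in rng.permutation(len(edges))] if edges else []
        if v in last:
            perm.append(last[v])
        order[v] = perm
    ptr = {v: 0 for v in vertices}
    walk = [start]
    for _ in range(n - 1):
        v = walk[-1]
        walk.append(order[v][ptr[v]])
        ptr[v] += 1
    result = "".join(walk)
    assert _dinucleotide_counts(result) == _dinucleotide_counts(seq)
    return result


def shuffle_di(seq: str, n: int, seed: int = 0, source_id: str = "") -> ShuffleSet:
    """n dinucleotide-preserving shuffles (exact count preservation).

    The first and last residues are preserved by construction.  Sequences
    admitting only one trail are returned unchanged (logged).
    """
    if len(seq) < 3:
        raise ValueError("sequence too short for a dinucleotide shuffle")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    identical = 0
    for i in range(n):
        rng = _rng_for(seed, source_id or seq[:16], stream=i)
        s = _euler_shuffle_once(seq, rng)
        if s == seq:
            identical += 1
        out.append(s)
    if identical == n:
        logger.info(
            "shuffle_di(%s): sequence admits a single Eulerian trail; "
            "all %d shuffles identical to the source", source_id or "<anon>", n,
        )
    return ShuffleSet(source_id=source_id, mode="di", n=n, seed=seed,
                      sequences=tuple(out))


def build_negative_set(
    seeds: Sequence[tuple[str, str]],
    per_seq: int,
    mode: str = "di",
    seed: int = 0,
) -> list[ShuffleSet]:
    """Shuffle every seed sequence ``per_seq`` times (the negative-control set).

    30 seeds at 500 shuffles each give the canonical 15,000-sequence control.
    """
    if not seeds:
        raise ValueError("no seed sequences given")
    if per_seq < 1:
        raise ValueError("per_seq must be >= 1")
    if mode not in ("mono", "di"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    shuffler = shuffle_di if mode == "di" else shuffle_mono
    return [
        shuffler(seq, per_seq, seed=seed, source_id=name) for name, seq in seeds
    ]


def consensus_null_set(
    profile: MotifProfile, n: int = 5000, seed: int = 0
) -> tuple[str, ...]:
    """Dinucleotide-preserving shuffles of the profile's consensus motif.

    The composition-matched decoy set used by default to calibrate the score
    threshold: its candidate-score tail dominates the genomic background's,
    so a quantile of it cleanly separates motifs from chance structure.
    """
    from .motif import consensus_candidate

    cons = consensus_candidate(profile)
    return shuffle_di(cons.sequence, n, seed=seed,
                      source_id="consensus-null").sequences


def negative_set_fasta_records(sets: Sequence[ShuffleSet]):
    """(header, sequence) pairs with provenance headers for FASTA export."""
    for ss in sets:
        for i, seq in enumerate(ss.sequences):
            yield f"{ss.source_id}|{ss.mode}|shuf{i}", seq


def null_candidate_scores(
    profile: MotifProfile,
    null_sequences: Sequence[str],
    constraints: MotifConstraints | None = None,
) -> tuple[list[float], int]:
    """Pooled candidate scores over the null set, plus the count of null
    sequences yielding no structural candidate."""
    constraints = constraints or profile.constraints
    scores: list[float] = []
    empty = 0
    for seq in null_sequences:
        s = enumerate_candidate_scores(seq, profile, constraints)
        if not s:
            empty += 1
        scores.extend(s)
    if empty:
        logger.info("%d of %d null sequences yielded no candidates",
                    empty, len(null_sequences))
    return scores, empty


def calibrate_threshold(
    profile: MotifProfile,
    null_sequences: Sequence[str],
    quantile: float = 0.999,
    constraints: MotifConstraints | None = None,
) -> float:
    """Score threshold = the stated quantile of the null candidate-score
    distribution (default 99.9th percentile)."""
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    scores, _ = null_candidate_scores(profile, null_sequences, constraints)
    if not scores:
        raise ValueError(
            "null set produced no candidate scores; supply more or longer "
            "null sequences"
        )
    return float(np.quantile(np.array(scores), quantile, method="higher"))


def fp_assay(
    profile: MotifProfile,
    null_sequences: Sequence[str],
    min_bits: float,
    constraints: MotifConstraints | None = None,
) -> FpAssayResult:
    """False-positive assay: null sequences with >= 1 hit at the threshold."""
    constraints = constraints or profile.constraints
    n_with = 0
    n_hits = 0
    for seq in null_sequences:
        surviving = [
            s for s in enumerate_candidate_scores(seq, profile, constraints)
            if s >= min_bits
        ]
        if surviving:
            n_with += 1
        n_hits += len(surviving)
    return FpAssayResult(
        n_sequences=len(null_sequences),
        n_sequences_with_hit=n_with,
        n_hits_total=n_hits,
    )
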