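"""Clustering, consensus-structure conservation, folding and covariation.

Sequences are clustered by single linkage on a pairwise-identity graph swept
over identity cutoffs (clusters of size < 2 are discarded).  Folding uses a
weighted base-pair-maximization model (G-C = 3, A-U = 2, G-U = 1, minimum
loop 3 nt, no pseudoknots); energies are in surrogate stability units, more
negative = more stable — they are deliberately not Turner free energies.  The
structure conservation index (SCI) is the ratio of the consensus folding
energy of an alignment (pair weights scaled by the fraction of rows able to
pair) to the mean folding energy of its individual rows; the folding z-score
standardizes a sequence's energy against composition-preserving shuffles,
negative values indicating unusually stable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._alphabet import CANONICAL_PAIRS, NUCLEOTIDES
from .io import normalize_structure, parse_pairs

PAIR_WEIGHT = {"GC": 3.0, "CG": 3.0, "AU": 2.0, "UA": 2.0, "GU": 1.0, "UG": 1.0}
MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    structure: str
    energy: float


@dataclass(frozen=True)
class ConservationStats:
    loop1_A1_fraction: float
    loop1_G4_fraction: float
    loop2_A1_fraction: float
    loop2_G4_fraction: float
    mean_stem_pair_conservation: float


@dataclass
class ClusterStats:
    members: list[str]
    alignment: list[tuple[str, str]]
    consensus_sequence: str
    consensus_structure: str
    consensus_energy: float
    mean_individual_energy: float
    sci: float


@dataclass
class ClusterReport:
    cutoff: float
    clusters: list[list[str]]
    singletons_discarded: int
    stats: list[ClusterStats] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pairwise identity & clustering


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Inputs may be gapped; gaps are stripped before aligning.
    """
    a = a.replace("-", "").upper()
    b = b.replace("-", "").upper()
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    aln = _make_aligner().align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


def cluster_at_identity(
    seqs: Sequence[tuple[str, str]],
    cutoff: float,
    with_stats: bool = True,
    identity_matrix: np.ndarray | None = None,
) -> ClusterReport:
    """Single-linkage clusters of sequences at an identity cutoff.

    Two sequences join a cluster when their identity is >= cutoff; connected
    components of size >= 2 are reported, singletons are counted and
    discarded.  ``identity_matrix`` may be supplied to reuse computed
    identities across a cutoff sweep.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to cluster")
    ids = [name for name, _ in seqs]
    n = len(seqs)
    if identity_matrix is None:
        identity_matrix = identity_matrix_of(seqs)
    adj = (identity_matrix >= cutoff).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    clusters = [sorted(g) for g in groups.values() if len(g) >= 2]
    clusters.sort(key=lambda g: (-len(g), ids[g[0]]))
    singles = sum(1 for g in groups.values() if len(g) < 2)
    report = ClusterReport(
        cutoff=cutoff,
        clusters=[[ids[i] for i in g] for g in clusters],
        singletons_discarded=singles,
    )
    if with_stats:
        for g in clusters:
            aln = star_align([seqs[i] for i in g])
            rows = [seq for _, seq in aln]
            sci, cons_seq, cons_struct, cons_e, mean_e = compute_sci(
                rows, full=True
            )
            report.stats.append(
                ClusterStats(
                    members=[ids[i] for i in g],
                    alignment=aln,
                    consensus_sequence=cons_seq,
                    consensus_structure=cons_struct,
                    consensus_energy=cons_e,
                    mean_individual_energy=mean_e,
                    sci=sci,
                )
            )
    return report


def identity_matrix_of(seqs: Sequence[tuple[str, str]]) -> np.ndarray:
    n = len(seqs)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(seqs[i][1], seqs[j][1])
    return mat


def sweep_identity(
    seqs: Sequence[tuple[str, str]],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.30, 0.601, 0.05), 2)),
    with_stats: bool = False,
) -> list[ClusterReport]:
    """Cluster at each cutoff of a sweep (default 0.30 to 0.60)."""
    mat = identity_matrix_of(seqs)
    return [
        cluster_at_identity(seqs, c, with_stats=with_stats, identity_matrix=mat)
        for c in cutoffs
    ]


def star_align(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Reference-projected multiple alignment.

    Rows are aligned pairwise to the longest member (ties: lexicographically
    smallest) and projected onto its coordinates; insertions relative to the
    reference are dropped.  Adequate for column statistics of tight clusters.
    """
    ref_name, ref = max(seqs, key=lambda p: (len(p[1]), p[1]))
    aligner = _make_aligner()
    out = []
    for name, seq in seqs:
        if seq == ref:
            out.append((name, seq))
            continue
        aln = aligner.align(ref, seq)[0]
        ga, gb = str(aln[0]), str(aln[1])
        projected = [y for x, y in zip(ga, gb) if x != "-"]
        out.append((name, "".join(projected)))
    return out


# ---------------------------------------------------------------------------
# folding


def _weight(a: str, b: str) -> float:
    return PAIR_WEIGHT.get(a + b, 0.0)


def fold_simplified(seq: str, pair_weight=None) -> FoldResult:
    """Maximum-weight nested secondary structure of an RNA.

    ``pair_weight(i, j)`` may override the per-position pair weight (used for
    consensus folding); by default it is the canonical-pair weight table.
    Traceback is deterministic: the leftmost base pairs with its farthest
    admissible partner among optimal choices.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set(NUCLEOTIDES) - {"N"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(seq)
    if pair_weight is None:
        def pair_weight(i: int, j: int) -> float:
            return _weight(seq[i], seq[j])
    if n == 0:
        return FoldResult(structure="", energy=0.0)
    # E[i][j] = max total weight on seq[i..j] inclusive
    E = [[0.0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = pair_weight(i, k)
                if w > 0:
                    cand = w + (E[i + 1][k - 1] if k - 1 > i else 0.0)
                    if k + 1 <= j:
                        cand += E[k + 1][j]
                    if cand > best:
                        best = cand
            E[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        target = E[i][j]
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            w = pair_weight(i, k)
            if w <= 0:
                continue
            cand = w + (E[i + 1][k - 1] if k - 1 > i else 0.0)
            if k + 1 <= j:
                cand += E[k + 1][j]
            if cand == target:
                structure[i] = "("
                structure[k] = ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return FoldResult(structure="".join(structure), energy=-E[0][n - 1])


# ---------------------------------------------------------------------------
# alignment statistics


def _consensus_columns(rows: Sequence[str]) -> tuple[list[int], str]:
    """Kept column indices (all-gap columns dropped) and the majority-base
    consensus; ties broken in ACGU order."""
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have unequal length")
    kept, cons = [], []
    for c in range(ncol):
        counts = {b: 0 for b in NUCLEOTIDES}
        nongap = 0
        for r in rows:
            ch = r[c]
            if ch in counts:
                counts[ch] += 1
                nongap += 1
        if nongap == 0:
            continue
        kept.append(c)
        cons.append(max(NUCLEOTIDES, key=lambda b: counts[b]))
    return kept, "".join(cons)


def compute_sci(rows: Sequence[str], full: bool = False):
    """Structure conservation index of a gapped alignment.

    The consensus sequence (column majority) is folded with each pair weight
    scaled by the fraction of rows whose bases at those columns form a
    canonical pair; SCI = consensus energy / mean individual energy (0 when
    the mean individual energy is 0).  Identical rows give SCI = 1 exactly.
    """
    rows = [r.upper().replace("T", "U") for r in rows]
    if len(rows) < 2:
        raise ValueError("SCI needs at least 2 rows")
    kept, cons = _consensus_columns(rows)
    nrow = len(rows)

    def compat_weight(i: int, j: int) -> float:
        base = _weight(cons[i], cons[j])
        if base == 0.0:
            return 0.0
        ci, cj = kept[i], kept[j]
        ok = sum(1 for r in rows if r[ci] + r[cj] in CANONICAL_PAIRS)
        return base * (ok / nrow)

    cons_fold = fold_simplified(cons, pair_weight=compat_weight)
    individual = [fold_simplified(r.replace("-", "")).energy for r in rows]
    mean_e = float(np.mean(individual))
    sci = 0.0 if mean_e == 0 else cons_fold.energy / mean_e
    if full:
        return sci, cons, cons_fold.structure, cons_fold.energy, mean_e
    return sci


def compute_zscore(
    seq: str, n_shuffles: int = 100, mode: str = "di", seed: int = 0
) -> float:
    """Folding z-score of a sequence against composition-preserving shuffles.

    z = (E_seq - mean(E_shuffled)) / sd(E_shuffled); 0 when the shuffles are
    degenerate (sd = 0).  Negative z indicates unusually stable structure.
    """
    from .shuffles import shuffle_di, shuffle_mono

    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30 for a stable z-score")
    seq = seq.upper().replace("T", "U")
    shuffler = shuffle_di if mode == "di" else shuffle_mono
    shuffled = shuffler(seq, n_shuffles, seed=seed).sequences
    e_seq = fold_simplified(seq).energy
    energies = np.array([fold_simplified(s).energy for s in shuffled])
    sd = float(energies.std(ddof=1)) if len(energies) > 1 else 0.0
    if sd == 0:
        return 0.0
    return float((e_seq - energies.mean()) / sd)


def column_conservation(
    rows: Sequence[str], ss_annotation: str
) -> ConservationStats:
    """Per-column conservation of the family's defining positions.

    ``ss_annotation`` is a dot-bracket string over the alignment columns with
    exactly two hairpins; fractions are counted over all rows (a gap counts
    as a mismatch).
    """
    from .io import parse_two_hairpins

    rows = [r.upper().replace("T", "U") for r in rows]
    if any(len(r) != len(ss_annotation) for r in rows):
        raise ValueError("annotation length disagrees with alignment columns")
    h1, h2 = parse_two_hairpins(ss_annotation)
    nrow = len(rows)

    def frac_at(col: int, base: str) -> float:
        return sum(1 for r in rows if r[col] == base) / nrow

    paired = list(h1.pairs) + list(h2.pairs)
    canon = [
        sum(1 for r in rows if r[i] + r[j] in CANONICAL_PAIRS) / nrow
        for i, j in paired
    ]
    return ConservationStats(
        loop1_A1_fraction=frac_at(h1.loop[0], "A"),
        loop1_G4_fraction=frac_at(h1.loop[3], "G"),
        loop2_A1_fraction=frac_at(h2.loop[0], "A"),
        loop2_G4_fraction=frac_at(h2.loop[3], "G"),
        mean_stem_pair_conservation=float(np.mean(canon)),
    )


def pair_covariation(
    rows: Sequence[str], paired_columns: Sequence[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Mutual information (bits) between paired alignment columns.

    Rows with a gap in either column of a pair are excluded pairwise.
    """
    if len(rows) < 2:
        raise ValueError("covariation needs at least 2 rows")
    rows = [r.upper().replace("T", "U") for r in rows]
    out = {}
    for i, j in paired_columns:
        pairs = [
            (r[i], r[j]) for r in rows if r[i] in NUCLEOTIDES and r[j] in NUCLEOTIDES
        ]
        if not pairs:
            out[(i, j)] = 0.0
            continue
        n = len(pairs)
        joint: dict[tuple[str, str], int] = {}
        pa: dict[str, int] = {}
        pb: dict[str, int] = {}
        for a, b in pairs:
            joint[(a, b)] = joint.get((a, b), 0) + 1
            pa[a] = pa.get(a, 0) + 1
            pb[b] = pb.get(b, 0) + 1
        mi = 0.0
        for (a, b), c in joint.items():
            pab = c / n
            mi += pab * np.log2(pab / ((pa[a] / n) * (pb[b] / n)))
        out[(i, j)] = max(0.0, float(mi))
    return out


def functional_candidate(
    sci: float, mean_z: float, sci_min: float = 0.4, z_max: float = -0.5
) -> bool:
    """Advisory flag for a conserved, stable (candidate functional) structure."""
    return sci >= sci_min and mean_z <= z_max


def structure_pairs(ss: str) -> list[tuple[int, int]]:
    """Paired column indices of a dot-bracket string (any bracket alphabet)."""
    return parse_pairs(normalize_structure(ss))
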