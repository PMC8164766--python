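"""Profile estimation, bit scoring, curation rules and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antarscan._alphabet import NT_INDEX, NUCLEOTIDES, PAIR_TYPES
from antarscan.motif import (
    CandidateMotif,
    ContractError,
    MotifConstraints,
    MotifProfile,
    build_profile,
    consensus_candidate,
    curation_filter,
    score_candidate,
)

from .conftest import identical_row_seed


def make_candidate(loop1="ACUGUU", loop2="AGCGCA", stem1=("GC",) * 3,
                   stem2=("CG",) * 3, linker="AAAA"):
    return CandidateMotif(stem1_pairs=stem1, loop1=loop1, linker=linker,
                          loop2=loop2, stem2_pairs=stem2)


# ---------------------------------------------------------------------------
# build_profile


def test_identical_rows_loop_logodds_match_hand_computation(tiny_profile):
    # 10 observations of the same base, Laplace pseudocount 1, uniform
    # background: freq = (10 + 1*0.25) / 11, log-odds = log2(freq / 0.25)
    expected = math.log2(((10 + 0.25) / 11) / 0.25)
    loop1 = tiny_profile.loop_logodds[0]
    for pos, base in enumerate("ACUGUU"):
        assert loop1[pos, NT_INDEX[base]] == pytest.approx(expected)


def test_identical_rows_seed_candidate_attains_max_score(tiny_profile):
    cand = make_candidate()
    score = score_candidate(tiny_profile, cand)
    assert score == pytest.approx(tiny_profile.max_score)


def test_uniform_loop_column_contributes_zero_bits():
    # loop1 position 2 cycles through all four bases across rows
    rows = []
    for i, b in enumerate("ACGU" * 2):
        row = "GGG" + f"AC{b}GUU" + "CCC" + "AAAA" + "CCC" + "AGCGCA" + "GGG"
        rows.append((f"r{i}", row))
    from antarscan.io import make_seed_alignment

    seed = make_seed_alignment(rows, "(((......)))....(((......)))")
    prof = build_profile(seed, background=None)
    assert np.allclose(prof.loop_logodds[0][2], 0.0, atol=1e-12)


def test_single_hairpin_seed_rejected():
    from antarscan.io import FormatError, make_seed_alignment

    with pytest.raises(FormatError):
        make_seed_alignment([("a", "GGGACUGUUCCC")], "(((......)))")


def test_fewer_than_two_rows_rejected():
    seed = identical_row_seed(1)
    with pytest.raises(ValueError, match="2 rows"):
        build_profile(seed)


def test_loop_table_normalization(family_profile):
    # exp2(logodds) * background recovers frequencies summing to 1 per column
    bg = family_profile.background
    for table in family_profile.loop_logodds:
        freqs = np.exp2(table) * bg
        assert np.allclose(freqs.sum(axis=1), 1.0)


def test_linker_distribution_sums_to_one(family_profile):
    assert np.exp2(family_profile.linker_length_logprob).sum() == pytest.approx(1.0)


def test_profile_json_roundtrip(tmp_path, family_profile):
    p = tmp_path / "profile.json"
    family_profile.to_json(p)
    back = MotifProfile.from_json(p)
    assert np.allclose(back.loop_logodds[0], family_profile.loop_logodds[0])
    assert np.allclose(back.stem_pair_logodds[1], family_profile.stem_pair_logodds[1])
    assert back.constraints == family_profile.constraints
    assert back.max_score == pytest.approx(family_profile.max_score)


# ---------------------------------------------------------------------------
# scoring


def test_consensus_candidate_scores_max(family_profile):
    cand = consensus_candidate(family_profile)
    assert score_candidate(family_profile, cand) == pytest.approx(
        family_profile.max_score
    )


def test_score_below_max_after_rarest_substitution(family_profile):
    cons = consensus_candidate(family_profile)
    table = family_profile.loop_logodds[0]
    rarest = NUCLEOTIDES[int(table[0].argmin())]
    worse = CandidateMotif(
        stem1_pairs=cons.stem1_pairs, loop1=rarest + cons.loop1[1:],
        linker=cons.linker, loop2=cons.loop2, stem2_pairs=cons.stem2_pairs,
    )
    assert score_candidate(family_profile, worse) < family_profile.max_score


def test_scores_never_exceed_max(family_profile):
    rng = np.random.default_rng(42)
    for _ in range(300):
        bp1, bp2 = rng.integers(3, 11, size=2)
        cand = CandidateMotif(
            stem1_pairs=tuple(rng.choice(PAIR_TYPES, size=bp1)),
            loop1="".join(rng.choice(list("ACGU"), size=6)),
            linker="".join(rng.choice(list("ACGU"), size=rng.integers(2, 26))),
            loop2="".join(rng.choice(list("ACGU"), size=6)),
            stem2_pairs=tuple(rng.choice(PAIR_TYPES, size=bp2)),
        )
        assert score_candidate(family_profile, cand) <= family_profile.max_score + 1e-9


def test_mean_background_candidate_score_nonpositive(family_profile):
    # candidates drawn from the background model have expected log-odds
    # -KL <= 0; a seeded Monte-Carlo mean must come out negative
    rng = np.random.default_rng(7)
    bg = family_profile.background
    pair_bg = np.array(
        [bg[NT_INDEX[p[0]]] * bg[NT_INDEX[p[1]]] for p in PAIR_TYPES]
    )
    pair_bg /= pair_bg.sum()
    scores = []
    for _ in range(1000):
        cand = CandidateMotif(
            stem1_pairs=tuple(rng.choice(PAIR_TYPES, size=5, p=pair_bg)),
            loop1="".join(rng.choice(list("ACGU"), size=6, p=bg)),
            linker="".join(
                rng.choice(list("ACGU"), size=rng.integers(2, 26), p=bg)
            ),
            loop2="".join(rng.choice(list("ACGU"), size=6, p=bg)),
            stem2_pairs=tuple(rng.choice(PAIR_TYPES, size=5, p=pair_bg)),
        )
        scores.append(score_candidate(family_profile, cand))
    assert np.mean(scores) < 0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    pos=st.integers(0, 5),
    loop_idx=st.integers(0, 1),
    data=st.data(),
)
def test_substituting_higher_frequency_base_never_decreases_score(
    family_profile, pos, loop_idx, data
):
    """Scoring monotonicity in per-position profile frequency."""
    cons = consensus_candidate(family_profile)
    table = family_profile.loop_logodds[loop_idx]
    base_a = data.draw(st.sampled_from("ACGU"))
    base_b = data.draw(st.sampled_from("ACGU"))
    if table[pos, NT_INDEX[base_a]] < table[pos, NT_INDEX[base_b]]:
        base_a, base_b = base_b, base_a
    # base_a now has log-odds >= base_b at this position

    def with_base(b):
        loops = [cons.loop1, cons.loop2]
        loops[loop_idx] = loops[loop_idx][:pos] + b + loops[loop_idx][pos + 1:]
        return CandidateMotif(
            stem1_pairs=cons.stem1_pairs, loop1=loops[0], linker=cons.linker,
            loop2=loops[1], stem2_pairs=cons.stem2_pairs,
        )

    assert score_candidate(family_profile, with_base(base_a)) >= score_candidate(
        family_profile, with_base(base_b)
    )


def test_structural_contract_enforced(family_profile):
    bad = make_candidate(stem1=("GC", "GC"))  # only 2 bp
    with pytest.raises(ContractError):
        score_candidate(family_profile, bad)
    bad = make_candidate(linker="A")  # linker below minimum
    with pytest.raises(ContractError):
        score_candidate(family_profile, bad)
    bad = make_candidate(stem1=("GC", "GC", "AA"))  # non-canonical pair
    with pytest.raises(ContractError):
        score_candidate(family_profile, bad)


# ---------------------------------------------------------------------------
# curation


@pytest.mark.parametrize(
    "loop1,loop2,expect_pass,expect_violations",
    [
        ("ACUGUU", "AGCGCA", True, 0),   # fully canonical A1/G4
        ("CCUGUU", "AGCGCA", True, 1),   # one variation allowed
        ("CCUGUU", "AGCUCA", False, 2),  # two variations exceed the allowance
        ("ACUAUU", "AGCGCA", True, 1),   # G4 variation also counts
        ("CCUAUU", "CGCUCA", False, 4),
    ],
)
def test_curation_filter_counts_conserved_position_violations(
    loop1, loop2, expect_pass, expect_violations
):
    ok, reasons = curation_filter(make_candidate(loop1=loop1, loop2=loop2))
    assert ok is expect_pass
    assert len(reasons) == expect_violations


def test_curation_lenient_mode_allows_one_per_loop():
    constraints = MotifConstraints(max_conserved_position_violations=2)
    ok, reasons = curation_filter(
        make_candidate(loop1="CCUGUU", loop2="AGCUCA"), constraints
    )
    assert ok and len(reasons) == 2


def test_constraints_validation():
    with pytest.raises(ValueError):
        MotifConstraints(loop_length=5)
    with pytest.raises(ValueError):
        MotifConstraints(min_stem_bp=2)
    with pytest.raises(ValueError):
        MotifConstraints(linker_min=1)
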