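import math

import pytest

from nrpslink.alignment_scoring import column_log_p, null_monomer_log_p
from nrpslink.core_model import (
    BGC_GAP,
    NRP_GAP,
    BGCMonomer,
    NRPMonomer,
    ResidueAlphabet,
    ScoringParams,
    default_alphabet,
    default_params,
)


@pytest.fixture(scope="session")
def alphabet() -> ResidueAlphabet:
    return default_alphabet()


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return default_params()


@pytest.fixture(scope="session")
def toy_alphabet() -> ResidueAlphabet:
    return ResidueAlphabet(("ala", "gly", "val"))


@pytest.fixture(scope="session")
def toy_params(toy_alphabet) -> ScoringParams:
    """Small hand-set parameter set over a 3-residue alphabet."""
    return ScoringParams(
        p_match_a=(0.0, 0.1, 0.2, 0.35, 0.5, 0.6),
        p_a={"ala": 0.1, "gly": 0.35, "val": 0.05, toy_alphabet.unsupported_sign: 0.5},
        p_m={-1: 0.7, 1: 0.3},
        p_e={-1: 0.6, 1: 0.4},
        p_match_m={-1: 0.5, 1: 0.2},
        p_mismatch_m={-1: 0.2, 1: 0.1},
        p_match_e={-1: 0.45, 1: 0.3},
        p_mismatch_e={-1: 0.15, 1: 0.1},
        p_insertion=0.05,
        p_deletion=0.08,
    )


def brute_force_best_alignment_score(nrp_seq, bgc_seq, params, unsupported_sign="*"):
    """Independent oracle: exhaustively enumerate every global alignment
    (all interleavings of match/deletion/insertion moves) and return the
    best log-odds score."""
    n, m = len(nrp_seq), len(bgc_seq)

    def column_sums(i, j):
        if i == n and j == m:
            yield 0.0
            return
        if i < n and j < m:
            lp = column_log_p(nrp_seq[i], bgc_seq[j], params, unsupported_sign)[0]
            for rest in column_sums(i + 1, j + 1):
                yield lp + rest
        if j < m:
            lp = column_log_p(NRP_GAP, bgc_seq[j], params, unsupported_sign)[0]
            for rest in column_sums(i, j + 1):
                yield lp + rest
        if i < n:
            lp = column_log_p(nrp_seq[i], BGC_GAP, params, unsupported_sign)[0]
            for rest in column_sums(i + 1, j):
                yield lp + rest

    null = sum(null_monomer_log_p(x, params, unsupported_sign) for x in nrp_seq)
    return max(column_sums(0, 0)) - null


def random_nrp_monomer(rng, alphabet, residues=None):
    pool = residues or alphabet.extended
    return NRPMonomer(rng.choice(pool), rng.choice((-1, 1)), rng.choice((-1, 0, 1)))


def random_bgc_monomer(rng, alphabet, residues=None):
    pool = residues or alphabet.residues
    return BGCMonomer(rng.randint(0, 100), rng.choice(pool),
                      rng.choice((-1, 1)), rng.choice((-1, 1)))
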