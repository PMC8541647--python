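"""Log-odds global alignment of NRP and BGC monomer sequences.

The score of a BGC-NRP pair is a log-odds ratio comparing two
hypotheses: that the assembly line encoded in the BGC synthesized the
peptide column-by-column as laid out in a global alignment, versus a
null hypothesis in which the peptide is "explained" by a sequence of
completely undefined modules of the same length.  Column probabilities
factor into independent residue, methylation and stereochemistry
contributions, plus per-column insertion/deletion probabilities.  The
optimal alignment is found with the Needleman-Wunsch algorithm; since
the null term does not depend on the alignment, maximizing the summed
column log-probabilities maximizes the log-odds score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from nrpslink.core_model import (
    BGC_GAP,
    NRP_GAP,
    BGCMonomer,
    Gap,
    NRPMonomer,
    ScoringParams,
    discretize_specificity,
)

__all__ = [
    "AlignmentColumn",
    "ScoredAlignment",
    "residue_log_p",
    "null_residue_log_p",
    "modification_log_p",
    "column_log_p",
    "null_monomer_log_p",
    "align",
    "score_ungapped",
    "best_pair_score",
    "render_alignment",
]

#: Probabilities are clamped to this floor before taking logs so that
#: zero frequencies from small training sets never produce -inf scores.
PROB_FLOOR = 1e-9


def _log(p: float) -> float:
    return math.log(max(p, PROB_FLOOR))


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a global alignment: an NRP monomer or gap against a
    BGC monomer or gap (never gap against gap)."""

    nrp: NRPMonomer | Gap
    bgc: BGCMonomer | Gap
    kind: str  # "match", "insertion" (BGC gap) or "deletion" (NRP gap)
    log_p: float
    parts: tuple[float, float, float]  # (residue, methylation, stereo)


@dataclass
class ScoredAlignment:
    """A global alignment with its log-odds score and the
    alignment-independent null log-probability it was normalized by."""

    columns: list[AlignmentColumn]
    score: float
    null_log_p: float
    nrp_ref: object = None
    bgc_ref: object = None

    @property
    def column_log_p_sum(self) -> float:
        return sum(c.log_p for c in self.columns)


def residue_log_p(a_nrp: str, level: int, a_bgc: str, params: ScoringParams,
                  unsupported_sign: str = "*") -> float:
    """Log-probability of observing structure residue ``a_nrp`` from a
    module predicting ``a_bgc`` at discretized specificity ``level``.

    A match requires literal equality of supported residues; two
    unsupported residues are assumed distinct and take the mismatch
    branch.  The mismatch branch redistributes the background frequency
    of ``a_nrp`` over the residues other than the predicted one.
    """
    if a_nrp == a_bgc and a_nrp != unsupported_sign:
        return _log(params.p_match_a[level])
    p_match = params.p_match_a[level]
    p_nrp = params.p_a.get(a_nrp, 0.0)
    p_bgc = params.p_a.get(a_bgc, 0.0)
    return _log((1.0 - p_match) * p_nrp / max(1.0 - p_bgc, PROB_FLOOR))


def null_residue_log_p(a_nrp: str, params: ScoringParams,
                       unsupported_sign: str = "*") -> float:
    """Log-probability of residue ``a_nrp`` under the null model (an
    undefined module: unreliable prediction of the unsupported sign)."""
    p_unsup = params.p_a.get(unsupported_sign, 0.0)
    if p_unsup >= 1.0:
        raise ValueError("background frequency of the unsupported sign must be < 1")
    return _log(params.p_a.get(a_nrp, 0.0) / (1.0 - p_unsup))


def modification_log_p(x_nrp: int, x_bgc: int, kind: str, params: ScoringParams) -> float:
    """Log-probability of a methylation or stereo flag pair in a match
    column.

    An undetermined structure-side stereo flag (0) is uninformative and
    contributes exactly 0; an undefined gene-side flag (0) falls back to
    the background frequency of the structure-side state.
    """
    if kind == "methylation":
        p_match, p_mismatch, p_bg = params.p_match_m, params.p_mismatch_m, params.p_m
        if x_nrp not in (-1, 1):
            raise ValueError("methylation flag must be -1/+1 on the NRP side")
    elif kind == "stereo":
        p_match, p_mismatch, p_bg = params.p_match_e, params.p_mismatch_e, params.p_e
        if x_nrp == 0:
            return 0.0
    else:
        raise ValueError(f"unknown modification kind {kind!r}")
    if x_bgc == 0:
        return _log(p_bg[x_nrp])
    if x_nrp == x_bgc:
        return _log(p_match[x_nrp])
    return _log(p_mismatch[x_nrp])


def null_monomer_log_p(m: NRPMonomer, params: ScoringParams,
                       unsupported_sign: str = "*") -> float:
    """Null-hypothesis log-probability of one NRP monomer (aligned
    against an undefined module)."""
    return (
        null_residue_log_p(m.residue, params, unsupported_sign)
        + _log(params.p_m[m.methylated])
        + (0.0 if m.stereo == 0 else _log(params.p_e[m.stereo]))
    )


def column_log_p(nrp: NRPMonomer | Gap, bgc: BGCMonomer | Gap,
                 params: ScoringParams, unsupported_sign: str = "*"
                 ) -> tuple[float, tuple[float, float, float]]:
    """Log-probability of a single alignment column, with its
    (residue, methylation, stereo) parts.

    Insertion columns (gap on the BGC side) cost the insertion
    probability times the background probability of the inserted
    monomer; deletion columns (gap on the NRP side) cost a uniform
    deletion probability regardless of the skipped module.
    """
    if isinstance(nrp, Gap) and isinstance(bgc, Gap):
        raise ValueError("gap-vs-gap column is not allowed")
    if isinstance(nrp, Gap):  # deletion: module skipped
        lp = _log(params.p_deletion)
        return lp, (lp, 0.0, 0.0)
    if isinstance(bgc, Gap):  # insertion: monomer not encoded by any module
        a = _log(params.p_insertion) + _log(params.p_a.get(nrp.residue, 0.0))
        m = _log(params.p_m[nrp.methylated])
        e = 0.0 if nrp.stereo == 0 else _log(params.p_e[nrp.stereo])
        return a + m + e, (a, m, e)
    level = discretize_specificity(bgc.specificity, params.level_boundaries)
    a = residue_log_p(nrp.residue, level, bgc.residue, params, unsupported_sign)
    m = modification_log_p(nrp.methylated, bgc.methylated, "methylation", params)
    e = modification_log_p(nrp.stereo, bgc.stereo, "stereo", params)
    return a + m + e, (a, m, e)


def _make_column(nrp, bgc, params, unsupported_sign) -> AlignmentColumn:
    lp, parts = column_log_p(nrp, bgc, params, unsupported_sign)
    if isinstance(nrp, Gap):
        kind = "deletion"
    elif isinstance(bgc, Gap):
        kind = "insertion"
    else:
        kind = "match"
    return AlignmentColumn(nrp, bgc, kind, lp, parts)


def align(nrp_seq: Sequence[NRPMonomer], bgc_seq: Sequence[BGCMonomer],
          params: ScoringParams, unsupported_sign: str = "*") -> ScoredAlignment:
    """Optimal global alignment of an NRP monomer sequence against a BGC
    monomer sequence under the log-odds model.

    Traceback ties are broken deterministically: match/mismatch is
    preferred over deletion (NRP gap), which is preferred over insertion
    (BGC gap).
    """
    nrp_seq = list(nrp_seq)
    bgc_seq = list(bgc_seq)
    if not nrp_seq or not bgc_seq:
        raise ValueError("both sequences must be non-empty")
    n, m = len(nrp_seq), len(bgc_seq)

    ins_cost = [column_log_p(x, BGC_GAP, params, unsupported_sign)[0] for x in nrp_seq]
    del_cost = column_log_p(NRP_GAP, bgc_seq[0], params, unsupported_sign)[0]  # uniform

    NEG = -math.inf
    # dp[i][j]: best summed column log-probability aligning nrp[:i] with bgc[:j]
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    move = [[""] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(1, n + 1):
        dp[i][0] = dp[i - 1][0] + ins_cost[i - 1]
        move[i][0] = "I"
    for j in range(1, m + 1):
        dp[0][j] = dp[0][j - 1] + del_cost
        move[0][j] = "D"
    match_cost = {}
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            mc = column_log_p(nrp_seq[i - 1], bgc_seq[j - 1], params, unsupported_sign)[0]
            match_cost[i, j] = mc
            cand = (
                (dp[i - 1][j - 1] + mc, "M"),
                (dp[i][j - 1] + del_cost, "D"),
                (dp[i - 1][j] + ins_cost[i - 1], "I"),
            )
            # max score; on ties prefer M, then D, then I (tuple order)
            best, bm = cand[0]
            for sc, mv in cand[1:]:
                if sc > best:
                    best, bm = sc, mv
            dp[i][j] = best
            move[i][j] = bm

    columns: list[AlignmentColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == "M":
            columns.append(_make_column(nrp_seq[i - 1], bgc_seq[j - 1], params, unsupported_sign))
            i, j = i - 1, j - 1
        elif mv == "D":
            columns.append(_make_column(NRP_GAP, bgc_seq[j - 1], params, unsupported_sign))
            j -= 1
        else:
            columns.append(_make_column(nrp_seq[i - 1], BGC_GAP, params, unsupported_sign))
            i -= 1
    columns.reverse()

    null_lp = sum(null_monomer_log_p(x, params, unsupported_sign) for x in nrp_seq)
    return ScoredAlignment(columns=columns, score=dp[n][m] - null_lp, null_log_p=null_lp)


def score_ungapped(nrp_seq: Sequence[NRPMonomer], bgc_seq: Sequence[BGCMonomer],
                   params: ScoringParams, unsupported_sign: str = "*") -> ScoredAlignment:
    """Score the single gap-free alignment of two equal-length sequences."""
    nrp_seq = list(nrp_seq)
    bgc_seq = list(bgc_seq)
    if len(nrp_seq) != len(bgc_seq):
        raise ValueError("ungapped alignment requires equal lengths")
    columns = [_make_column(x, y, params, unsupported_sign) for x, y in zip(nrp_seq, bgc_seq)]
    total = sum(c.log_p for c in columns)
    null_lp = sum(null_monomer_log_p(x, params, unsupported_sign) for x in nrp_seq)
    return ScoredAlignment(columns=columns, score=total - null_lp, null_log_p=null_lp)


def best_pair_score(nrp_candidates: Sequence[Sequence[NRPMonomer]],
                    assembly_lines: Sequence[Sequence[BGCMonomer]],
                    params: ScoringParams, unsupported_sign: str = "*"
                    ) -> tuple[ScoredAlignment, list[list[float]]]:
    """Align every NRP candidate against every assembly line; return the
    best-scoring alignment (ties broken lexicographically on candidate
    indices) and the full score table."""
    if not nrp_candidates or not assembly_lines:
        raise ValueError("candidate lists must be non-empty")
    table: list[list[float]] = []
    best: ScoredAlignment | None = None
    best_idx = None
    for i, nrp in enumerate(nrp_candidates):
        row = []
        for j, bgc in enumerate(assembly_lines):
            aln = align(nrp, bgc, params, unsupported_sign)
            row.append(aln.score)
            if best is None or aln.score > best.score:
                best, best_idx = aln, (i, j)
        table.append(row)
    best.nrp_ref, best.bgc_ref = best_idx
    return best, table


def render_alignment(aln: ScoredAlignment, indent: str = "  ") -> str:
    """Plain-text rendering of an alignment: one row per column with the
    gene-side monomer over the structure-side monomer and the per-column
    score parts."""
    lines = [f"{indent}{'BGC':>18s}  {'NRP':>14s}  {'kind':>9s}  {'logP':>9s}  (a, m, e)"]
    for c in aln.columns:
        if isinstance(c.bgc, Gap):
            bgc_txt = "-"
        else:
            flags = f"m{c.bgc.methylated:+d}/e{c.bgc.stereo:+d}" if not c.bgc.undefined else "undef"
            bgc_txt = f"{c.bgc.residue}[s={c.bgc.specificity}] {flags}"
        if isinstance(c.nrp, Gap):
            nrp_txt = "-"
        else:
            nrp_txt = f"{c.nrp.residue} m{c.nrp.methylated:+d}/e{c.nrp.stereo:+d}"
        parts = ", ".join(f"{p:.3f}" for p in c.parts)
        lines.append(f"{indent}{bgc_txt:>18s}  {nrp_txt:>14s}  {c.kind:>9s}  {c.log_p:9.3f}  ({parts})")
    lines.append(f"{indent}score = {aln.score:.4f} (null logP = {aln.null_log_p:.4f})")
    return "\n".join(lines)
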