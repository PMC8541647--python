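"""Estimation of scoring parameters from data.

Two sources feed the model.  Background frequencies of residues,
methylation and stereo states come from a corpus of NRP monomer
sequences (any unsupported residue is pooled into the reserved sign;
undetermined stereo flags are excluded from the stereo denominator).
Match/mismatch and indel probabilities come from curated BGC-NRP
alignments: every estimate is a plain event frequency.  Following the
counting convention of the model, the denominator for stereo match /
mismatch frequencies is the number of non-indel columns whose
structure-side stereochemistry is determined, pooled over both
gene-side states; methylation is counted analogously.  Insertion
columns are normalized per NRP monomer and deletion columns per BGC
monomer.  Uncertainty is assessed by bootstrapping whole alignments.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from nrpslink.core_model import (
    BGCMonomer,
    Gap,
    NRP_GAP,
    BGC_GAP,
    NRPMonomer,
    ResidueAlphabet,
    ScoringParams,
    DEFAULT_LEVEL_BOUNDARIES,
    discretize_specificity,
)

__all__ = [
    "CuratedAlignment",
    "estimate_background",
    "estimate_alignment_params",
    "estimate_params",
    "bootstrap_params",
    "load_curated_alignments",
    "save_curated_alignments",
]

#: Floor used when an event class has no observations at all.
FREQ_FLOOR = 1e-9


@dataclass
class CuratedAlignment:
    """A ground-truth global alignment of one BGC-NRP pair: a list of
    (NRP monomer or gap, BGC monomer or gap) columns."""

    bgc_id: str
    compound_id: str
    columns: list[tuple[NRPMonomer | Gap, BGCMonomer | Gap]]

    def __post_init__(self) -> None:
        for nrp, bgc in self.columns:
            if isinstance(nrp, Gap) and isinstance(bgc, Gap):
                raise ValueError("gap-vs-gap column in curated alignment")


def estimate_background(nrp_sequences: Sequence[Sequence[NRPMonomer]],
                        alphabet: ResidueAlphabet
                        ) -> tuple[dict[str, float], dict[int, float], dict[int, float]]:
    """Plug-in background frequencies (residues, methylation, stereo)
    from a corpus of NRP monomer sequences.

    Residues outside the alphabet are pooled into the unsupported sign;
    stereo frequencies are computed over monomers with determined
    stereochemistry only.
    """
    monomers = [m for seq in nrp_sequences for m in seq]
    if not monomers:
        raise ValueError("empty corpus")
    p_a = {a: 0.0 for a in alphabet.extended}
    for m in monomers:
        p_a[alphabet.normalize(m.residue)] += 1.0
    total = float(len(monomers))
    p_a = {a: c / total for a, c in p_a.items()}

    n_methyl = sum(1 for m in monomers if m.methylated == 1)
    p_m = {1: n_methyl / total, -1: (total - n_methyl) / total}

    chiral = [m for m in monomers if m.stereo != 0]
    if chiral:
        n_d = sum(1 for m in chiral if m.stereo == 1)
        p_e = {1: n_d / len(chiral), -1: 1.0 - n_d / len(chiral)}
    else:
        p_e = {1: 0.5, -1: 0.5}
    return p_a, p_m, p_e


def estimate_alignment_params(alignments: Sequence[CuratedAlignment],
                              level_boundaries: Sequence[int] = DEFAULT_LEVEL_BOUNDARIES,
                              ) -> dict:
    """Frequency estimates of the match/mismatch and indel probabilities
    from curated alignments.

    Returns a dict with keys ``p_match_a``, ``p_match_m``,
    ``p_mismatch_m``, ``p_match_e``, ``p_mismatch_e``, ``p_insertion``
    and ``p_deletion``; combine with background frequencies to build a
    full :class:`ScoringParams`.
    """
    if not alignments:
        raise ValueError("at least one curated alignment is required")
    boundaries = tuple(level_boundaries)

    level_total = [0] * 6
    level_match = [0] * 6
    m_joint = {(-1, -1): 0, (-1, 1): 0, (1, -1): 0, (1, 1): 0}
    m_total = 0
    e_joint = {(-1, -1): 0, (-1, 1): 0, (1, -1): 0, (1, 1): 0}
    e_total = 0
    n_insertion = n_deletion = n_nrp = n_bgc = 0

    for aln in alignments:
        for nrp, bgc in aln.columns:
            if isinstance(nrp, Gap):
                n_deletion += 1
                n_bgc += 1
                continue
            n_nrp += 1
            if isinstance(bgc, Gap):
                n_insertion += 1
                continue
            n_bgc += 1
            level = discretize_specificity(bgc.specificity, boundaries)
            level_total[level] += 1
            if nrp.residue == bgc.residue and not bgc.undefined:
                level_match[level] += 1
            if nrp.methylated in (-1, 1):
                m_total += 1
                if bgc.methylated in (-1, 1):
                    m_joint[nrp.methylated, bgc.methylated] += 1
            if nrp.stereo in (-1, 1):
                e_total += 1
                if bgc.stereo in (-1, 1):
                    e_joint[nrp.stereo, bgc.stereo] += 1

    def freq(num: int, den: int) -> float:
        return num / den if den > 0 else FREQ_FLOOR

    p_match_a = [0.0] + [freq(level_match[lvl], level_total[lvl]) for lvl in range(1, 6)]
    return {
        "p_match_a": tuple(p_match_a),
        "p_match_m": {s: freq(m_joint[s, s], m_total) for s in (-1, 1)},
        "p_mismatch_m": {s: freq(m_joint[s, -s], m_total) for s in (-1, 1)},
        "p_match_e": {s: freq(e_joint[s, s], e_total) for s in (-1, 1)},
        "p_mismatch_e": {s: freq(e_joint[s, -s], e_total) for s in (-1, 1)},
        "p_insertion": freq(n_insertion, n_nrp),
        "p_deletion": freq(n_deletion, n_bgc),
    }


def estimate_params(alignments: Sequence[CuratedAlignment],
                    nrp_sequences: Sequence[Sequence[NRPMonomer]],
                    alphabet: ResidueAlphabet,
                    level_boundaries: Sequence[int] = DEFAULT_LEVEL_BOUNDARIES
                    ) -> ScoringParams:
    """Full parameter estimation: backgrounds from the structure corpus,
    match/mismatch/indel parts from the curated alignments."""
    p_a, p_m, p_e = estimate_background(nrp_sequences, alphabet)
    parts = estimate_alignment_params(alignments, level_boundaries)
    return ScoringParams(p_a=p_a, p_m=p_m, p_e=p_e,
                         level_boundaries=tuple(level_boundaries), **parts)


def _params_vector(parts: dict) -> dict[str, float]:
    flat = {}
    for lvl, p in enumerate(parts["p_match_a"]):
        flat[f"p_match_a[{lvl}]"] = p
    for name in ("p_match_m", "p_mismatch_m", "p_match_e", "p_mismatch_e"):
        for k, v in parts[name].items():
            flat[f"{name}[{k:+d}]"] = v
    flat["p_insertion"] = parts["p_insertion"]
    flat["p_deletion"] = parts["p_deletion"]
    return flat


def bootstrap_params(alignments: Sequence[CuratedAlignment],
                     n_samples: int = 100,
                     seed: int | None = None,
                     level_boundaries: Sequence[int] = DEFAULT_LEVEL_BOUNDARIES,
                     aggregate: str = "mean") -> tuple[list[dict], dict]:
    """Bootstrap the alignment-derived parameters.

    Whole alignments are resampled with replacement to the original
    count (preserving within-cluster correlation of columns),
    parameters are re-estimated per sample, and a per-parameter summary
    (point estimate via ``aggregate`` = "mean" or "median", plus the
    standard deviation) is returned along with the individual samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(alignments)
    samples = []
    for _ in range(n_samples):
        idx = rng.integers(0, n, size=n)
        samples.append(estimate_alignment_params([alignments[i] for i in idx],
                                                 level_boundaries))
    flats = [_params_vector(s) for s in samples]
    agg = statistics.mean if aggregate == "mean" else statistics.median
    summary = {}
    for key in flats[0]:
        values = [f[key] for f in flats]
        summary[key] = {
            "estimate": agg(values),
            "sd": statistics.pstdev(values),
        }
    return samples, summary


# ---------------------------------------------------------------------------
# Curated-alignment TSV: one column-pair per row with gaps encoded as "-".

_HEADER = ["bgc_id", "compound_id", "nrp_residue", "nrp_m", "nrp_e",
           "bgc_residue", "bgc_s", "bgc_m", "bgc_e", "column_kind"]


def save_curated_alignments(alignments: Iterable[CuratedAlignment],
                            path: str | Path) -> None:
    """Write curated alignments as TSV (one row per alignment column)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for aln in alignments:
            for nrp, bgc in aln.columns:
                if isinstance(nrp, Gap):
                    nrp_fields = ["-", "-", "-"]
                    kind = "deletion"
                else:
                    nrp_fields = [nrp.residue, str(nrp.methylated), str(nrp.stereo)]
                    kind = "insertion" if isinstance(bgc, Gap) else "match"
                if isinstance(bgc, Gap):
                    bgc_fields = ["-", "-", "-", "-"]
                else:
                    bgc_fields = [bgc.residue, str(bgc.specificity),
                                  str(bgc.methylated), str(bgc.stereo)]
                writer.writerow([aln.bgc_id, aln.compound_id, *nrp_fields,
                                 *bgc_fields, kind])


def load_curated_alignments(path: str | Path) -> list[CuratedAlignment]:
    """Read curated alignments written by :func:`save_curated_alignments`."""
    alignments: dict[tuple[str, str], CuratedAlignment] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _HEADER:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_HEADER)} fields")
            bgc_id, compound_id = row[0], row[1]
            if row[2] == "-":
                nrp: NRPMonomer | Gap = NRP_GAP
            else:
                nrp = NRPMonomer(row[2], int(row[3]), int(row[4]))
            if row[5] == "-":
                bgc: BGCMonomer | Gap = BGC_GAP
            else:
                s, m, e = int(row[6]), int(row[7]), int(row[8])
                bgc = BGCMonomer(s, row[5], m, e, undefined=(m == 0 and e == 0))
            key = (bgc_id, compound_id)
            if key not in alignments:
                alignments[key] = CuratedAlignment(bgc_id, compound_id, [])
            alignments[key].columns.append((nrp, bgc))
    return list(alignments.values())
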