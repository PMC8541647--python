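"""All-vs-all matching, reciprocal filtering, reports and the FDR
benchmark evaluator.

Every (compound, BGC) pair is scored by the best alignment over the
compound's candidate linearizations and the cluster's candidate
assembly lines.  Matches below a minimum score are discarded.  Because
a few promiscuous compounds or clusters can dominate a plain top-score
list, the combined report keeps a match only if the compound ranks
among the best hits of the cluster AND the cluster ranks among the best
hits of the compound (reciprocal filtering; by default strict
reciprocal best).  For benchmarking against known pairings, a cluster
counts as correctly identified when its ground-truth compound ranks
within a cutoff among its hits; the false discovery rate over the
score-sorted representatives of all clusters is FDR[i] =
(i - Numcor[i]) / i for each list prefix i.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from nrpslink.alignment_scoring import ScoredAlignment, best_pair_score, render_alignment
from nrpslink.bgc_assembler import AssemblyLine
from nrpslink.core_model import ScoringParams
from nrpslink.nrp_linearizer import CandidateNRPSequence

__all__ = [
    "MatchResult",
    "BenchmarkRecord",
    "match_all",
    "combined_report",
    "fdr_curve",
    "fdr_from_flags",
    "build_benchmark_records",
    "write_reports",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 6.0
DEFAULT_K_BEST = 1
DEFAULT_RANK_CUTOFF = 10


@dataclass
class MatchResult:
    """One scored compound-cluster pair with its best alignment."""

    compound_id: str
    genome_id: str
    bgc_id: str
    score: float
    alignment: ScoredAlignment
    candidate_index: int
    line_index: int


@dataclass
class BenchmarkRecord:
    """Per-cluster benchmark summary: its score-ranked hits, the
    ground-truth compound and derived rank/score statistics."""

    bgc_id: str
    hits: list[tuple[str, float]]  # (compound_id, score), descending
    ground_truth: str

    @property
    def s_best(self) -> float:
        return self.hits[0][1] if self.hits else -math.inf

    @property
    def r_gt(self) -> int | None:
        for rank, (cid, _) in enumerate(self.hits, start=1):
            if cid == self.ground_truth:
                return rank
        return None

    @property
    def s_gt(self) -> float | None:
        for cid, score in self.hits:
            if cid == self.ground_truth:
                return score
        return None


def _sort_key(r: MatchResult):
    return (-r.score, r.compound_id, r.genome_id, r.bgc_id)


def match_all(nrp_records: Mapping[str, Sequence[CandidateNRPSequence]],
              bgc_records: Sequence[tuple[str, str, Sequence[AssemblyLine]]],
              params: ScoringParams,
              min_score: float = DEFAULT_MIN_SCORE,
              unsupported_sign: str = "*") -> list[MatchResult]:
    """Score every compound against every cluster.

    ``nrp_records`` maps compound id to its candidate sequences;
    ``bgc_records`` is a list of (genome_id, bgc_id, assembly lines).
    Matches scoring strictly below ``min_score`` are discarded; the rest
    are returned score-descending with deterministic tie order.
    """
    results: list[MatchResult] = []
    if not nrp_records or not bgc_records:
        logger.warning("empty matching input")
        return results
    for compound_id, candidates in nrp_records.items():
        if not candidates:
            continue
        cand_seqs = [c.monomers for c in candidates]
        for genome_id, bgc_id, lines in bgc_records:
            if not lines:
                continue
            line_seqs = [l.monomers for l in lines]
            best, _table = best_pair_score(cand_seqs, line_seqs, params, unsupported_sign)
            if best.score < min_score:
                continue
            ci, li = best.nrp_ref, best.bgc_ref
            results.append(MatchResult(
                compound_id=compound_id, genome_id=genome_id, bgc_id=bgc_id,
                score=best.score, alignment=best,
                candidate_index=ci, line_index=li,
            ))
    results.sort(key=_sort_key)
    return results


def combined_report(results: Sequence[MatchResult],
                    k_best: int = DEFAULT_K_BEST) -> list[MatchResult]:
    """Reciprocal filtering: keep a match only if its compound ranks
    within ``k_best`` among the cluster's hits and the cluster ranks
    within ``k_best`` among the compound's hits."""
    by_bgc: dict[tuple[str, str], list[MatchResult]] = {}
    by_compound: dict[str, list[MatchResult]] = {}
    for r in results:
        by_bgc.setdefault((r.genome_id, r.bgc_id), []).append(r)
        by_compound.setdefault(r.compound_id, []).append(r)

    def ranks(groups):
        rank: dict[int, int] = {}
        for group in groups.values():
            for i, r in enumerate(sorted(group, key=_sort_key), start=1):
                rank[id(r)] = i
        return rank

    bgc_rank = ranks(by_bgc)
    compound_rank = ranks(by_compound)
    return [r for r in results
            if bgc_rank[id(r)] <= k_best and compound_rank[id(r)] <= k_best]


def fdr_from_flags(flags: Sequence[bool],
                   scores: Sequence[float] | None = None) -> list[float]:
    """FDR over prefixes of a correctness vector already in score order:
    FDR[i] = (i - Numcor[i]) / i.  If ``scores`` are given, tied entries
    share the FDR computed over the whole tie group."""
    n = len(flags)
    fdr = []
    numcor = 0
    for i, flag in enumerate(flags, start=1):
        numcor += bool(flag)
        fdr.append((i - numcor) / i)
    if scores is not None:
        if len(scores) != n:
            raise ValueError("scores and flags must have equal length")
        i = 0
        while i < n:
            j = i
            while j + 1 < n and scores[j + 1] == scores[i]:
                j += 1
            for k in range(i, j + 1):
                fdr[k] = fdr[j]
            i = j + 1
    return fdr


def fdr_curve(records: Sequence[BenchmarkRecord],
              correct_rank_cutoff: int = DEFAULT_RANK_CUTOFF
              ) -> list[tuple[str, float, bool, float]]:
    """Evaluate the ranked-identification benchmark.

    A cluster is correctly identified when its ground-truth compound
    ranks within ``correct_rank_cutoff`` among its hits; its
    representative score is the ground-truth hit's score if correct,
    else the best hit's.  Representatives are sorted score-descending
    and the prefix FDR is computed, with tied scores sharing the FDR of
    their tie group.  Returns (bgc_id, representative score, correct,
    FDR) per prefix.
    """
    reps = []
    for rec in records:
        r_gt = rec.r_gt
        correct = r_gt is not None and r_gt <= correct_rank_cutoff
        score = rec.s_gt if correct else rec.s_best
        reps.append((rec.bgc_id, score, correct))
    reps.sort(key=lambda t: (-t[1], t[0]))
    scores = [s for _, s, _ in reps]
    flags = [c for _, _, c in reps]
    fdr = fdr_from_flags(flags, scores)
    return [(bgc_id, score, correct, f)
            for (bgc_id, score, correct), f in zip(reps, fdr)]


def build_benchmark_records(results: Sequence[MatchResult],
                            truth: Mapping[str, str]) -> list[BenchmarkRecord]:
    """Group match results per cluster and attach the ground-truth
    compound (``truth`` maps bgc_id to compound_id)."""
    by_bgc: dict[str, list[MatchResult]] = {}
    for r in results:
        by_bgc.setdefault(r.bgc_id, []).append(r)
    records = []
    for bgc_id, gt in truth.items():
        hits = sorted(by_bgc.get(bgc_id, []), key=_sort_key)
        records.append(BenchmarkRecord(
            bgc_id=bgc_id,
            hits=[(r.compound_id, r.score) for r in hits],
            ground_truth=gt,
        ))
    return records


# ---------------------------------------------------------------------------
# Report files

_COMBINED_HEADER = ["score", "compound_id", "genome_id", "bgc_id",
                    "candidate_index", "line_index"]


def write_reports(results: Sequence[MatchResult],
                  combined: Sequence[MatchResult],
                  output_dir: str | Path,
                  config_echo: Mapping | None = None) -> dict[str, Path]:
    """Write the combined TSV, per-compound and per-genome alignment
    reports, and a run log; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    combined_path = out / "combined_report.tsv"
    with open(combined_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COMBINED_HEADER)
        for r in combined:
            writer.writerow([f"{r.score:.6f}", r.compound_id, r.genome_id,
                             r.bgc_id, r.candidate_index, r.line_index])
    paths["combined"] = combined_path

    def grouped_report(path: Path, key) -> None:
        groups: dict[str, list[MatchResult]] = {}
        for r in results:
            groups.setdefault(key(r), []).append(r)
        with open(path, "w", encoding="utf-8") as fh:
            for group_id in sorted(groups):
                fh.write(f"== {group_id} ==\n")
                for r in sorted(groups[group_id], key=_sort_key):
                    fh.write(f"{r.score:.4f}\t{r.compound_id}\t{r.genome_id}\t{r.bgc_id}\n")
                    fh.write(render_alignment(r.alignment) + "\n")
                fh.write("\n")

    per_compound = out / "per_compound_report.txt"
    grouped_report(per_compound, lambda r: r.compound_id)
    paths["per_compound"] = per_compound

    per_genome = out / "per_genome_report.txt"
    grouped_report(per_genome, lambda r: r.genome_id)
    paths["per_genome"] = per_genome

    log_path = out / "run_info.txt"
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write(f"matches: {len(results)}\ncombined: {len(combined)}\n")
        for k, v in (config_echo or {}).items():
            fh.write(f"{k}: {v}\n")
    paths["log"] = log_path
    return paths


def read_combined_report(path: str | Path) -> list[dict]:
    """Parse a combined-report TSV back into dicts (scores as floats)."""
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            row["score"] = float(row["score"])
            row["candidate_index"] = int(row["candidate_index"])
            row["line_index"] = int(row["line_index"])
            rows.append(row)
    return rows
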