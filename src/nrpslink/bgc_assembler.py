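"""Reconstruction of candidate assembly lines from BGC annotations.

A BGC annotation lists NRPS genes (with genomic coordinates) whose
modules carry domain lists and, for adenylation (A) domains, ranked
substrate predictions with Stachelhaus and SVM scores.  Each module is
converted to one BGC monomer; each gene yields a *strip* — the ordered
run of its monomers, whose internal order is never permuted because
module order within a gene is conserved during synthesis.  Deficient
modules (lacking an A domain) generate strip variants modelling
stuttering and iterative gene reuse.  Over-merged BGCs are split at
large inter-gene gaps and at starter-condensation (CS) / thioesterase
(TE) domains.  Finally, strips are ordered into full assembly lines:
collinear order first, then rule-based repairs, then constrained
permutations when the optional CS / TE / COM domains demand a
non-collinear order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from nrpslink.core_model import BGCMonomer, ResidueAlphabet, undefined_bgc_monomer

__all__ = [
    "DomainAnnotation",
    "GeneAnnotation",
    "Strip",
    "AssemblyLine",
    "BGCRecord",
    "GenomeRecord",
    "module_to_monomer",
    "expand_deficient_modules",
    "split_bgc",
    "check_consistency",
    "enumerate_assembly_lines",
    "assemble_bgc",
    "load_bgc_annotations",
    "save_bgc_annotations",
]

logger = logging.getLogger(__name__)

DOMAIN_KINDS = frozenset({"A", "C", "C/E", "E", "M", "PCP", "CS", "TE", "COM_N", "COM_C"})

DEFAULT_MAX_BGC_DIST = 10_000
DEFAULT_MAX_COPIES = 3
DEFAULT_MAX_SEQUENCES = 720


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain; substrate predictions (residue, Stachelhaus
    score, SVM score) are present exactly for A domains."""

    kind: str
    predictions: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if (self.kind == "A") != bool(self.predictions):
            raise ValueError("substrate predictions must be present iff kind is A")


@dataclass
class GeneAnnotation:
    """One NRPS gene: coordinates (1-based inclusive), strand and its
    ordered modules (each an ordered list of domains, as annotated)."""

    gene_id: str
    start: int
    end: int
    strand: str
    modules: list[list[DomainAnnotation]]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    def _has(self, kind: str) -> bool:
        return any(d.kind == kind for mod in self.modules for d in mod)

    @property
    def has_CS(self) -> bool:
        return self._has("CS")

    @property
    def has_TE(self) -> bool:
        return self._has("TE")

    @property
    def has_COM_N(self) -> bool:
        return self._has("COM_N")

    @property
    def has_COM_C(self) -> bool:
        return self._has("COM_C")


@dataclass(frozen=True)
class Strip:
    """The ordered monomer run of one gene, with the gene's positional
    flags and a tag describing any copy-number expansion applied."""

    gene_id: str
    monomers: tuple[BGCMonomer, ...]
    has_CS: bool = False
    has_TE: bool = False
    has_COM_N: bool = False
    has_COM_C: bool = False
    variant_tag: str = "base"


@dataclass
class AssemblyLine:
    """A candidate BGC monomer sequence: concatenated strips in one
    consistent order."""

    monomers: tuple[BGCMonomer, ...]
    strip_order: tuple[tuple[str, str], ...]  # (gene_id, variant_tag)
    bgc_id: str


@dataclass
class BGCRecord:
    bgc_id: str
    genes: list[GeneAnnotation]


@dataclass
class GenomeRecord:
    genome_id: str
    bgcs: list[BGCRecord]


def _is_deficient(module: Sequence[DomainAnnotation]) -> bool:
    return not any(d.kind == "A" for d in module)


def _is_sole_pcp(module: Sequence[DomainAnnotation]) -> bool:
    return len(module) == 1 and module[0].kind == "PCP"


def module_to_monomer(module: Sequence[DomainAnnotation], next_module_has_CE: bool,
                      alphabet: ResidueAlphabet,
                      synonyms: Mapping[str, str] | None = None) -> BGCMonomer:
    """Convert one typical module into a BGC monomer.

    The core residue is the prediction with the highest mean of its
    Stachelhaus and SVM scores (first listed wins ties); the specificity
    score is that mean, rounded half-up.  Methylation follows the
    presence of an M domain.  The stereo flag is D (+1) if the module
    carries an E domain or the *next* module carries a dual C/E domain
    (which epimerizes the previous residue), else L (-1).  Predicted
    residues outside the alphabet are looked up in the optional synonym
    map; if still unknown, the monomer is flagged undefined.
    """
    a_domains = [d for d in module if d.kind == "A"]
    if len(a_domains) != 1:
        raise ValueError("module must contain exactly one A domain")
    best_res, best_mean = None, -math.inf
    for residue, stach, svm in a_domains[0].predictions:
        mean = (float(stach) + float(svm)) / 2.0
        if mean > best_mean:
            best_res, best_mean = residue, mean
    specificity = int(math.floor(best_mean + 0.5))  # half-up, deterministic
    methylated = 1 if any(d.kind == "M" for d in module) else -1
    stereo = 1 if any(d.kind == "E" for d in module) or next_module_has_CE else -1

    residue = best_res.strip().lower()
    if synonyms and residue in synonyms:
        residue = synonyms[residue]
    if residue not in alphabet:
        logger.warning("predicted residue %r outside the alphabet; monomer set undefined",
                       best_res)
        return undefined_bgc_monomer(alphabet)
    return BGCMonomer(specificity=specificity, residue=residue,
                      methylated=methylated, stereo=stereo)


def expand_deficient_modules(gene: GeneAnnotation, alphabet: ResidueAlphabet,
                             max_copies: int = DEFAULT_MAX_COPIES,
                             synonyms: Mapping[str, str] | None = None) -> list[Strip]:
    """Build all strip variants of one gene.

    Typical modules each contribute one monomer.  An A-domain-less
    deficient module may *stutter*: it reuses the previous typical
    module's A domain, so variants repeat that monomer so it occurs
    1..``max_copies`` times in total (one occurrence is the unexpanded
    strip).  A deficient module that is a sole PCP domain and last in
    the gene signals iterative reuse of the whole gene: variants repeat
    the entire strip 1..``max_copies`` times.  Expansions for multiple
    deficient modules combine multiplicatively.
    """
    flags = dict(has_CS=gene.has_CS, has_TE=gene.has_TE,
                 has_COM_N=gene.has_COM_N, has_COM_C=gene.has_COM_C)

    n_mod = len(gene.modules)
    base: list[BGCMonomer] = []       # monomer per typical module
    stutter_positions: list[int] = [] # index into `base` of the monomer a stutter repeats
    iterative = False
    skipped = 0
    for i, module in enumerate(gene.modules):
        next_has_ce = i + 1 < n_mod and any(d.kind == "C/E" for d in gene.modules[i + 1])
        if not _is_deficient(module):
            base.append(module_to_monomer(module, next_has_ce, alphabet, synonyms))
            continue
        if _is_sole_pcp(module) and i == n_mod - 1:
            iterative = True
        elif base:
            stutter_positions.append(len(base) - 1)
        else:
            skipped += 1
            logger.warning("%s: deficient module %d has no preceding typical module; "
                           "stutter variant skipped", gene.gene_id, i)

    if not base:
        logger.warning("%s: no typical module; gene yields no strip", gene.gene_id)
        return []

    # extra copies per stutter position: 0..max_copies-1 each
    copy_choices = [range(max_copies) for _ in stutter_positions]
    repeat_choices = range(1, max_copies + 1) if iterative else (1,)

    strips: list[Strip] = []
    for extras in product(*copy_choices):
        monomers: list[BGCMonomer] = []
        for idx, mono in enumerate(base):
            monomers.append(mono)
            for pos, extra in zip(stutter_positions, extras):
                if pos == idx:
                    monomers.extend([mono] * extra)
        for n_rep in repeat_choices:
            tag_parts = [f"stutter@{pos}x{extra + 1}"
                         for pos, extra in zip(stutter_positions, extras) if extra]
            if n_rep > 1:
                tag_parts.append(f"iterx{n_rep}")
            tag = ";".join(tag_parts) if tag_parts else "base"
            strips.append(Strip(gene_id=gene.gene_id,
                                monomers=tuple(monomers) * n_rep,
                                variant_tag=tag, **flags))
    return strips


@dataclass
class SubBGC:
    """A (possibly split) piece of a BGC; ``is_unsplit_copy`` marks the
    retained original of a CS/TE-split cluster, kept for non-collinear
    handling."""

    genes: list[GeneAnnotation]
    is_unsplit_copy: bool = False


def split_bgc(genes: Sequence[GeneAnnotation],
              max_dist: int = DEFAULT_MAX_BGC_DIST) -> list[SubBGC]:
    """Split an over-merged BGC.

    First the gene list (sorted by coordinate) is cut at inter-gene gaps
    exceeding ``max_dist`` nucleotides (gap = next start - previous
    end - 1, coordinates 1-based inclusive).  Each piece is then cut
    immediately before any CS-bearing gene that is not first and
    immediately after any TE-bearing gene that is not last; whenever a
    CS/TE cut fires, the uncut piece is also retained, flagged, since an
    out-of-place CS/TE may instead indicate a non-collinear assembly
    line.
    """
    genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    if not genes:
        return []

    pieces: list[list[GeneAnnotation]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        gap = cur.start - prev.end - 1
        if gap > max_dist:
            pieces.append([cur])
        else:
            pieces[-1].append(cur)

    out: list[SubBGC] = []
    for piece in pieces:
        cut_after = set()
        for i, gene in enumerate(piece):
            if gene.has_CS and i > 0:
                cut_after.add(i - 1)
            if gene.has_TE and i < len(piece) - 1:
                cut_after.add(i)
        if not cut_after:
            out.append(SubBGC(piece))
            continue
        sub: list[GeneAnnotation] = []
        for i, gene in enumerate(piece):
            sub.append(gene)
            if i in cut_after:
                out.append(SubBGC(sub))
                sub = []
        if sub:
            out.append(SubBGC(sub))
        out.append(SubBGC(piece, is_unsplit_copy=True))
    return out


def check_consistency(strip_order: Sequence[Strip]) -> bool:
    """The four ordering conditions for an assembly line: every CS strip
    is first, every TE strip is last, the first strip lacks an
    N-terminal COM domain and the last strip lacks a C-terminal one."""
    if not strip_order:
        raise ValueError("empty strip order")
    last = len(strip_order) - 1
    for i, strip in enumerate(strip_order):
        if strip.has_CS and i != 0:
            return False
        if strip.has_TE and i != last:
            return False
    return not strip_order[0].has_COM_N and not strip_order[-1].has_COM_C


def _violations(strip_order: Sequence[Strip]) -> set[str]:
    v = set()
    last = len(strip_order) - 1
    for i, strip in enumerate(strip_order):
        if strip.has_CS and i != 0:
            v.add("i")
        if strip.has_TE and i != last:
            v.add("ii")
    if strip_order[0].has_COM_N:
        v.add("iii")
    if strip_order[-1].has_COM_C:
        v.add("iv")
    return v


def _consistent_orders(flags: Sequence[Strip]) -> list[tuple[int, ...]]:
    """All consistent orderings (as index tuples) of the given strips,
    determined by flags only."""
    n = len(flags)
    orders = []
    for perm in permutations(range(n)):
        if check_consistency([flags[i] for i in perm]):
            orders.append(perm)
    return orders


def enumerate_assembly_lines(strips_per_gene: Sequence[Sequence[Strip]],
                             bgc_id: str,
                             max_sequences: int = DEFAULT_MAX_SEQUENCES
                             ) -> list[AssemblyLine]:
    """Order the genes' strips into candidate assembly lines.

    The collinear (genomic) order is assumed first.  If it is
    inconsistent solely because a CS strip is not first and/or a TE
    strip is not last, the offending strips are moved there (a stable
    repair).  Otherwise all consistent permutations are enumerated.  If
    nothing is consistent, the collinear order is used with a warning.
    The chosen orders are crossed with the per-gene strip variants;
    output is deterministic and capped at ``max_sequences``.
    """
    if not strips_per_gene or any(not variants for variants in strips_per_gene):
        raise ValueError("every gene needs at least one strip variant")
    # positional flags are shared by all variants of a gene
    rep = [variants[0] for variants in strips_per_gene]
    n = len(rep)

    collinear = tuple(range(n))

    def repaired(viol: set[str]) -> tuple[int, ...]:
        # stable move of the single CS strip to the front / TE strip to the back
        order = list(collinear)
        cs = [i for i in order if rep[i].has_CS]
        te = [i for i in order if rep[i].has_TE]
        if "i" in viol and len(cs) == 1:
            order.remove(cs[0])
            order.insert(0, cs[0])
        if "ii" in viol and len(te) == 1:
            order.remove(te[0])
            order.append(te[0])
        return tuple(order)

    viol = _violations(rep)
    if not viol:
        orders = [collinear]
    elif viol <= {"i", "ii"}:
        orders = [repaired(viol)]
    elif math.factorial(n) > max_sequences:
        logger.warning("%s: %d strips exceed the permutation budget; using the "
                       "collinear/repaired order only", bgc_id, n)
        orders = [repaired(viol)]
    else:
        orders = _consistent_orders(rep)
        if not orders:
            logger.warning("%s: no consistent strip order; falling back to collinear",
                           bgc_id)
            orders = [collinear]

    lines: list[AssemblyLine] = []
    for order in orders:
        for combo in product(*(strips_per_gene[i] for i in order)):
            if len(lines) >= max_sequences:
                logger.warning("%s: assembly-line enumeration capped at %d", bgc_id,
                               max_sequences)
                return lines
            monomers = tuple(m for strip in combo for m in strip.monomers)
            if not monomers:
                continue
            lines.append(AssemblyLine(
                monomers=monomers,
                strip_order=tuple((s.gene_id, s.variant_tag) for s in combo),
                bgc_id=bgc_id,
            ))
    return lines


def assemble_bgc(bgc: BGCRecord, alphabet: ResidueAlphabet,
                 max_dist: int = DEFAULT_MAX_BGC_DIST,
                 max_copies: int = DEFAULT_MAX_COPIES,
                 max_sequences: int = DEFAULT_MAX_SEQUENCES,
                 synonyms: Mapping[str, str] | None = None) -> list[AssemblyLine]:
    """Full BGC processing: split, build strip variants, enumerate
    consistent assembly lines for every (sub-)cluster."""
    lines: list[AssemblyLine] = []
    pieces = split_bgc(bgc.genes, max_dist)
    multi = len(pieces) > 1
    for k, piece in enumerate(pieces):
        suffix = ""
        if multi:
            suffix = ".unsplit" if piece.is_unsplit_copy else f".part{k}"
        strips_per_gene = [
            expand_deficient_modules(g, alphabet, max_copies, synonyms)
            for g in piece.genes
        ]
        strips_per_gene = [s for s in strips_per_gene if s]
        if not strips_per_gene:
            continue
        lines.extend(enumerate_assembly_lines(strips_per_gene, bgc.bgc_id + suffix,
                                              max_sequences))
    return lines


# ---------------------------------------------------------------------------
# JSON interchange format: {genome_id, bgcs: [{bgc_id, genes: [{gene_id,
# start, end, strand, modules: [[{kind, predictions?}]]}]}]}; coordinates
# 1-based inclusive.

def _domain_from_dict(d: dict) -> DomainAnnotation:
    preds = tuple((p["residue"], float(p["stachelhaus"]), float(p["svm"]))
                  for p in d.get("predictions", []))
    return DomainAnnotation(kind=d["kind"], predictions=preds)


def load_bgc_annotations(path: str | Path) -> list[GenomeRecord]:
    """Read genome/BGC annotations from the JSON interchange format."""
    with open(path, encoding="utf-8") as fh:
        docs = json.load(fh)
    if isinstance(docs, dict):
        docs = [docs]
    genomes = []
    for doc in docs:
        bgcs = []
        for b in doc["bgcs"]:
            genes = [
                GeneAnnotation(
                    gene_id=g["gene_id"], start=int(g["start"]), end=int(g["end"]),
                    strand=g.get("strand", "+"),
                    modules=[[_domain_from_dict(d) for d in mod] for mod in g["modules"]],
                )
                for g in b["genes"]
            ]
            bgcs.append(BGCRecord(bgc_id=b["bgc_id"], genes=genes))
        genomes.append(GenomeRecord(genome_id=doc["genome_id"], bgcs=bgcs))
    return genomes


def save_bgc_annotations(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write genome/BGC annotations to the JSON interchange format."""
    docs = []
    for genome in genomes:
        docs.append({
            "genome_id": genome.genome_id,
            "bgcs": [
                {
                    "bgc_id": b.bgc_id,
                    "genes": [
                        {
                            "gene_id": g.gene_id, "start": g.start, "end": g.end,
                            "strand": g.strand,
                            "modules": [
                                [
                                    {"kind": d.kind} if not d.predictions else
                                    {"kind": d.kind, "predictions": [
                                        {"residue": r, "stachelhaus": st, "svm": sv}
                                        for r, st, sv in d.predictions
                                    ]}
                                    for d in mod
                                ]
                                for mod in g.modules
                            ],
                        }
                        for g in b.genes
                    ],
                }
                for b in genome.bgcs
            ],
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(docs, fh, indent=1)
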