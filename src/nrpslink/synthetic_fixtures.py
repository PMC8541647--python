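"""Synthetic paired fixtures with planted ground truth.

The generator draws monomer sequences from the background model
(residues from their background frequencies, methylation and stereo
flags likewise), then emits the two matched views every other module
consumes: a monomer graph for the structure side and a BGC annotation
whose collinear assembly line encodes the same residues with high
specificity scores.  Controlled perturbations (residue mismatches,
insertions/deletions, gene shuffling with intact CS/TE flags, stutter
modules, tailoring edges, cyclization) emulate the noise the matcher
must tolerate; the applied alignment is recorded as ground truth.
Decoy structures are resampled from the same background so fixture
difficulty tracks the entropy of the residue alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from nrpslink.bgc_assembler import BGCRecord, DomainAnnotation, GeneAnnotation, GenomeRecord
from nrpslink.core_model import (
    BGC_GAP,
    NRP_GAP,
    BGCMonomer,
    Gap,
    NRPMonomer,
    ResidueAlphabet,
    ScoringParams,
    default_alphabet,
    validate_params,
)
from nrpslink.nrp_linearizer import MonomerGraph
from nrpslink.training import CuratedAlignment

__all__ = [
    "Perturbations",
    "PlantedPair",
    "generate_params",
    "generate_planted_pair",
    "generate_training_set",
    "generate_decoy_graphs",
]


@dataclass(frozen=True)
class Perturbations:
    """Perturbation settings for a planted pair.

    Rates are per-monomer probabilities; ``shuffle_strips`` permutes the
    genes in the annotation while keeping CS/TE flags on the true first
    and last genes so that consistency constraints can recover the
    planted order.
    """

    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0   # NRP monomer not encoded by any module
    deletion_rate: float = 0.0    # module whose product is absent from the NRP
    shuffle_strips: bool = False
    stutter: bool = False         # add one A-less deficient module
    n_tailoring_edges: int = 0
    cyclic: bool = False


@dataclass
class PlantedPair:
    """A synthetic compound/BGC pair with its generation ground truth."""

    compound_id: str
    bgc_id: str
    graph: MonomerGraph
    genome: GenomeRecord
    true_alignment: CuratedAlignment
    params: ScoringParams
    seed: int
    perturbations: Perturbations


def _draw(rng: np.random.Generator, items: list, probs: list[float]):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return items[int(rng.choice(len(items), p=p))]


def generate_params(seed: int | None = None,
                    alphabet: ResidueAlphabet | None = None) -> ScoringParams:
    """A random, internally consistent parameter set.

    Residue backgrounds are Dirichlet-distributed over the extended
    alphabet; match probabilities increase with specificity level; the
    methylation and stereo match/mismatch tables are drawn as normalized
    joint frequencies so that frequency estimators are consistent for
    them.
    """
    rng = np.random.default_rng(seed)
    alphabet = alphabet or default_alphabet()
    names = alphabet.extended
    p_a_vec = rng.dirichlet(np.full(len(names), 2.0))
    p_a = {a: float(p) for a, p in zip(names, p_a_vec)}

    def pair(lo=0.2, hi=0.8):
        p = float(rng.uniform(lo, hi))
        return {-1: p, 1: 1.0 - p}

    p_m = pair()
    p_e = pair()
    # increasing match probabilities over levels 1..5
    levels = np.sort(rng.uniform(0.05, 0.95, size=5))
    p_match_a = (0.0, *map(float, levels))
    # joint (match(-1), match(+1), mismatch(-1), mismatch(+1)) frequencies,
    # biased toward matches
    mj = rng.dirichlet([8.0, 8.0, 2.0, 2.0])
    ej = rng.dirichlet([8.0, 8.0, 2.0, 2.0])
    params = ScoringParams(
        p_match_a=p_match_a,
        p_a=p_a,
        p_m=p_m,
        p_e=p_e,
        p_match_m={-1: float(mj[0]), 1: float(mj[1])},
        p_mismatch_m={-1: float(mj[2]), 1: float(mj[3])},
        p_match_e={-1: float(ej[0]), 1: float(ej[1])},
        p_mismatch_e={-1: float(ej[2]), 1: float(ej[3])},
        p_insertion=float(rng.uniform(0.01, 0.10)),
        p_deletion=float(rng.uniform(0.01, 0.10)),
    )
    violations = validate_params(params)
    assert not violations, violations
    return params


def _sample_nrp_monomer(rng: np.random.Generator, params: ScoringParams,
                        alphabet: ResidueAlphabet, supported_only: bool = True
                        ) -> NRPMonomer:
    names = list(alphabet.residues) if supported_only else list(alphabet.extended)
    probs = [params.p_a[a] for a in names]
    residue = _draw(rng, names, probs)
    methylated = _draw(rng, [-1, 1], [params.p_m[-1], params.p_m[1]])
    stereo = _draw(rng, [-1, 1], [params.p_e[-1], params.p_e[1]])
    return NRPMonomer(residue, methylated, stereo)


def _monomer_graph(compound_id: str, monomers: list[NRPMonomer],
                   rng: np.random.Generator, cyclic: bool,
                   n_tailoring: int) -> MonomerGraph:
    g = nx.DiGraph()
    n = len(monomers)
    for i, m in enumerate(monomers):
        g.add_node(i, residue=m.residue, supported=True,
                   methylated=m.methylated, stereo=m.stereo)
    for i in range(n - 1):
        g.add_edge(i, i + 1, bond="amide")
    if cyclic:
        g.add_edge(n - 1, 0, bond="amide")
    tailoring_labels = ["ester", "glycosidic", "carbon-carbon", "disulfide"]
    added = 0
    attempts = 0
    while added < n_tailoring and attempts < 20 * max(1, n_tailoring):
        attempts += 1
        u, v = int(rng.integers(0, n)), int(rng.integers(0, n))
        if u == v or g.has_edge(u, v) or g.has_edge(v, u):
            continue
        g.add_edge(u, v, bond=str(rng.choice(tailoring_labels)))
        added += 1
    return MonomerGraph(compound_id=compound_id, graph=g)


def _module_for(residue: str, methylated: int, stereo: int,
                rng: np.random.Generator, alphabet: ResidueAlphabet,
                first: bool = False) -> list[DomainAnnotation]:
    """One typical NRPS module encoding the given monomer, with a
    high-scoring true prediction and a lower-scoring decoy prediction."""
    true_score = float(rng.integers(80, 101))
    decoy_pool = [a for a in alphabet.residues if a != residue]
    decoy = str(rng.choice(decoy_pool))
    decoy_score = float(rng.integers(20, 61))
    preds = ((residue, true_score, true_score), (decoy, decoy_score, decoy_score))
    domains = [] if first else [DomainAnnotation("C")]
    domains.append(DomainAnnotation("A", preds))
    if methylated == 1:
        domains.append(DomainAnnotation("M"))
    if stereo == 1:
        domains.append(DomainAnnotation("E"))
    domains.append(DomainAnnotation("PCP"))
    return domains


def generate_planted_pair(length: int, perturbations: Perturbations,
                          params: ScoringParams, seed: int,
                          alphabet: ResidueAlphabet | None = None,
                          compound_id: str = "compound",
                          genome_id: str = "genome",
                          bgc_id: str = "bgc") -> PlantedPair:
    """Generate one compound/BGC pair with planted ground truth.

    The true residue sequence is drawn from the background model; the
    BGC encodes it across 1-3 genes with high specificity for the true
    residues.  Perturbations then modify the structure side (mismatches,
    insertions), the gene side (deletions, stutter modules, strip
    shuffling) or the graph topology (tailoring edges, cyclization).
    With all perturbations at zero the planted alignment is gap-free and
    fully matched.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if perturbations.cyclic and perturbations.shuffle_strips:
        raise ValueError("cyclic backbone and strip shuffling cannot be combined")
    rng = np.random.default_rng(seed)
    alphabet = alphabet or default_alphabet()

    core = [_sample_nrp_monomer(rng, params, alphabet) for _ in range(length)]

    # per-core-position events plus interleaved insertions
    events: list[tuple[str, int | None]] = []  # (kind, core index)
    for i in range(length):
        if rng.random() < perturbations.deletion_rate and length > 2:
            events.append(("deletion", i))
            continue
        if rng.random() < perturbations.mismatch_rate:
            events.append(("mismatch", i))
        else:
            events.append(("match", i))
        if rng.random() < perturbations.insertion_rate:
            events.append(("insertion", None))

    # gene side: 1-3 genes over the core modules
    n_genes = int(rng.integers(1, min(3, length - 1) + 1))
    cut_points = sorted(rng.choice(np.arange(1, length), size=n_genes - 1,
                                   replace=False).tolist()) if n_genes > 1 else []
    bounds = [0, *cut_points, length]

    genes: list[GeneAnnotation] = []
    bgc_monomers: list[BGCMonomer] = []
    pos = 1
    for gi in range(n_genes):
        lo, hi = bounds[gi], bounds[gi + 1]
        modules = []
        for i in range(lo, hi):
            m = core[i]
            modules.append(_module_for(m.residue, m.methylated, m.stereo, rng,
                                       alphabet, first=(gi == 0 and i == lo)))
            spec = int(max(mod_d.predictions[0][1] for mod_d in modules[-1]
                           if mod_d.kind == "A"))
            bgc_monomers.append(BGCMonomer(spec, m.residue, m.methylated,
                                           1 if m.stereo == 1 else -1))
        if gi == 0:
            modules[0].insert(0, DomainAnnotation("CS"))
        if gi == n_genes - 1:
            modules[-1].append(DomainAnnotation("TE"))
        if perturbations.stutter and gi == 0 and hi - lo >= 1:
            modules.insert(1, [DomainAnnotation("C"), DomainAnnotation("PCP")])
        gene_len = 3000 * (hi - lo) + 200
        genes.append(GeneAnnotation(gene_id=f"{bgc_id}_g{gi}", start=pos,
                                    end=pos + gene_len, strand="+",
                                    modules=modules))
        pos += gene_len + 100

    if perturbations.shuffle_strips and n_genes > 1:
        order = rng.permutation(n_genes)
        shuffled = [genes[int(i)] for i in order]
        pos = 1
        re_positioned = []
        for g in shuffled:
            gene_len = g.end - g.start
            re_positioned.append(GeneAnnotation(g.gene_id, pos, pos + gene_len,
                                                g.strand, g.modules))
            pos += gene_len + 100
        genes = re_positioned

    # assemble the structure-side monomers and the ground-truth alignment
    bgc_iter = iter(bgc_monomers)
    nrp_monomers: list[NRPMonomer] = []
    alignment_cols: list[tuple[NRPMonomer | Gap, BGCMonomer | Gap]] = []
    for kind, i in events:
        if kind == "deletion":
            alignment_cols.append((NRP_GAP, next(bgc_iter)))
        elif kind == "insertion":
            ins = _sample_nrp_monomer(rng, params, alphabet)
            nrp_monomers.append(ins)
            alignment_cols.append((ins, BGC_GAP))
        else:
            m = core[i]
            if kind == "mismatch":
                others = [a for a in alphabet.residues if a != m.residue]
                m = NRPMonomer(str(rng.choice(others)), m.methylated, m.stereo)
            nrp_monomers.append(m)
            alignment_cols.append((m, next(bgc_iter)))

    if len(nrp_monomers) < 2:
        raise ValueError("perturbations removed too many monomers; use a longer core")

    graph = _monomer_graph(compound_id, nrp_monomers, rng,
                           perturbations.cyclic, perturbations.n_tailoring_edges)
    genome = GenomeRecord(genome_id=genome_id,
                          bgcs=[BGCRecord(bgc_id=bgc_id, genes=genes)])
    truth = CuratedAlignment(bgc_id=bgc_id, compound_id=compound_id,
                             columns=alignment_cols)
    return PlantedPair(compound_id=compound_id, bgc_id=bgc_id, graph=graph,
                       genome=genome, true_alignment=truth, params=params,
                       seed=seed, perturbations=perturbations)


def generate_decoy_graphs(n: int, length_range: tuple[int, int],
                          params: ScoringParams, seed: int,
                          alphabet: ResidueAlphabet | None = None,
                          prefix: str = "decoy") -> list[MonomerGraph]:
    """Decoy compounds: linear monomer graphs resampled from the
    background model with lengths drawn uniformly from
    ``length_range``."""
    rng = np.random.default_rng(seed)
    alphabet = alphabet or default_alphabet()
    graphs = []
    for k in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        monomers = [_sample_nrp_monomer(rng, params, alphabet) for _ in range(length)]
        graphs.append(_monomer_graph(f"{prefix}{k}", monomers, rng,
                                     cyclic=False, n_tailoring=0))
    return graphs


def generate_training_set(n_alignments: int, params: ScoringParams, seed: int,
                          alphabet: ResidueAlphabet | None = None,
                          columns_per_alignment: int = 12,
                          p_nrp_stereo_undetermined: float = 0.1
                          ) -> list[CuratedAlignment]:
    """Curated alignments sampled from the generative model the scoring
    assumes, so that the frequency estimators are consistent.

    Per column: the column type (match-like / insertion / deletion) is
    drawn so that insertion columns occur at rate ``p_insertion`` per
    structure monomer and deletions at ``p_deletion`` per gene monomer.
    In a match-like column the gene-side residue is drawn from the
    background, a specificity level is drawn uniformly, and the
    structure residue matches with the level's match probability or is
    redistributed over the other residues; methylation and stereo flag
    pairs are drawn from the joint match/mismatch frequencies.
    """
    if n_alignments < 1:
        raise ValueError("n_alignments must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = alphabet or default_alphabet()
    b = tuple(params.level_boundaries)

    # column-type frequencies solving  ins/(ins+match) = p_insertion,
    # del/(del+match) = p_deletion
    f_match = 1.0
    f_ins = params.p_insertion / max(1.0 - params.p_insertion, 1e-12)
    f_del = params.p_deletion / max(1.0 - params.p_deletion, 1e-12)

    # representative raw scores, one inside each discrete level
    level_scores = []
    lo = 1
    for edge in b:
        level_scores.append((lo + edge) // 2)
        lo = edge + 1

    names = list(alphabet.residues)
    bg = [params.p_a[a] for a in names]

    m_keys = [(-1, -1), (1, 1), (-1, 1), (1, -1)]
    m_probs = [params.p_match_m[-1], params.p_match_m[1],
               params.p_mismatch_m[-1], params.p_mismatch_m[1]]
    e_probs = [params.p_match_e[-1], params.p_match_e[1],
               params.p_mismatch_e[-1], params.p_mismatch_e[1]]

    alignments = []
    for k in range(n_alignments):
        columns: list[tuple[NRPMonomer | Gap, BGCMonomer | Gap]] = []
        for _ in range(columns_per_alignment):
            kind = _draw(rng, ["match", "insertion", "deletion"],
                         [f_match, f_ins, f_del])
            if kind == "insertion":
                columns.append((_sample_nrp_monomer(rng, params, alphabet), BGC_GAP))
                continue
            # gene-side monomer
            a_bgc = _draw(rng, names, bg)
            level = int(rng.integers(1, 6))
            s = level_scores[level - 1]
            m_nrp, m_bgc = _draw(rng, m_keys, m_probs)
            e_nrp, e_bgc = _draw(rng, m_keys, e_probs)
            bgc = BGCMonomer(s, a_bgc, m_bgc, e_bgc)
            if kind == "deletion":
                columns.append((NRP_GAP, bgc))
                continue
            if rng.random() < params.p_match_a[level]:
                a_nrp = a_bgc
            else:
                others = [a for a in names if a != a_bgc]
                w = [params.p_a[a] for a in others]
                a_nrp = _draw(rng, others, w)
            if rng.random() < p_nrp_stereo_undetermined:
                e_nrp = 0
            columns.append((NRPMonomer(a_nrp, m_nrp, e_nrp), bgc))
        alignments.append(CuratedAlignment(bgc_id=f"tbgc{k}",
                                           compound_id=f"tcmp{k}",
                                           columns=columns))
    return alignments
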