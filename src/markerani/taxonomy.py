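"""Species delimitation and taxonomy auditing from marker-concatenate ANI.

The delimitation rule is one-dimensional in ANIstt: a pair is intra-species at
or above the 96% intra floor, inter-species at or below the 94% inter ceiling,
and intermediate in the open zone between — the "genetic continuum" band.
When genome ANI is also available a pair can additionally be placed in the 2-D
intra region (ANIm > 95 and ANIstt > 96), inter region (ANIm < 93 and
ANIstt < 94) or between them (strict inequalities on all bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .ani import PairwiseANITable, anistt, gene_ani_table, align_pair
from .seqio import GeneAlignment, StrainPanel, _norm_species
from .screen import ThresholdConfig, species_relation

__all__ = [
    "PairClassification",
    "AssignmentResult",
    "classify_pair",
    "audit_type_strain_panel",
    "assign_strain",
]


@dataclass(frozen=True)
class PairClassification:
    id_a: str
    id_b: str
    anistt: float
    anim: float | None
    category: str  # intra | inter | intermediate
    region_2d: str | None  # intra-region | inter-region | between | None
    flags: frozenset[str] = frozenset()


def classify_pair(
    anistt_value: float,
    anim: float | None = None,
    cfg: ThresholdConfig | None = None,
    id_a: str = "A",
    id_b: str = "B",
) -> PairClassification:
    """Categorize one strain pair from its marker-concatenate ANI.

    Boundaries are closed on the observed extremes: intra iff ANIstt >=
    ``intra_floor`` (96), inter iff ANIstt <= ``inter_ceiling`` (94); the
    remainder is intermediate. The 2-D region uses strict inequalities and is
    only set when a genome ANI is supplied.
    """
    cfg = cfg or ThresholdConfig()
    if not (0.0 <= anistt_value <= 100.0):
        raise ValueError("ANIstt outside [0, 100]")
    if anistt_value >= cfg.intra_floor:
        category = "intra"
    elif anistt_value <= cfg.inter_ceiling:
        category = "inter"
    else:
        category = "intermediate"
    region = None
    flags: set[str] = set()
    if anim is not None:
        if anim > cfg.region_genome_high and anistt_value > cfg.intra_floor:
            region = "intra-region"
        elif anim < cfg.region_genome_low and anistt_value < cfg.inter_ceiling:
            region = "inter-region"
        else:
            region = "between"
            flags.add("genetic-continuum")
    elif category == "intermediate":
        flags.add("genetic-continuum")
    return PairClassification(
        id_a=id_a,
        id_b=id_b,
        anistt=anistt_value,
        anim=anim,
        category=category,
        region_2d=region,
        flags=frozenset(flags),
    )


def audit_type_strain_panel(
    table: PairwiseANITable,
    labels: Mapping[str, str],
    cfg: ThresholdConfig | None = None,
) -> dict:
    """Audit a panel of type strains, one per species.

    Counts how many inter-species type-strain pairs fall below the inter
    ceiling (the strict "supported" criterion of the per-genus audits) and,
    because the literature also invokes the intra floor as the lenient bound,
    how many fall below it as well. Species whose type strains exceed the
    intra floor are linked, and the connected components of that graph are the
    merge candidates (prospective synonymies).
    """
    cfg = cfg or ThresholdConfig()
    species_of: dict[str, str] = {}
    for sid in table.ids:
        if sid not in labels:
            raise KeyError(f"strain {sid!r} has no species label")
        sp = _norm_species(labels[sid])
        if sp in species_of.values():
            raise ValueError(f"duplicate species among type strains: {labels[sid]!r}")
        species_of[sid] = sp
    n_inter = 0
    n_below_ceiling = 0
    n_below_floor = 0
    g = nx.Graph()
    g.add_nodes_from(species_of.values())
    for a, b, ani in table.pairs():
        n_inter += 1
        if ani < cfg.inter_ceiling:
            n_below_ceiling += 1
        if ani < cfg.intra_floor:
            n_below_floor += 1
        if ani >= cfg.intra_floor:
            g.add_edge(species_of[a], species_of[b])
    merge_candidates = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) > 1),
        key=lambda c: c[0],
    )
    return {
        "n_inter_pairs": n_inter,
        "n_below_inter_ceiling": n_below_ceiling,
        "n_below_intra_floor": n_below_floor,
        "merge_candidates": merge_candidates,
    }


@dataclass
class AssignmentResult:
    query_id: str
    best_type_strain: str
    best_anistt: float
    verdict: str  # assigned:<species> | novel-species-candidate | ambiguous
    all_scores: dict[str, float]
    flags: frozenset[str] = frozenset()


def _pair_anistt_unaligned(
    query_genes: Mapping[str, str], ref_genes: Mapping[str, str]
) -> float:
    """Pool diffs/sites across genes, aligning each query/reference gene pair."""
    from .ani import gene_pair_diff

    diffs = sites = 0
    for gene, qseq in query_genes.items():
        ra, rb = align_pair(qseq, ref_genes[gene])
        stat = gene_pair_diff(ra, rb)
        diffs += stat.diffs
        sites += stat.sites
    return 100.0 * (1.0 - diffs / sites)


def assign_strain(
    query_id: str,
    query_genes: Mapping[str, str],
    panel: StrainPanel,
    cfg: ThresholdConfig | None = None,
    genes: Sequence[str] = ("SMc00019", "truA", "thrA"),
    aligned: bool = False,
) -> AssignmentResult:
    """Assign a query strain to a species by ANIstt against every type strain.

    The query needs all marker genes. Verdict: assigned to the best-scoring
    type strain's species when the best ANIstt reaches the intra floor; a
    novel-species candidate when even the best score sits at or below the
    inter ceiling; ambiguous (intermediate) otherwise. If the query is itself
    a labeled type strain assigned to a different species, the pair is flagged
    as a later-synonym candidate (which name has priority is not decided here).
    """
    cfg = cfg or ThresholdConfig()
    missing = [g for g in genes if g not in query_genes]
    if missing:
        raise ValueError(f"query {query_id!r} lacks genes {missing}")
    type_strains = [s for s in panel.strains if s.is_type_strain and s.id != query_id]
    if not type_strains:
        raise ValueError("reference panel holds no type strains")

    scores: dict[str, float] = {}
    for ts in type_strains:
        if aligned:
            diffs = sites = 0
            from .ani import gene_pair_diff

            for g in genes:
                aln = panel.alignment(g)
                stat = gene_pair_diff(query_genes[g], aln.rows[ts.id])
                diffs += stat.diffs
                sites += stat.sites
            scores[ts.id] = 100.0 * (1.0 - diffs / sites)
        else:
            ref = {g: panel.alignment(g).rows[ts.id].replace("-", "") for g in genes}
            scores[ts.id] = _pair_anistt_unaligned(
                {g: query_genes[g].replace("-", "") for g in genes}, ref
            )

    best_id = max(scores, key=lambda k: (scores[k], k))
    best = scores[best_id]
    best_species = next(s.species for s in type_strains if s.id == best_id)
    if best >= cfg.intra_floor:
        verdict = f"assigned:{best_species}"
    elif best <= cfg.inter_ceiling:
        verdict = "novel-species-candidate"
    else:
        verdict = "ambiguous"

    flags: set[str] = set()
    query_rec = next((s for s in panel.strains if s.id == query_id), None)
    if (
        query_rec is not None
        and query_rec.is_type_strain
        and verdict.startswith("assigned:")
        and _norm_species(best_species) != _norm_species(query_rec.species)
    ):
        flags.add("later-synonym-candidate")
    return AssignmentResult(
        query_id=query_id,
        best_type_strain=best_id,
        best_anistt=best,
        verdict=verdict,
        all_scores=scores,
        flags=frozenset(flags),
    )
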