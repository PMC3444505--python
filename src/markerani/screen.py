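"""Marker-gene screening.

A candidate taxonomic marker is a core gene whose gene-level ANI (ANIg)
reproduces the species structure defined by genome-level ANI: intra-species
pairs stay above a fixed gene boundary (95% or 96%) exactly when the genome
assignment (ANIm >= 95%) says they are conspecific, and the gene shows a clear
gap between the lowest intra-species and highest inter-species ANI. Screening
additionally prefers short genes (amplifiable, < 1.5 kb) and gene trees close
to a reference species tree (normalized Robinson-Foulds distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ani import PairwiseANITable, gene_ani_table
from .seqio import GeneAlignment, StrainPanel, _norm_species

__all__ = [
    "ThresholdConfig",
    "GapReport",
    "MarkerReport",
    "species_relation",
    "gap_statistic",
    "boundary_concordance",
    "screen_markers",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """The ANI boundary constants of the delimitation scheme.

    * ``genome_species_boundary``: ANIm at/above which a pair is conspecific
      (95%, closed at the boundary).
    * ``candidate_gene_boundaries``: thresholds a marker gene may use (95, 96).
    * ``intra_floor`` / ``inter_ceiling``: the observed extremes of the marker
      concatenate — lowest intra-species ANIstt 96%, highest inter-species 94%;
      the open interval between them is the intermediate zone.
    * ``region_genome_low/high``: the genome-side bounds (93%, 95%) of the 2-D
      inter/intra regions used for scatter tallies (strict inequalities).
    """

    genome_species_boundary: float = 95.0
    candidate_gene_boundaries: frozenset[float] = frozenset({95.0, 96.0})
    intra_floor: float = 96.0
    inter_ceiling: float = 94.0
    region_genome_low: float = 93.0
    region_genome_high: float = 95.0

    def __post_init__(self) -> None:
        if not self.inter_ceiling < self.intra_floor:
            raise ValueError("need inter_ceiling < intra_floor")
        if not self.region_genome_low < self.region_genome_high:
            raise ValueError("need region_genome_low < region_genome_high")
        for v in (
            self.genome_species_boundary,
            self.intra_floor,
            self.inter_ceiling,
            self.region_genome_low,
            self.region_genome_high,
            *self.candidate_gene_boundaries,
        ):
            if not (0.0 < v < 100.0):
                raise ValueError(f"threshold {v} outside (0, 100)")


@dataclass
class GapReport:
    """Min intra-species ANI, max inter-species ANI and their gap for one table."""

    source: str
    min_intra: float
    max_inter: float
    violating_pairs: list[tuple[str, str, float, str]] = field(default_factory=list)

    @property
    def gap(self) -> float:
        return self.min_intra - self.max_inter


@dataclass
class MarkerReport:
    gene_name: str
    length_bp: int
    concordant: bool
    chosen_boundary: float | None
    gap_report: GapReport | None
    rf_congruence: float | None
    rank: int | None = None
    failure: str | None = None


def species_relation(labels: Mapping[str, str], id_a: str, id_b: str) -> str:
    """'intra' iff the two strains carry the same species label (case-folded)."""
    for x in (id_a, id_b):
        if x not in labels:
            raise KeyError(f"strain {x!r} has no species label")
    return (
        "intra"
        if _norm_species(labels[id_a]) == _norm_species(labels[id_b])
        else "inter"
    )


def gap_statistic(
    table: PairwiseANITable,
    labels: Mapping[str, str],
    cfg: ThresholdConfig | None = None,
) -> GapReport:
    """Boundary extremes of a labeled ANI table.

    ``violating_pairs`` lists intra pairs below ``intra_floor`` and inter pairs
    above ``inter_ceiling``; it is empty exactly when the table respects both
    boundaries and the inter maximum sits below the intra minimum.
    """
    cfg = cfg or ThresholdConfig()
    intra: list[float] = []
    inter: list[float] = []
    violations: list[tuple[str, str, float, str]] = []
    for a, b, ani in table.pairs():
        rel = species_relation(labels, a, b)
        if rel == "intra":
            intra.append(ani)
            if ani < cfg.intra_floor:
                violations.append((a, b, ani, f"intra pair below floor {cfg.intra_floor}"))
        else:
            inter.append(ani)
            if ani > cfg.inter_ceiling:
                violations.append((a, b, ani, f"inter pair above ceiling {cfg.inter_ceiling}"))
    if not intra:
        raise ValueError("no intra-species pairs in table")
    if not inter:
        raise ValueError("no inter-species pairs in table")
    return GapReport(
        source=table.source,
        min_intra=min(intra),
        max_inter=max(inter),
        violating_pairs=violations,
    )


def boundary_concordance(
    gene_table: PairwiseANITable,
    genome_table: PairwiseANITable,
    labels: Mapping[str, str],
    cfg: ThresholdConfig | None = None,
) -> dict:
    """Does some candidate gene boundary reproduce the genome assignments?

    The genome calls a pair conspecific iff ANIm >= ``genome_species_boundary``.
    The gene is concordant iff some threshold t among the candidates makes
    (ANIg >= t) agree with the genome call on every shared pair; the smallest
    such t is reported (conservative toward lumping). ``mismatches`` lists the
    pairs disagreeing under the best-scoring candidate.
    """
    cfg = cfg or ThresholdConfig()
    gene_pairs = {(a, b) for a, b, _ in gene_table.pairs()}
    genome_pairs = {(a, b) for a, b, _ in genome_table.pairs()}
    if gene_pairs != genome_pairs:
        raise ValueError(
            "gene and genome tables cover different pairs "
            f"(only-gene: {sorted(gene_pairs - genome_pairs)[:3]}, "
            f"only-genome: {sorted(genome_pairs - gene_pairs)[:3]})"
        )
    best_t: float | None = None
    best_mismatches: list[tuple[str, str, float, float]] | None = None
    for t in sorted(cfg.candidate_gene_boundaries):
        mism = []
        for a, b in gene_pairs:
            genome_same = genome_table.get(a, b) >= cfg.genome_species_boundary
            gene_same = gene_table.get(a, b) >= t
            if gene_same != genome_same:
                mism.append((a, b, gene_table.get(a, b), genome_table.get(a, b)))
        if not mism:
            return {"concordant": True, "chosen_boundary": t, "mismatches": []}
        if best_mismatches is None or len(mism) < len(best_mismatches):
            best_t, best_mismatches = t, mism
    return {
        "concordant": False,
        "chosen_boundary": None,
        "mismatches": best_mismatches or [],
        "best_candidate": best_t,
    }


def _nj_rf_to_reference(table: PairwiseANITable, ref_tree) -> float:
    from .phylo import nj_tree, rf_distance

    tree = nj_tree(table)
    return rf_distance(tree, ref_tree, normalize=True)


def screen_markers(
    panel: StrainPanel,
    genome_table: PairwiseANITable,
    cfg: ThresholdConfig | None = None,
    max_len_bp: int = 1500,
    ref_tree=None,
    gap_mode: str = "pairwise",
) -> list[MarkerReport]:
    """Screen every gene of a panel and rank candidate markers.

    Ranking: concordant genes first, then larger ANI gap, then smaller
    normalized RF distance to the reference tree (when supplied), then shorter
    gene, with the gene name as the deterministic final tie-break. Genes whose
    statistics cannot be computed are reported as screened-out with the reason
    rather than dropped. ``max_len_bp`` is annotated via the ranking's length
    criterion; genes longer than it still appear, ranked after equally good
    shorter genes (length is a preference, not a hard filter).
    """
    cfg = cfg or ThresholdConfig()
    labels = panel.labels
    reports: list[MarkerReport] = []
    for aln in panel.gene_alignments:
        try:
            gene_table = gene_ani_table(aln, gap_mode=gap_mode)
            conc = boundary_concordance(gene_table, genome_table, labels, cfg)
            gap = gap_statistic(gene_table, labels, cfg)
            rf = (
                _nj_rf_to_reference(gene_table, ref_tree)
                if ref_tree is not None
                else None
            )
            reports.append(
                MarkerReport(
                    gene_name=aln.gene_name,
                    length_bp=aln.ungapped_length(),
                    concordant=conc["concordant"],
                    chosen_boundary=conc["chosen_boundary"],
                    gap_report=gap,
                    rf_congruence=rf,
                )
            )
        except (ValueError, KeyError) as exc:
            reports.append(
                MarkerReport(
                    gene_name=aln.gene_name,
                    length_bp=aln.ungapped_length(),
                    concordant=False,
                    chosen_boundary=None,
                    gap_report=None,
                    rf_congruence=None,
                    failure=str(exc),
                )
            )

    def sort_key(r: MarkerReport):
        return (
            r.failure is not None,
            not r.concordant,
            -(r.gap_report.gap if r.gap_report else float("-inf")),
            r.rf_congruence if r.rf_congruence is not None else 0.0,
            r.length_bp,
            r.gene_name,
        )

    reports.sort(key=sort_key)
    for i, r in enumerate(reports, start=1):
        r.rank = i
    return reports
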