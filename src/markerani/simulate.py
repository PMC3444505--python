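"""Synthetic strain panels with known divergence structure.

The generator emulates the situation the marker-screening workflow is built
for: a clade of bacterial strains grouped into species, where intra-species
per-site divergences are small (default up to 0.03) and inter-species
divergences are clearly larger (default 0.06–0.20, spanning roughly 80–100%
identity), with core genes evolving at gene-specific rate multipliers,
optional inter-lineage gene transfer (recombination) that decouples a gene's
history from the genome's, and neutral intergenic filler.

Sequences evolve root → species ancestor → strain under a uniform
("Jukes–Cantor-like") substitution model: each site mutates with the edge's
per-site probability, to one of the three other bases uniformly. No indels are
generated, so gene "alignments" are trivially the raw sequences and the true
divergence of any pair is an exact realized count, logged in
:class:`SimTruth` by direct comparison of the final sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import GeneAlignment, StrainPanel, StrainRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "TransferEvent",
    "simulate_panel",
    "expected_ani",
    "simulate_genome_pair",
    "mutate_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the panel generator.

    Defaults draw a 5-species, 3-strains-per-species panel with a clean ANI
    gap: intra-species divergence at most 0.03 (ANI >= 97) and inter-species
    divergence at least 0.06 (ANI <= 94). ``gene_rate_multipliers`` gives one
    clock multiplier per gene (1.0 = genome-like); ``n_transfer_events``
    replaces a recipient's gene with a cross-species donor copy.
    """

    seed: int
    n_species: int = 5
    strains_per_species: int = 3
    intra_divergence: tuple[float, float] = (0.0, 0.03)
    inter_divergence: tuple[float, float] = (0.06, 0.20)
    n_genes: int = 3
    gene_length: tuple[int, int] = (900, 1500)
    gene_rate_multipliers: tuple[float, ...] | None = None
    n_transfer_events: int = 0
    transfer_genes: tuple[str, ...] | None = None
    genome_filler_bp: int = 20_000

    def __post_init__(self) -> None:
        for lo, hi in (self.intra_divergence, self.inter_divergence, self.gene_length):
            if lo > hi:
                raise ValueError("empty range in SimConfig")
        if self.gene_rate_multipliers is not None:
            if len(self.gene_rate_multipliers) != self.n_genes:
                raise ValueError("need one rate multiplier per gene")
            if any(m < 0 for m in self.gene_rate_multipliers):
                raise ValueError("rates must be >= 0")
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValueError("need at least one species and one strain")

    @property
    def multipliers(self) -> tuple[float, ...]:
        return self.gene_rate_multipliers or tuple(1.0 for _ in range(self.n_genes))


@dataclass(frozen=True)
class TransferEvent:
    gene: str
    donor: str
    recipient: str


@dataclass
class SimTruth:
    """Realized (not nominal) pairwise divergences of a simulated panel."""

    labels: dict[str, str]
    genome_divergence: dict[tuple[str, str], float]
    gene_divergence: dict[str, dict[tuple[str, str], float]]
    transfers: list[TransferEvent] = field(default_factory=list)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def divergence(self, id_a: str, id_b: str, scope: str = "genome") -> float:
        key = self._key(id_a, id_b)
        if scope == "genome":
            table = self.genome_divergence
        else:
            if scope not in self.gene_divergence:
                raise KeyError(f"unknown gene scope {scope!r}")
            table = self.gene_divergence[scope]
        if key not in table:
            raise KeyError(f"unknown pair {key}")
        return table[key]


def expected_ani(truth: SimTruth, id_a: str, id_b: str, scope: str = "genome") -> float:
    """True ANI of a pair: 100·(1 − realized substitution fraction)."""
    return 100.0 * (1.0 - truth.divergence(id_a, id_b, scope))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, d: float) -> np.ndarray:
    """Each site mutates with probability d, to a different base uniformly."""
    d = min(d, 0.75)
    out = seq.copy()
    mask = rng.random(len(seq)) < d
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode("ascii")


def mutate_sequence(seq: str, divergence: float, seed: int) -> tuple[str, int]:
    """Mutate a sequence at a per-site probability; returns (mutant, n_diffs)."""
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    enc = lut[codes]
    if np.any(enc == 255):
        raise ValueError("sequence must be unambiguous A/C/G/T")
    mut = _mutate(rng, enc, divergence)
    return _decode(mut), int((mut != enc).sum())


def simulate_genome_pair(length: int, divergence: float, seed: int) -> tuple[str, str, float]:
    """An indel-free genome pair at a nominal per-site divergence.

    Returns (genome_a, genome_b, realized_divergence); the realized value is
    the exact fraction of differing sites and is what an ANI estimator should
    recover as 100·(1 − realized).
    """
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, length)
    b = _mutate(rng, a, divergence)
    realized = float((a != b).mean())
    return _decode(a), _decode(b), realized


def simulate_panel(cfg: SimConfig) -> tuple[StrainPanel, SimTruth]:
    """Generate a labeled strain panel plus its ground truth.

    Construction is a fixed-depth, coalescent-free species star: each species
    ancestor sits at a depth drawn from half the inter-species range below the
    root, each strain at a depth from half the intra range below its species
    ancestor, so inter-pair path lengths land in the inter range and intra
    pairs in the intra range. Each gene (and the intergenic filler, multiplier
    1.0) evolves independently along these edges at its rate multiplier.
    Transfer events then overwrite a random cross-species recipient's gene
    with the donor's copy. Genomes are the concatenation of the
    (post-transfer) genes and the filler. Identical seeds give byte-identical
    panels.
    """
    rng = np.random.default_rng(cfg.seed)
    mults = cfg.multipliers
    gene_names = [f"gene{i + 1:02d}" for i in range(cfg.n_genes)]
    gene_lengths = [
        int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        for _ in gene_names
    ]

    # depths: species ancestors below the root, strains below their ancestor
    sp_depths = rng.uniform(
        cfg.inter_divergence[0] / 2, cfg.inter_divergence[1] / 2, size=cfg.n_species
    )
    strain_depths = rng.uniform(
        cfg.intra_divergence[0] / 2,
        cfg.intra_divergence[1] / 2,
        size=(cfg.n_species, cfg.strains_per_species),
    )

    strains: list[StrainRecord] = []
    strain_ids: list[str] = []
    for s in range(cfg.n_species):
        for t in range(cfg.strains_per_species):
            sid = f"sp{s + 1:02d}_st{t + 1:02d}"
            strains.append(
                StrainRecord(sid, f"species_{s + 1:02d}", is_type_strain=(t == 0))
            )
            strain_ids.append(sid)

    blocks = list(zip(gene_names, gene_lengths, mults)) + [
        ("__filler__", cfg.genome_filler_bp, 1.0)
    ]
    seqs: dict[str, dict[str, np.ndarray]] = {name: {} for name, _, _ in blocks}
    for name, length, mult in blocks:
        if length <= 0:
            continue
        root = _random_seq(rng, length)
        for s in range(cfg.n_species):
            anc = _mutate(rng, root, sp_depths[s] * mult)
            for t in range(cfg.strains_per_species):
                sid = f"sp{s + 1:02d}_st{t + 1:02d}"
                seqs[name][sid] = _mutate(rng, anc, strain_depths[s, t] * mult)

    transfers: list[TransferEvent] = []
    if cfg.n_transfer_events:
        if cfg.n_species < 2:
            raise ValueError("transfers need at least two species")
        pool = list(cfg.transfer_genes) if cfg.transfer_genes else gene_names
        unknown = set(pool) - set(gene_names)
        if unknown:
            raise ValueError(f"transfer_genes not in panel: {sorted(unknown)}")
        for ev in range(cfg.n_transfer_events):
            # round-robin over the transferable genes so each receives events
            gene = pool[ev % len(pool)]
            sa, sb = rng.choice(cfg.n_species, size=2, replace=False)
            donor = f"sp{sa + 1:02d}_st{int(rng.integers(0, cfg.strains_per_species)) + 1:02d}"
            recipient = f"sp{sb + 1:02d}_st{int(rng.integers(0, cfg.strains_per_species)) + 1:02d}"
            seqs[gene][recipient] = seqs[gene][donor].copy()
            transfers.append(TransferEvent(gene=gene, donor=donor, recipient=recipient))

    genomes_arr = {
        sid: np.concatenate(
            [seqs[name][sid] for name, length, _ in blocks if length > 0]
        )
        for sid in strain_ids
    }

    genome_div: dict[tuple[str, str], float] = {}
    gene_div: dict[str, dict[tuple[str, str], float]] = {g: {} for g in gene_names}
    for i, a in enumerate(strain_ids):
        for b in strain_ids[i + 1 :]:
            key = (a, b)
            genome_div[key] = float((genomes_arr[a] != genomes_arr[b]).mean())
            for g in gene_names:
                gene_div[g][key] = float((seqs[g][a] != seqs[g][b]).mean())

    alignments = [
        GeneAlignment(g, {sid: _decode(seqs[g][sid]) for sid in strain_ids})
        for g in gene_names
    ]
    panel = StrainPanel(
        strains=strains,
        genomes={sid: _decode(genomes_arr[sid]) for sid in strain_ids},
        gene_alignments=alignments,
    )
    truth = SimTruth(
        labels={s.id: s.species for s in strains},
        genome_divergence=genome_div,
        gene_divergence=gene_div,
        transfers=transfers,
    )
    return panel, truth
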