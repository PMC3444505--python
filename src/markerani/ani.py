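"""Average nucleotide identity engines.

Three ANI flavours, all on the 0–100% scale:

* gene ANI (ANIg): per-pair difference counting on an aligned gene, under
  pairwise deletion — a column contributes only when both rows carry an
  unambiguous A/C/G/T, so gaps and IUPAC ambiguity codes never count as
  differences;
* concatenate ANI: ANIg of a gene concatenation (for the SMc00019-truA-thrA
  marker set this is the ANIstt statistic), i.e. diffs and sites pooled across
  genes, which length-weights each gene rather than averaging per-gene ANIg;
* genome ANI: a fragment-seeded whole-genome estimator in the ANIm/ANIb
  tradition — the query is cut into non-overlapping fragments, each fragment is
  placed on the subject by exact k-mer seeding (both strands) and aligned
  globally against a window around the best seed diagonal, and fragments
  passing the classic 30%-identity / 70%-coverage filter contribute their
  identity, weighted by aligned length; the final value symmetrizes the two
  directions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from .seqio import GeneAlignment, StrainPanel, concatenate

__all__ = [
    "AniParams",
    "PairDiffStat",
    "PairwiseANITable",
    "GenomeAniResult",
    "gene_pair_diff",
    "gene_ani_table",
    "anistt",
    "genome_ani",
    "align_pair",
]

_ACGT = frozenset(b"ACGT")
_RC = bytes.maketrans(b"ACGTRYSWKMBDHVN", b"TGCAYRSWMKVHDBN")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AniParams:
    """Tuning knobs of the fragment-seeded genome ANI estimator.

    ``fragment_len`` 1020 bp and the 30%/70% identity/coverage floor follow the
    classic fragment-ANI recipe; ``seed_k`` is the exact-match seed length used
    to place fragments before alignment.
    """

    fragment_len: int = 1020
    seed_k: int = 15
    min_frag_identity: float = 30.0
    min_frag_coverage: float = 0.70
    both_strands: bool = True
    window_margin: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.seed_k < self.fragment_len):
            raise ValueError("need 0 < seed_k < fragment_len")
        if not (0 <= self.min_frag_identity <= 100):
            raise ValueError("min_frag_identity must be in [0, 100]")
        if not (0 < self.min_frag_coverage <= 1):
            raise ValueError("min_frag_coverage must be in (0, 1]")


@dataclass(frozen=True)
class PairDiffStat:
    """Compared sites and differences for one strain pair."""

    diffs: int
    sites: int

    def __post_init__(self) -> None:
        if not (0 <= self.diffs <= self.sites):
            raise ValueError("need 0 <= diffs <= sites")
        if self.sites == 0:
            raise ValueError("zero compared sites: pair unreportable")

    @property
    def ani(self) -> float:
        return 100.0 * (1.0 - self.diffs / self.sites)


class PairwiseANITable:
    """Symmetric strain x strain ANI table tagged by source.

    Source is ``genome``, ``gene:<name>`` or ``concatenate:<names>``. Values
    are stored at full float precision with per-pair support (compared sites or
    aligned bp); the diagonal is implicitly 100.
    """

    def __init__(self, source: str = "genome"):
        self.source = source
        self._values: dict[tuple[str, str], float] = {}
        self._support: dict[tuple[str, str], float] = {}
        self._ids: list[str] = []

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, ani: float, support: float = 1.0) -> None:
        if a == b:
            raise ValueError("diagonal is implicit")
        if not (0.0 <= ani <= 100.0):
            raise ValueError(f"ANI {ani} outside [0, 100]")
        if support <= 0:
            raise ValueError("support must be positive")
        for x in (a, b):
            if x not in self._ids:
                self._ids.append(x)
        self._values[self._key(a, b)] = float(ani)
        self._support[self._key(a, b)] = float(support)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        return self._values[self._key(a, b)]

    def support(self, a: str, b: str) -> float:
        return self._support[self._key(a, b)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._values

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), v in self._values.items():
            yield a, b, v

    def __len__(self) -> int:
        return len(self._values)


def _row_codes(row: str) -> np.ndarray:
    return np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def gene_pair_diff(row_a: str, row_b: str, gap_mode: str = "pairwise") -> PairDiffStat:
    """Count differing sites between two aligned rows under pairwise deletion.

    A column is compared iff both rows hold an unambiguous A/C/G/T (case
    folded). ``gap_mode`` is fixed to pairwise deletion here; complete deletion
    is applied at table level where the full alignment is in view.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    if gap_mode != "pairwise":
        raise ValueError("gene_pair_diff implements pairwise deletion only")
    a = _row_codes(row_a)
    b = _row_codes(row_b)
    ok = np.isin(a, _ACGT_CODES) & np.isin(b, _ACGT_CODES)
    sites = int(ok.sum())
    if sites == 0:
        raise ValueError("zero compared sites: pair unreportable")
    diffs = int((ok & (a != b)).sum())
    return PairDiffStat(diffs=diffs, sites=sites)


def _complete_deletion(aln: GeneAlignment) -> GeneAlignment:
    """Drop every column where any row has a gap or ambiguity code."""
    mats = {sid: _row_codes(r) for sid, r in aln.rows.items()}
    keep = np.ones(aln.length, dtype=bool)
    for m in mats.values():
        keep &= np.isin(m, _ACGT_CODES)
    rows = {
        sid: bytes(m[keep]).decode("ascii") for sid, m in mats.items()
    }
    return GeneAlignment(aln.gene_name, rows)


def gene_ani_table(aln: GeneAlignment, gap_mode: str = "pairwise") -> PairwiseANITable:
    """ANIg for every unordered strain pair of one gene alignment.

    Pairs with zero compared sites are collected (skipped, recorded on the
    table's ``failures`` attribute) rather than aborting the whole gene.
    """
    if gap_mode == "complete":
        aln = _complete_deletion(aln)
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    table = PairwiseANITable(source=f"gene:{aln.gene_name}")
    failures: list[tuple[str, str, str]] = []
    ids = list(aln.rows)
    mats = {sid: _row_codes(aln.rows[sid]) for sid in ids}
    ok = {sid: np.isin(m, _ACGT_CODES) for sid, m in mats.items()}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            both = ok[a] & ok[b]
            sites = int(both.sum())
            if sites == 0:
                failures.append((a, b, "zero compared sites"))
                continue
            diffs = int((both & (mats[a] != mats[b])).sum())
            table.set(a, b, 100.0 * (1.0 - diffs / sites), support=sites)
    table.failures = failures  # type: ignore[attr-defined]
    return table


def anistt(
    panel: StrainPanel,
    genes: Sequence[str] = ("SMc00019", "truA", "thrA"),
    gap_mode: str = "pairwise",
) -> PairwiseANITable:
    """Concatenate ANI over the named marker genes (ANIstt for the default set).

    Equivalent to pooling diffs and sites across genes — each gene contributes
    proportionally to its compared sites, which is the length-weighted
    combination, not the unweighted mean of per-gene ANIg values.
    """
    alns = [panel.alignment(g) for g in genes]
    cat = concatenate(alns, order=list(genes))
    table = gene_ani_table(cat, gap_mode=gap_mode)
    table.source = "concatenate:" + "+".join(genes)
    return table


@dataclass(frozen=True)
class GenomeAniResult:
    """Outcome of fragment-based genome ANI; ``ani`` is None when no fragment
    passes the identity/coverage filter (no homology detected — distinct from
    an ANI of zero)."""

    ani: float | None
    aligned_fraction: float
    n_fragments_used: int

    @property
    def no_homology(self) -> bool:
        return self.ani is None


def _revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


def _kmer_index(seq: bytes, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _best_diagonal(frag: bytes, index: Mapping[bytes, list[int]], k: int, stride: int = 4):
    """Most-supported seed diagonal of one fragment, or None without seeds."""
    diag_hits: dict[int, int] = {}
    for q in range(0, len(frag) - k + 1, stride):
        for p in index.get(frag[q : q + k], ()):
            d = p - q
            diag_hits[d] = diag_hits.get(d, 0) + 1
    if not diag_hits:
        return None
    # ties broken toward the smallest diagonal for determinism
    best = max(diag_hits, key=lambda d: (diag_hits[d], -d))
    return best, diag_hits[best]


def _align_fragment(frag: bytes, target: bytes, diag: int, margin: int):
    """Globally align a fragment to a window of the target around a diagonal.

    Returns (identity %, coverage, aligned_columns) or None if the alignment
    engine fails to produce a path.
    """
    lo = max(0, diag - margin)
    hi = min(len(target), diag + len(frag) + margin)
    window = target[lo:hi]
    if len(window) < len(frag) // 2:
        return None
    res = edlib.align(
        frag.decode("ascii"), window.decode("ascii"), mode="HW", task="path"
    )
    cigar = res.get("cigar")
    if not cigar:
        return None
    matches = columns = qlen = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
            qlen += n
        elif op in ("X", "M"):
            qlen += n
        elif op == "I":  # insertion relative to target consumes query
            qlen += n
    if columns == 0:
        return None
    identity = 100.0 * matches / columns
    coverage = qlen / len(frag)
    return identity, coverage, columns


def _one_direction(query: bytes, target: bytes, params: AniParams):
    k = params.seed_k
    index = _kmer_index(target, k)
    rc_query = _revcomp(query) if params.both_strands else None
    weights = 0.0
    weighted_identity = 0.0
    used = 0
    n_frags = len(query) // params.fragment_len
    for f in range(n_frags):
        start = f * params.fragment_len
        frag = query[start : start + params.fragment_len]
        cand = []
        fwd = _best_diagonal(frag, index, k)
        if fwd:
            cand.append((fwd[1], frag, fwd[0]))
        if rc_query is not None:
            rc_start = len(query) - start - params.fragment_len
            rfrag = rc_query[rc_start : rc_start + params.fragment_len]
            rev = _best_diagonal(rfrag, index, k)
            if rev:
                cand.append((rev[1], rfrag, rev[0]))
        if not cand:
            continue
        _, chosen, diag = max(cand, key=lambda c: c[0])
        hit = _align_fragment(chosen, target, diag, params.window_margin)
        if hit is None:
            continue
        identity, coverage, columns = hit
        if identity >= params.min_frag_identity and coverage >= params.min_frag_coverage:
            weighted_identity += identity * columns
            weights += columns
            used += 1
    if used == 0:
        return None, 0.0, 0
    ani = weighted_identity / weights
    # fraction of the fragment-covered query that produced a qualifying hit
    aligned_fraction = used / n_frags
    return ani, aligned_fraction, used


def genome_ani(genome_a: str, genome_b: str, params: AniParams | None = None) -> GenomeAniResult:
    """Fragment-seeded genome ANI, symmetrized over both query/subject roles."""
    params = params or AniParams()
    a = genome_a.upper().encode("ascii")
    b = genome_b.upper().encode("ascii")
    if len(a) < params.fragment_len or len(b) < params.fragment_len:
        raise ValueError("both genomes must be at least one fragment long")
    ab = _one_direction(a, b, params)
    ba = _one_direction(b, a, params)
    parts = [r for r in (ab, ba) if r[0] is not None]
    if not parts:
        return GenomeAniResult(ani=None, aligned_fraction=0.0, n_fragments_used=0)
    ani = float(np.mean([r[0] for r in parts]))
    frac = float(np.mean([r[1] for r in parts]))
    used = sum(r[2] for r in parts)
    return GenomeAniResult(ani=ani, aligned_fraction=frac, n_fragments_used=used)


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -4
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment of two unaligned gene sequences.

    Scoring: match +1, mismatch -1, gap open -4, gap extend -1. Used when gene
    inputs arrive unaligned; pre-aligned rows are consumed as-is.
    """
    aln = next(iter(_get_aligner().align(seq_a.upper(), seq_b.upper())))
    return str(aln[0]), str(aln[1])
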