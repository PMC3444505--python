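from __future__ import annotations

import numpy as np
import pytest

from markerani.ani import PairwiseANITable
from markerani.seqio import GeneAlignment, StrainPanel, StrainRecord


def random_alignment(rng: np.random.Generator, n_rows: int, length: int,
                     gap_frac: float = 0.05, amb_frac: float = 0.02,
                     prefix: str = "s") -> GeneAlignment:
    """A random alignment including gaps and ambiguity codes."""
    alphabet = np.array(list("ACGT"))
    rows = {}
    for i in range(n_rows):
        chars = alphabet[rng.integers(0, 4, size=length)]
        mask = rng.random(length)
        chars[mask < gap_frac] = "-"
        chars[(mask >= gap_frac) & (mask < gap_frac + amb_frac)] = "N"
        rows[f"{prefix}{i}"] = "".join(chars)
    return GeneAlignment("rand", rows)


def table_from_dict(values: dict[tuple[str, str], float], source: str = "genome") -> PairwiseANITable:
    t = PairwiseANITable(source=source)
    for (a, b), v in values.items():
        t.set(a, b, v)
    return t


@pytest.fixture
def two_species_panel() -> StrainPanel:
    """Four strains, two species, one 12-column gene with a clean ANI gap."""
    rows = {
        "a1": "ACGTACGTACGT",
        "a2": "ACGTACGTACGA",  # 1 diff from a1
        "b1": "TGCATGCAACGT",  # far from a*
        "b2": "TGCATGCAACGA",
    }
    return StrainPanel(
        strains=[
            StrainRecord("a1", "Species alpha", True),
            StrainRecord("a2", "Species alpha"),
            StrainRecord("b1", "Species beta", True),
            StrainRecord("b2", "Species beta"),
        ],
        gene_alignments=[GeneAlignment("toy", rows)],
    )
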