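import numpy as np
import pytest

from markerani.ani import gene_ani_table
from markerani.screen import (
    ThresholdConfig,
    boundary_concordance,
    gap_statistic,
    screen_markers,
    species_relation,
)
from markerani.seqio import GeneAlignment, StrainPanel, StrainRecord
from markerani.simulate import SimConfig, expected_ani, simulate_panel

from conftest import table_from_dict

LABELS = {"a1": "alpha", "a2": "alpha", "b1": "beta", "b2": "beta"}


def random_labeled_table(rng, n_strains=8, n_species=3):
    ids = [f"s{i}" for i in range(n_strains)]
    labels = {i: f"sp{rng.integers(0, n_species)}" for i in ids}
    # ensure at least one intra and one inter pair exist
    labels[ids[0]] = labels[ids[1]] = "sp0"
    labels[ids[2]] = "sp_other"
    vals = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            vals[(a, b)] = float(rng.uniform(80, 100))
    return table_from_dict(vals), labels


class TestSpeciesRelation:
    def test_same_label_intra(self):
        assert species_relation(LABELS, "a1", "a2") == "intra"

    def test_different_label_inter(self):
        assert species_relation(LABELS, "a1", "b1") == "inter"

    def test_case_and_whitespace_folded(self):
        labels = {"x": " Alpha ", "y": "alpha"}
        assert species_relation(labels, "x", "y") == "intra"

    def test_missing_label_is_error(self):
        with pytest.raises(KeyError):
            species_relation(LABELS, "a1", "zz")


class TestGapStatistic:
    def test_direct_min_max(self):
        t = table_from_dict({("a1", "a2"): 97.0, ("a1", "b1"): 90.0, ("a2", "b1"): 91.0})
        rep = gap_statistic(t, LABELS)
        assert (rep.min_intra, rep.max_inter, rep.gap) == (97.0, 91.0, 6.0)
        assert rep.violating_pairs == []

    def test_inter_pair_above_ceiling_listed(self):
        t = table_from_dict({("a1", "a2"): 97.0, ("a1", "b1"): 95.5, ("a2", "b1"): 90.0})
        rep = gap_statistic(t, LABELS)
        assert [(v[0], v[1], v[2]) for v in rep.violating_pairs] == [("a1", "b1", 95.5)]

    def test_one_sided_table_is_error(self):
        t = table_from_dict({("a1", "a2"): 97.0})
        with pytest.raises(ValueError, match="inter"):
            gap_statistic(t, LABELS)

    def test_matches_exhaustive_oracle_on_random_panels(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            table, labels = random_labeled_table(rng)
            rep = gap_statistic(table, labels)
            intra = [v for a, b, v in table.pairs() if labels[a] == labels[b]]
            inter = [v for a, b, v in table.pairs() if labels[a] != labels[b]]
            assert rep.min_intra == min(intra)
            assert rep.max_inter == max(inter)
            expected_viol = sum(1 for v in intra if v < 96.0) + sum(
                1 for v in inter if v > 94.0
            )
            assert len(rep.violating_pairs) == expected_viol


class TestBoundaryConcordance:
    def test_perfectly_separated_panel(self):
        gene = table_from_dict({("a1", "a2"): 97.5, ("a1", "b1"): 91.0, ("a2", "b1"): 92.0})
        genome = table_from_dict({("a1", "a2"): 98.0, ("a1", "b1"): 90.0, ("a2", "b1"): 90.5})
        res = boundary_concordance(gene, genome, LABELS)
        assert res == {"concordant": True, "chosen_boundary": 95.0, "mismatches": []}

    def test_inter_pair_above_gene_boundary_mismatch(self):
        gene = table_from_dict({("a1", "a2"): 97.5, ("a1", "b1"): 96.5, ("a2", "b1"): 92.0})
        genome = table_from_dict({("a1", "a2"): 98.0, ("a1", "b1"): 90.0, ("a2", "b1"): 90.5})
        res = boundary_concordance(gene, genome, LABELS)
        assert not res["concordant"]
        assert ("a1", "b1") in {(m[0], m[1]) for m in res["mismatches"]}

    def test_pair_coverage_mismatch_is_error(self):
        gene = table_from_dict({("a1", "a2"): 97.5})
        genome = table_from_dict({("a1", "b1"): 90.0})
        with pytest.raises(ValueError, match="different pairs"):
            boundary_concordance(gene, genome, LABELS)

    def test_matches_exhaustive_boundary_oracle(self):
        """Concordance equals an oracle that tries both candidate boundaries
        over every pair, on random gene/genome table pairs."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            genome, labels = random_labeled_table(rng, n_strains=6)
            gene, _ = random_labeled_table(rng, n_strains=6)
            res = boundary_concordance(gene, genome, labels)
            feasible = []
            for t in (95.0, 96.0):
                ok = all(
                    (gene.get(a, b) >= t) == (genome.get(a, b) >= 95.0)
                    for a, b, _ in gene.pairs()
                )
                if ok:
                    feasible.append(t)
            assert res["concordant"] == bool(feasible)
            if feasible:
                assert res["chosen_boundary"] == min(feasible)

    def test_monotone_under_mismatch_removal(self):
        """Dropping a mismatching pair never turns a concordant gene
        non-concordant (checked by re-running without the offending pair)."""
        rng = np.random.default_rng(5)
        genome, labels = random_labeled_table(rng, n_strains=6)
        gene, _ = random_labeled_table(rng, n_strains=6)
        res = boundary_concordance(gene, genome, labels)
        if res["concordant"]:
            pytest.skip("instance had no mismatch to remove")
        drop = {(m[0], m[1]) for m in res["mismatches"][:1]}
        g2 = table_from_dict(
            {(a, b): v for a, b, v in gene.pairs() if (a, b) not in drop}
        )
        m2 = table_from_dict(
            {(a, b): v for a, b, v in genome.pairs() if (a, b) not in drop}
        )
        res2 = boundary_concordance(g2, m2, labels)
        assert len(res2["mismatches"]) <= len(res["mismatches"])


def truth_genome_table(panel, truth):
    from markerani.ani import PairwiseANITable

    t = PairwiseANITable(source="genome")
    ids = [s.id for s in panel.strains]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            t.set(a, b, expected_ani(truth, a, b, "genome"))
    return t


class TestScreenMarkers:
    def simulated_screen(self, seed=1, **kw):
        cfg = SimConfig(
            seed=seed,
            n_species=3,
            strains_per_species=2,
            n_genes=4,
            inter_divergence=(0.07, 0.18),
            intra_divergence=(0.012, 0.03),
            gene_rate_multipliers=(1.0, 0.15, 6.0, 1.0),
            genome_filler_bp=30_000,
            **kw,
        )
        panel, truth = simulate_panel(cfg)
        return panel, truth_genome_table(panel, truth)

    def test_clocklike_genes_rank_first(self):
        panel, genome = self.simulated_screen()
        reports = screen_markers(panel, genome)
        top2 = {r.gene_name for r in reports[:2]}
        assert top2 == {"gene01", "gene04"}
        assert all(r.concordant for r in reports[:2])
        assert not reports[-1].concordant

    def test_length_breaks_ties(self):
        rows_short = {"a1": "ACGTACGTACGT", "a2": "ACGTACGTACGA",
                      "b1": "TGCATGCATGCA", "b2": "TGCATGCATGCC"}
        rows_long = {k: v * 2 for k, v in rows_short.items()}
        panel = StrainPanel(
            strains=[StrainRecord(i, sp) for i, sp in
                     [("a1", "alpha"), ("a2", "alpha"), ("b1", "beta"), ("b2", "beta")]],
            gene_alignments=[GeneAlignment("long", rows_long),
                             GeneAlignment("short", rows_short)],
        )
        genome = table_from_dict({
            ("a1", "a2"): 98.0, ("b1", "b2"): 98.0,
            ("a1", "b1"): 85.0, ("a1", "b2"): 85.0,
            ("a2", "b1"): 85.0, ("a2", "b2"): 85.0,
        })
        reports = screen_markers(panel, genome)
        assert [r.gene_name for r in reports] == ["short", "long"]

    def test_gene_order_permutation_invariant(self):
        panel, genome = self.simulated_screen(seed=3)
        fwd = screen_markers(panel, genome)
        panel.gene_alignments = list(reversed(panel.gene_alignments))
        rev = screen_markers(panel, genome)
        assert [r.gene_name for r in fwd] == [r.gene_name for r in rev]

    def test_failing_gene_reported_not_dropped(self):
        panel, genome = self.simulated_screen(seed=4)
        # a gene whose rows are all gaps for one pair cannot be screened
        bad = GeneAlignment(
            "bad",
            {s.id: ("-" * 20 if s.id.startswith("sp01") else "A" * 20)
             for s in panel.strains},
        )
        panel.gene_alignments.append(bad)
        reports = screen_markers(panel, genome)
        byname = {r.gene_name: r for r in reports}
        assert byname["bad"].failure is not None
        assert byname["bad"].rank == len(reports)


class TestThresholdConfig:
    def test_rejects_inverted_boundaries(self):
        with pytest.raises(ValueError):
            ThresholdConfig(intra_floor=94.0, inter_ceiling=96.0)
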