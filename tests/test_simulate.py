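"""Synthetic family generator: planted structure, mutation model, determinism."""

import numpy as np
import pytest

from viropan import FamilySpec, generate_family, mutate_sequence, plant_occupancy
from viropan.io import write_proteomes
from viropan.simulate import ORPHAN, planted_compartments, random_protein


class TestFamilySpec:
    def test_rejects_fewer_than_three_genomes(self):
        with pytest.raises(ValueError, match="3 genomes"):
            FamilySpec(n_genomes=2, n_core=1, n_shell=0, n_cloud=0)

    @pytest.mark.parametrize("field,value", [
        ("divergence", 0.8), ("divergence", -0.1), ("paralog_rate", 1.5),
    ])
    def test_rejects_out_of_range_rates(self, field, value):
        with pytest.raises(ValueError):
            FamilySpec(n_genomes=4, n_core=1, n_shell=0, n_cloud=0, **{field: value})


class TestPlantOccupancy:
    def test_three_genome_family_has_no_shell_interval(self):
        spec = FamilySpec(n_genomes=3, n_core=1, n_shell=1, n_cloud=1)
        with pytest.raises(ValueError, match=r"shell occupancy interval .* empty"):
            plant_occupancy(spec)

    def test_core_occupancy_meets_95_percent_threshold(self):
        spec = FamilySpec(n_genomes=20, n_core=5, n_shell=0, n_cloud=0, seed=1)
        occ = plant_occupancy(spec)
        assert all(len(g) >= 19 for g in occ.values())  # ceil(0.95*20)

    def test_cloud_occupancy_is_one_or_two_and_seed_reproducible(self):
        spec = FamilySpec(n_genomes=10, n_core=0, n_shell=0, n_cloud=5, seed=11)
        occ = plant_occupancy(spec)
        assert len(occ) == 5
        assert all(len(g) in (1, 2) for g in occ.values())
        assert plant_occupancy(spec) == occ

    def test_shell_occupancy_between_three_and_core_threshold(self):
        spec = FamilySpec(n_genomes=12, n_core=0, n_shell=20, n_cloud=0, seed=2)
        core_min = spec.core_min_occupancy
        occ = plant_occupancy(spec)
        assert all(3 <= len(g) <= core_min - 1 for g in occ.values())


class TestMutateSequence:
    def test_zero_divergence_is_identity(self):
        seq = random_protein(120, np.random.default_rng(0))
        assert mutate_sequence(seq, 0.0, 0.0, seed=5) == seq

    def test_same_seed_same_output(self):
        seq = random_protein(200, np.random.default_rng(1))
        out = mutate_sequence(seq, 0.3, 0.02, seed=42)
        assert mutate_sequence(seq, 0.3, 0.02, seed=42) == out

    def test_substituted_fraction_matches_binomial_expectation(self):
        # 100 replicates at length 1000: mean substituted fraction ~ Binomial(0.2)
        seq = random_protein(1000, np.random.default_rng(2))
        fractions = [
            sum(a != b for a, b in zip(seq, mutate_sequence(seq, 0.2, 0.0, seed=s)))
            / len(seq)
            for s in range(100)
        ]
        assert abs(np.mean(fractions) - 0.2) < 0.02

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="divergence"):
            mutate_sequence("ACDEF", 1.2)

    def test_empty_ancestor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mutate_sequence("", 0.1)

    def test_indels_alter_the_sequence(self):
        seq = random_protein(500, np.random.default_rng(3))
        out = mutate_sequence(seq, 0.0, 0.2, seed=9)
        assert out != seq
        # with ~50 deletions and ~50 insertions expected, a run of several
        # seeds must produce at least one length change
        lengths = {len(mutate_sequence(seq, 0.0, 0.2, seed=s)) for s in range(5)}
        assert lengths != {500}


class TestGenerateFamily:
    def test_protein_counts_match_planted_occupancy(self):
        spec = FamilySpec(n_genomes=4, n_core=2, n_shell=0, n_cloud=1, seed=3)
        occ = plant_occupancy(spec)
        proteomes, truth = generate_family(spec)
        expected = sum(len(g) for g in occ.values())
        assert len(truth) == expected
        assert sum(len(p) for p in proteomes.values()) == expected
        by_cluster = truth.groupby("cluster_id")["genome_id"].apply(
            lambda g: tuple(sorted(g))
        )
        assert dict(by_cluster) == occ

    def test_every_incidence_doubled_at_paralog_rate_one(self):
        spec = FamilySpec(n_genomes=4, n_core=3, n_shell=0, n_cloud=0,
                          paralog_rate=1.0, seed=4)
        _, truth = generate_family(spec)
        per = truth.groupby(["cluster_id", "genome_id"]).size()
        assert (per == 2).all()
        assert truth["is_paralog"].sum() == len(truth) / 2

    def test_orphans_are_labelled_and_counted(self):
        spec = FamilySpec(n_genomes=3, n_core=1, n_shell=0, n_cloud=0,
                          orphan_per_genome=2, seed=5)
        _, truth = generate_family(spec)
        assert (truth["cluster_id"] == ORPHAN).sum() == 6

    def test_fasta_output_is_byte_identical_for_same_seed(self, tmp_path):
        spec = FamilySpec(n_genomes=3, n_core=2, n_shell=0, n_cloud=1,
                          paralog_rate=0.5, orphan_per_genome=1, seed=6)
        for sub in ("a", "b"):
            proteomes, _ = generate_family(spec)
            write_proteomes(proteomes, tmp_path / sub)
        for fa in (tmp_path / "a").iterdir():
            assert fa.read_bytes() == (tmp_path / "b" / fa.name).read_bytes()

    def test_planted_compartments_reflect_spec_counts(self):
        spec = FamilySpec(n_genomes=10, n_core=4, n_shell=3, n_cloud=5,
                          orphan_per_genome=1, seed=8)
        _, truth = generate_family(spec)
        comp = planted_compartments(truth)
        assert comp["core"] == 4
        assert comp["shell"] == 3
        assert comp["cloud"] == 5 + 10  # occupancy-1/2 clusters plus orphan singletons
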