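"""The planted-architecture genome generator and its companion-isolate mutator."""

import pytest

from oracles import bruteforce_orfs
from totiscan.genome_model import GenomeRecord
from totiscan.orf_annotation import derive_architecture, find_orfs
from totiscan.prf_scanner import detect_prf
from totiscan.synthetic_data import (
    ArchitectureError,
    GenomeArchitecture,
    PseudoknotSpec,
    architecture_from_yaml,
    generate_genome,
    generate_isolate_pair,
    generate_mutant,
    tktv1_architecture,
)


def test_generation_is_deterministic(tktv1_arch):
    a = generate_genome(tktv1_arch, seed=9)
    b = generate_genome(tktv1_arch, seed=9)
    assert a.sequence == b.sequence
    c = generate_genome(tktv1_arch, seed=10)
    assert c.sequence != a.sequence


def test_fixture_has_planted_elements_verbatim(fixture_genome, tktv1_arch):
    g = fixture_genome
    assert g.length == 4712
    assert g.slice(98, 100) == "AUG" and g.slice(2159, 2161) == "UAA"
    assert g.slice(2410, 2412) == "AUG" and g.slice(4651, 4653) == "UAA"
    assert g.slice(2104, 2110) == "UGUUUUC"
    assert g.slice(1987, 1989) == "UAA"  # 5' boundary of the stop-free -1 frame


def test_no_unplanted_orf_at_min_length(tktv1_arch):
    for seed in range(3):
        genome = generate_genome(tktv1_arch, seed=seed)
        assert bruteforce_orfs(genome.sequence, 300) == [(98, 2161), (2410, 4653)]


def test_packaged_yaml_matches_builtin_architecture(tktv1_arch):
    assert architecture_from_yaml(seed=1) == tktv1_arch


def test_architecture_validation_errors():
    with pytest.raises(ArchitectureError, match="divisible"):
        GenomeArchitecture(
            name="bad",
            total_length=1000,
            orfs=((10, 100),),  # 91 nt
            slippery_start=40,
            slippery_heptamer="UGUUUUC",
            pseudoknot=PseudoknotSpec(start=60, stem1=3, stem2=3, loops=(1, 1, 1)),
            minus_one_stop_free_from=36,
        )
    with pytest.raises(ArchitectureError, match="not a relaxed slippery"):
        GenomeArchitecture(
            name="bad",
            total_length=1000,
            orfs=((10, 99),),
            slippery_start=40,
            slippery_heptamer="GGGCCCA",
            pseudoknot=PseudoknotSpec(start=60, stem1=3, stem2=3, loops=(1, 1, 1)),
            minus_one_stop_free_from=36,
        )
    with pytest.raises(ArchitectureError, match="spacer"):
        GenomeArchitecture(
            name="bad",
            total_length=1000,
            orfs=((10, 99),),
            slippery_start=40,
            slippery_heptamer="UGUUUUC",
            pseudoknot=PseudoknotSpec(start=90, stem1=3, stem2=3, loops=(1, 1, 1)),
            minus_one_stop_free_from=36,
        )


def test_full_pipeline_recovery_across_seeds():
    """Annotating freshly generated genomes reproduces every printed length."""
    for seed in range(20, 40):
        arch = tktv1_architecture(seed=seed)
        genome = generate_genome(arch)
        orfs = find_orfs(genome)
        assert [(o.region.start, o.region.end) for o in orfs] == [(98, 2161), (2410, 4653)]
        annotation = derive_architecture(genome, orfs)
        assert annotation.five_prime_utr.length == 97
        assert [r.length for r in annotation.intergenic] == [248]
        assert annotation.three_prime_utr.length == 59
        assert [o.protein_length for o in orfs] == [687, 747]
        signal = detect_prf(genome, orfs[0])
        assert signal.spacer.length == 19
        assert signal.fusion.protein_length == 1518
        assert signal.fusion.overlap_nt == 172


def test_mutant_changes_exactly_the_specified_positions(fixture_pair, tktv1_arch):
    genome, mutant = fixture_pair
    changed = [i + 1 for i, (a, b) in enumerate(zip(genome.sequence, mutant.sequence)) if a != b]
    assert changed == sorted(p for p, _ in tktv1_arch.mutations)
    assert mutant.length == genome.length


def test_mutant_empty_spec_is_identical(fixture_genome):
    clone = generate_mutant(fixture_genome, (), seed=5)
    assert clone.sequence == fixture_genome.sequence


def test_mutant_is_deterministic(fixture_genome, tktv1_arch):
    m1 = generate_mutant(fixture_genome, tktv1_arch.mutations, seed=2)
    m2 = generate_mutant(fixture_genome, tktv1_arch.mutations, seed=2)
    assert m1.sequence == m2.sequence


def test_silent_mutation_at_met_codon_errors(fixture_genome):
    # ORF1 initiator AUG admits no synonymous change at any codon position
    with pytest.raises(ValueError, match="no synonymous"):
        generate_mutant(fixture_genome, ((98, "silent"),), seed=1)


def test_utr_class_rejected_inside_orf(fixture_genome):
    with pytest.raises(ValueError, match="coding position"):
        generate_mutant(fixture_genome, ((1000, "utr"),), seed=1)


def test_isolate_pair_round_trip(tktv1_arch):
    genome, mutant = generate_isolate_pair(tktv1_arch)
    assert genome.id != mutant.id
    assert sum(a != b for a, b in zip(genome.sequence, mutant.sequence)) == 5
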