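import math

import pytest

from strainsnp import filter_bases, read_fasta, read_pileup
from strainsnp.simulate import (
    FixedState,
    PolymorphicState,
    SimulationConfig,
    generate_contigs,
    implant_truth,
    read_truth_table,
    run_simulation,
    simulate_pileups,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_contigs": 0},
            {"contig_length_range": (10, 50)},
            {"contig_length_range": (100, 50)},
            {"poly_rate": 1.5},
            {"poly_rate": 0.7, "fixed_diff_rate": 0.7},
            {"base_error_rate": 1.0},
            {"mean_depth": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenerateContigs:
    def test_counts_and_orf_validity(self):
        cfg = SimulationConfig(n_contigs=3, contig_length_range=(100, 200),
                               orf_fraction=1.0, seed=7)
        contigs = generate_contigs(cfg)
        assert len(contigs) == 3
        for c in contigs:
            assert 100 <= len(c.sequence) <= 200
            assert c.has_orf
            cds = c.sequence[c.cds_start - 1 : c.cds_end]
            if c.strand == "-":
                cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(cds) % 3 == 0
            # nonempty UTR flanks
            assert c.cds_start >= 2 and c.cds_end <= len(c.sequence) - 1
            # internal codons are sense codons (honest reading frame)
            for i in range(3, len(cds) - 3, 3):
                assert cds[i : i + 3] not in ("TAA", "TAG", "TGA")

    def test_orf_fraction_zero(self):
        cfg = SimulationConfig(n_contigs=5, orf_fraction=0.0, seed=1)
        assert not any(c.has_orf for c in generate_contigs(cfg))

    def test_range_too_short_for_orf_rejected(self):
        # min length 30 satisfies the range invariant but fraction 0 is fine
        cfg = SimulationConfig(n_contigs=2, contig_length_range=(30, 30),
                               orf_fraction=1.0, seed=0)
        contigs = generate_contigs(cfg)  # 30 bases can host ATG+codon+stop+UTRs
        assert all(c.has_orf for c in contigs)

    def test_determinism_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_contigs=4, poly_rate=0.01, fixed_diff_rate=0.005,
                               mean_depth=15, seed=99)
        r1 = run_simulation(cfg, tmp_path / "a")
        r2 = run_simulation(cfg, tmp_path / "b")
        for key in ("reference", "orf_table", "truth_table"):
            assert r1[key].read_bytes() == r2[key].read_bytes()
        for strain in cfg.strains:
            assert r1["pileups"][strain].read_bytes() == r2["pileups"][strain].read_bytes()


class TestImplantTruth:
    def test_zero_rates_empty_truth(self):
        cfg = SimulationConfig(n_contigs=3, poly_rate=0.0, fixed_diff_rate=0.0, seed=5)
        contigs = generate_contigs(cfg)
        assert implant_truth(contigs, cfg) == []

    def test_rate_one_forces_all_sites_polymorphic(self):
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(30, 30), n_strains=1,
                               orf_fraction=0.0, poly_rate=1.0, fixed_diff_rate=0.0, seed=3)
        contigs = generate_contigs(cfg)
        truth = implant_truth(contigs, cfg)
        assert len(truth) == 30
        assert all(t.kind == "polymorphic" for t in truth)
        for t in truth:
            state = t.per_strain_state["strain1"]
            assert isinstance(state, PolymorphicState)
            assert state.allele_a == t.reference_allele != state.allele_b
            assert 0.1 <= state.freq_b <= 0.5

    def test_fixed_difference_structure_four_strains(self):
        """Every fixed-difference site: exactly one strain fixed non-reference."""
        cfg = SimulationConfig(n_contigs=5, n_strains=4, poly_rate=0.0,
                               fixed_diff_rate=0.05, orf_fraction=0.0, seed=21)
        contigs = generate_contigs(cfg)
        truth = implant_truth(contigs, cfg)
        assert truth  # rate 0.05 over ~2000 bases
        for t in truth:
            states = t.per_strain_state
            assert set(states) == set(cfg.strains)
            nonref = [s for s, st in states.items()
                      if isinstance(st, FixedState) and st.allele != t.reference_allele]
            ref = [s for s, st in states.items()
                   if isinstance(st, FixedState) and st.allele == t.reference_allele]
            assert len(nonref) == 1
            assert len(ref) == len(cfg.strains) - 1


class TestSimulatePileups:
    def test_zero_error_reference_site_all_match_symbols(self, tmp_path):
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(30, 30), n_strains=1,
                               orf_fraction=0.0, poly_rate=0.0, fixed_diff_rate=0.0,
                               mean_depth=20, base_error_rate=0.0, seed=8)
        contigs = generate_contigs(cfg)
        paths = simulate_pileups(contigs, [], cfg, tmp_path)
        for site in read_pileup(paths["strain1"]):
            assert set(site.read_bases) == {site.reference_base}
            assert site.depth == len(site.read_bases)

    def test_zero_error_fixed_site_reads_equal_fixed_allele(self, tmp_path):
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(40, 40), n_strains=2,
                               orf_fraction=0.0, poly_rate=0.0, fixed_diff_rate=0.3,
                               mean_depth=50, base_error_rate=0.0, seed=12)
        contigs = generate_contigs(cfg)
        truth = implant_truth(contigs, cfg)
        assert truth
        paths = simulate_pileups(contigs, truth, cfg, tmp_path)
        by_site = {(t.contig_id, t.position): t for t in truth}
        for strain in cfg.strains:
            for site in read_pileup(paths[strain]):
                t = by_site.get((site.contig_id, site.position))
                if t is None:
                    continue
                allele = t.per_strain_state[strain].allele
                assert set(site.read_bases) == {allele}

    def test_polymorphic_frequency_within_binomial_bound(self, tmp_path):
        """Observed alternate fraction within 3 binomial SEs of the truth."""
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(30, 30), n_strains=1,
                               orf_fraction=0.0, poly_rate=0.0, fixed_diff_rate=0.0,
                               mean_depth=1000, base_error_rate=0.0, seed=17)
        contigs = generate_contigs(cfg)
        from strainsnp.simulate import TruthVariant

        truth = [TruthVariant(contigs[0].contig_id, 5, contigs[0].sequence[4],
                              {"strain1": PolymorphicState(
                                  contigs[0].sequence[4],
                                  "A" if contigs[0].sequence[4] != "A" else "C",
                                  0.5)})]
        paths = simulate_pileups(contigs, truth, cfg, tmp_path)
        site = next(s for s in read_pileup(paths["strain1"]) if s.position == 5)
        alt = truth[0].per_strain_state["strain1"].allele_b
        frac = site.read_bases.count(alt) / len(site.read_bases)
        se = math.sqrt(0.25 / len(site.read_bases))
        assert abs(frac - 0.5) <= 3 * se

    def test_total_depth_within_poisson_bound(self, tmp_path):
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(100, 100), n_strains=1,
                               orf_fraction=0.0, poly_rate=0.0, fixed_diff_rate=0.0,
                               mean_depth=30, base_error_rate=0.0, seed=23)
        contigs = generate_contigs(cfg)
        paths = simulate_pileups(contigs, [], cfg, tmp_path)
        total = sum(s.depth for s in read_pileup(paths["strain1"]))
        assert abs(total - 3000) <= 3 * math.sqrt(3000)

    def test_allele_counts_converge_to_truth_at_high_depth(self, tmp_path):
        """Aggregated pileup frequencies approach truth within 2% at depth 1e4."""
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(30, 30), n_strains=1,
                               orf_fraction=0.0, poly_rate=0.0, fixed_diff_rate=0.0,
                               mean_depth=10_000, base_error_rate=0.0, seed=29)
        contigs = generate_contigs(cfg)
        from strainsnp.simulate import TruthVariant

        ref = contigs[0].sequence[9]
        alt = "G" if ref != "G" else "T"
        truth = [TruthVariant(contigs[0].contig_id, 10, ref,
                              {"strain1": PolymorphicState(ref, alt, 0.3)})]
        paths = simulate_pileups(contigs, truth, cfg, tmp_path)
        site = next(s for s in read_pileup(paths["strain1"]) if s.position == 10)
        counts = filter_bases(site, min_base_quality=0)
        frac = counts.as_dict()[alt] / counts.filtered_depth
        assert abs(frac - 0.3) <= 0.02


class TestArtefacts:
    def test_truth_table_round_trip(self, small_sim):
        back = read_truth_table(small_sim["truth_table"])
        orig = {(t.contig_id, t.position): t for t in small_sim["truth"]}
        assert len(back) == len(orig)
        for t in back:
            o = orig[(t.contig_id, t.position)]
            assert t.reference_allele == o.reference_allele
            for strain, state in t.per_strain_state.items():
                ostate = o.per_strain_state[strain]
                if isinstance(state, PolymorphicState):
                    assert isinstance(ostate, PolymorphicState)
                    assert state.freq_b == pytest.approx(ostate.freq_b)
                else:
                    assert state.allele == ostate.allele

    def test_reference_fasta_matches_contigs(self, small_sim):
        back = read_fasta(small_sim["reference"])
        assert [(c.contig_id, c.sequence) for c in back] == [
            (c.contig_id, c.sequence) for c in small_sim["contigs"]
        ]
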