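import numpy as np
import pytest
from scipy.stats import chisquare

from phylodissect.simulate import (SimulationSpec, apply_missing_mask,
                                   build_tree, flatworm_like, lba_demo,
                                   simulate_dollo_characters,
                                   simulate_supermatrix)
from phylodissect.substitution import poisson_model, transition_probabilities
from phylodissect.supermatrix import completeness_stats
from phylodissect.tree import PhyloTree, nontrivial_splits


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_taxa=3),
        dict(long_branch_scale=0.5),
        dict(target_completeness=0.0),
        dict(target_completeness=1.5),
        dict(gene_rate_shape=-1.0),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationSpec(**kw)


class TestBuildTree:
    def test_scale_one_is_identity(self):
        base = build_tree(SimulationSpec(n_taxa=8, seed=5))
        scaled = build_tree(SimulationSpec(n_taxa=8, seed=5,
                                           long_branch_taxa=("t01", "t05"),
                                           long_branch_scale=1.0))
        assert base.to_newick() == scaled.to_newick()

    def test_long_branch_taxa_scaled_on_terminals(self):
        a = build_tree(SimulationSpec(n_taxa=8, seed=5))
        b = build_tree(SimulationSpec(n_taxa=8, seed=5,
                                      long_branch_taxa=("t03",),
                                      long_branch_scale=10.0))
        assert b.leaf("t03").length == pytest.approx(10 * a.leaf("t03").length)
        assert b.leaf("t04").length == pytest.approx(a.leaf("t04").length)

    def test_felsenstein_zone_quartet_construction(self):
        spec = lba_demo(0)
        tree = build_tree(spec)
        # two long terminals that are not sisters
        assert tree.leaf("A").length == pytest.approx(0.16 * 5)
        assert tree.leaf("B").length == pytest.approx(0.16 * 5)
        assert nontrivial_splits(tree) == {frozenset({"B", "D"})}

    def test_explicit_newick_round_trips(self):
        nwk = "((A:0.1,B:0.2):0.05,C:0.3,D:0.4);"
        spec = SimulationSpec(n_taxa=4, topology_mode=nwk)
        tree = build_tree(spec)
        back = PhyloTree.from_newick(tree.to_newick())
        assert nontrivial_splits(back) == nontrivial_splits(
            PhyloTree.from_newick(nwk))
        for leaf in back.leaves():
            want = PhyloTree.from_newick(nwk).leaf(leaf.name).length
            assert leaf.length == pytest.approx(want, abs=1e-10)

    def test_unknown_long_branch_taxon_rejected(self):
        with pytest.raises(ValueError, match="long_branch_taxa"):
            build_tree(SimulationSpec(n_taxa=6, long_branch_taxa=("nope",)))


class TestSimulateSupermatrix:
    def test_zero_branch_lengths_copy_root_states(self):
        nwk = "((A:0,B:0):0,C:0,D:0);"
        spec = SimulationSpec(n_taxa=4, topology_mode=nwk, n_genes=3,
                              gene_length_mean=50, target_completeness=1.0,
                              seed=1)
        mat, truth = simulate_supermatrix(spec)
        for t in mat.taxa[1:]:
            assert mat.row_string(t) == mat.row_string(mat.taxa[0])

    def test_seeded_determinism(self):
        spec = SimulationSpec(n_taxa=6, n_genes=5, gene_length_mean=60,
                              target_completeness=0.8, seed=9)
        m1, t1 = simulate_supermatrix(spec)
        m2, t2 = simulate_supermatrix(spec)
        assert m1 == m2
        assert np.array_equal(t1.site_profile_assignments,
                              t2.site_profile_assignments)
        assert np.array_equal(t1.missing_mask, t2.missing_mask)
        assert t1.true_tree.to_newick() == t2.true_tree.to_newick()

    def test_single_branch_frequencies_match_transition_oracle(self):
        # one branch of length t, K=1 profile, no rate variation:
        # (root, child) state pairs follow pi_i * P_ij(t)
        t_len = 0.7
        nwk = f"((A:{t_len},B:0.0):0.0,C:0.0,D:0.0);"
        spec = SimulationSpec(n_taxa=4, topology_mode=nwk, n_genes=1,
                              gene_length_mean=50000, gene_length_dispersion=1e-9,
                              gene_rate_shape=1e9, alpha=1e9, n_categories=1,
                              n_profiles=1, profile_concentration=1e9,
                              target_completeness=1.0, seed=4)
        model = poisson_model(alpha=1e9, n_categories=1)
        mat, truth = simulate_supermatrix(spec, model)
        # B carries the root states (zero-length branch), A the evolved ones
        root_states = mat.row("B")
        child_states = mat.row("A")
        q = model.rate_matrix()
        p = transition_probabilities(q, model.frequencies, t_len)
        joint = np.outer(model.frequencies, np.ones(20)) * p
        counts = np.zeros((20, 20))
        np.add.at(counts, (root_states, child_states), 1)
        stat = chisquare(counts.ravel(), joint.ravel() * counts.sum())
        assert stat.pvalue > 0.001

    def test_gene_rate_doubling_doubles_divergence(self):
        # same single branch, one gene at rate r vs one at 2r: observed
        # difference fractions must match the transition-matrix curve
        nwk = "((A:0.05,B:0.0):0.0,C:0.0,D:0.0);"
        base = SimulationSpec(n_taxa=4, topology_mode=nwk, n_genes=2,
                              gene_length_mean=20000, gene_length_dispersion=1e-9,
                              alpha=1e9, n_categories=1, n_profiles=1,
                              profile_concentration=1e9,
                              target_completeness=1.0, seed=6)
        model = poisson_model(alpha=1e9, n_categories=1)
        mat, truth = simulate_supermatrix(base, model)
        rates = [truth.gene_rates[p.gene_id] for p in mat.partitions]
        diffs = []
        for p in mat.partitions:
            a = mat.data[0, p.start:p.end]
            b = mat.data[1, p.start:p.end]
            diffs.append(float((a != b).mean()))
        for rate, diff, n in zip(rates, diffs,
                                 [p.length for p in mat.partitions]):
            t = 0.05 * rate
            expected = (19 / 20) * (1 - np.exp(-t * 20 / 19))
            sigma = np.sqrt(expected * (1 - expected) / n)
            assert abs(diff - expected) < 3 * sigma


class TestMissingMask:
    def test_target_one_is_identity(self):
        spec = SimulationSpec(n_taxa=5, n_genes=4, gene_length_mean=40,
                              target_completeness=1.0, seed=2)
        mat, _ = simulate_supermatrix(spec)
        out, mask = apply_missing_mask(mat, 1.0, None, seed=3)
        assert out == mat and not mask.any()

    def test_target_zero_rejected(self):
        spec = SimulationSpec(n_taxa=5, n_genes=4, gene_length_mean=40,
                              target_completeness=1.0, seed=2)
        mat, _ = simulate_supermatrix(spec)
        with pytest.raises(ValueError):
            apply_missing_mask(mat, 0.0, None, seed=3)

    def test_realized_completeness_within_binomial_band(self):
        spec = SimulationSpec(n_taxa=20, n_genes=200, gene_length_mean=40,
                              gene_length_dispersion=1e-9,
                              target_completeness=1.0, seed=8)
        mat, _ = simulate_supermatrix(spec)
        out, mask = apply_missing_mask(mat, 0.72, None, seed=8)
        realized = completeness_stats(out).overall / 100
        # 20 x 200 gene blocks: binomial(4000, 0.72) tail bound
        sigma = np.sqrt(0.72 * 0.28 / 4000)
        assert 0.69 <= realized <= 0.75
        assert abs(realized - 0.72) < 4 * sigma

    def test_mask_conservation_is_exact(self):
        spec = SimulationSpec(n_taxa=8, n_genes=30, gene_length_mean=50,
                              target_completeness=1.0, seed=12)
        mat, _ = simulate_supermatrix(spec)
        out, mask = apply_missing_mask(mat, 0.6, 50.0, seed=12)
        lengths = np.array([p.length for p in mat.partitions])
        masked_cells = (mask * lengths[None, :]).sum()
        present_before = (~mat.missing_mask()).sum()
        present_after = (~out.missing_mask()).sum()
        assert present_before - present_after == masked_cells


class TestDolloCharacters:
    def tree(self):
        return PhyloTree.from_newick(
            "(((A:1,B:1)ab:1,(C:1,D:1)cd:1)abcd:1,(E:1,(F:1,G:1)fg:1)efg:1)r;")

    def test_no_losses_no_noise_all_present(self):
        pam = simulate_dollo_characters(self.tree(), ["m1", "m2"], {},
                                        fn_rate=0.0, seed=1)
        assert pam.detected.all()

    def test_clade_stem_loss_hits_exactly_that_clade(self):
        pam = simulate_dollo_characters(self.tree(), ["m"], {"m": ["abcd"]},
                                        fn_rate=0.0, seed=1)
        lost = {t for t in pam.taxa if pam.state(t, "m") == "undetected"}
        assert lost == {"A", "B", "C", "D"}

    def test_false_negative_rate_within_binomial_band(self):
        markers = [f"m{i}" for i in range(1000)]
        pam = simulate_dollo_characters(self.tree(), markers, {},
                                        fn_rate=0.1, seed=3)
        frac = 1.0 - pam.detected.mean()
        n = pam.detected.size
        sigma = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 3 * sigma

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_dollo_characters(self.tree(), ["m"], {"m": ["zz"]},
                                      fn_rate=0.0, seed=1)


class TestPresets:
    def test_flatworm_preset_shape(self):
        spec = flatworm_like(3)
        assert spec.n_taxa == 24 and spec.n_genes == 400
        assert spec.target_completeness == pytest.approx(0.72)
        assert len(spec.long_branch_taxa) == 4

    def test_lba_preset_is_felsenstein_zone(self):
        spec = lba_demo(0)
        tree = build_tree(spec)
        long = {t for t in ("A", "B")}
        sisters = nontrivial_splits(tree)
        assert sisters == {frozenset({"B", "D"})}  # A with C; long A,B apart
        assert all(tree.leaf(t).length > 4 * tree.leaf("C").length
                   for t in long)
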