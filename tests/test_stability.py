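from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.ct_data import ArityError
from refstab.stability import (
    ALGORITHMS,
    bestkeeper,
    delta_ct_stability,
    genorm_m,
    genorm_rank,
    normfinder_stability,
    stability_table,
)
from refstab.synth import SynthConfig, GeneSpec, generate, spiked_instability

from conftest import make_matrix
from oracles import BRUTE, brute_genorm_exclusion

# Frozen from the brute-force oracle on the worked 3x4 matrix
# A:(10,10,10,10), B:(11,12,11,12), C:(15,14,15,16); pairwise SDs are
# sqrt(1/3), sqrt(2/3) and 1.
WORKED_M = {"A": 0.6969234250586759, "B": 0.7886751345948129, "C": 0.9082482904638630}


def random_matrix(rng, n_genes=None, n_samples=None):
    n_genes = n_genes or int(rng.integers(4, 7))
    n_samples = n_samples or int(rng.integers(4, 13))
    return make_matrix(rng.uniform(8, 30, size=(n_genes, n_samples)))


class TestGenormM:
    def test_perfectly_covarying_pair_has_zero_m(self):
        m = make_matrix([[10, 11, 12, 13], [13, 14, 15, 16]])
        assert genorm_m(m).to_numpy() == pytest.approx([0.0, 0.0])

    def test_sample_shift_cancels(self, worked_matrix):
        base = genorm_m(worked_matrix)
        ct = worked_matrix.ct.copy()
        ct[:, 2] += 3.5  # same shift for every gene of one sample
        shifted = genorm_m(make_matrix(ct, genes=worked_matrix.genes))
        np.testing.assert_allclose(shifted.to_numpy(), base.to_numpy())

    def test_worked_matrix_matches_oracle(self, worked_matrix):
        m = genorm_m(worked_matrix)
        for g, expect in WORKED_M.items():
            assert m[g] == pytest.approx(expect, abs=1e-12)

    def test_single_gene_is_arity_error(self):
        with pytest.raises(ArityError):
            genorm_m(make_matrix([[10, 11, 12]]))


class TestGenormRank:
    def test_three_genes_give_tied_pair_and_rank3(self, worked_matrix):
        t = genorm_rank(worked_matrix)
        assert sorted(t.ranks) == [1, 1, 3]

    def test_exclusion_order_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_matrix(rng)
            t = genorm_rank(m)
            order, pair = brute_genorm_exclusion(m)
            assert t.extras["exclusion_order"] == order
            assert set(t.extras["tied_best_pair"]) == set(pair)

    def test_reported_value_is_m_at_exclusion_round(self, worked_matrix):
        t = genorm_rank(worked_matrix)
        # worst gene's value is its M in the full 3-gene round
        worst = t.extras["exclusion_order"][0]
        assert t.value(worst) == pytest.approx(WORKED_M[worst])
        # the tied pair share the two-gene-round M
        a, b = t.extras["tied_best_pair"]
        assert t.value(a) == pytest.approx(t.value(b))

    def test_noisy_gene_excluded_first(self):
        """A gene with 5x noise is excluded first in >=95% of replicates."""
        hkgs = tuple(GeneSpec(f"G{i}", 15.0, 0.3) for i in range(5))
        base = SynthConfig(hkgs=hkgs, targets=(), conditions=("A", "B", "C"))
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = spiked_instability(replace(base, seed=seed), "G2", 5.0)
            t = genorm_rank(generate(cfg))
            hits += t.extras["exclusion_order"][0] == "G2"
        assert hits >= 0.95 * n_rep


class TestNormFinder:
    def test_exact_additive_data_has_zero_stability(self):
        beta = np.array([0.0, 1.0, -2.0, 0.5])
        ct = np.vstack([10 + beta, 12 + beta, 20 + beta])
        t = normfinder_stability(make_matrix(ct))
        np.testing.assert_allclose(t.values, 0.0, atol=1e-12)

    def test_sample_permutation_invariance(self, worked_matrix):
        base = normfinder_stability(worked_matrix)
        perm = [3, 1, 0, 2]
        shuffled = make_matrix(
            worked_matrix.ct[:, perm], genes=worked_matrix.genes
        )
        np.testing.assert_allclose(
            normfinder_stability(shuffled).values, base.values
        )

    def test_recovers_generative_sigma(self):
        """Mean estimate over replicates within 10% of the true noise SD."""
        sigmas = [0.1, 0.1, 0.1, 0.1, 0.5]
        hkgs = tuple(GeneSpec(f"G{i}", 15.0, s) for i, s in enumerate(sigmas))
        est = np.zeros(5)
        n_rep = 100
        for seed in range(n_rep):
            cfg = SynthConfig(
                hkgs=hkgs, targets=(), conditions=("A",), n_donors=100,
                donor_sd=0.5, seed=seed,
            )
            est += normfinder_stability(generate(cfg)).values
        est /= n_rep
        np.testing.assert_allclose(est, sigmas, rtol=0.10)

    def test_grouped_mode_flags_intergroup_shifter(self):
        """A gene shifting between conditions scores worst in grouped mode."""
        rng = np.random.default_rng(5)
        conds = ["A"] * 6 + ["B"] * 6
        ct = 15 + rng.normal(0, 0.1, size=(4, 12))
        ct[0, 6:] += 2.0  # gene 1 jumps between groups
        m = make_matrix(ct, conditions=conds)
        t = normfinder_stability(m, groups=["A", "B"])
        assert np.argmax(t.values) == 0

    def test_grouped_degenerate_group_errors(self):
        m = make_matrix(np.full((3, 3), 15.0), conditions=["A", "A", "B"])
        with pytest.raises(ArityError, match="group"):
            normfinder_stability(m, groups=["A", "B"])

    def test_two_genes_is_arity_error(self):
        with pytest.raises(ArityError):
            normfinder_stability(make_matrix([[10, 11], [12, 13]]))


class TestBestKeeper:
    def test_constant_gene_best_with_warning(self):
        m = make_matrix([[20, 20, 20], [10, 12, 14]])
        with pytest.warns(UserWarning, match="constant"):
            t = bestkeeper(m)
        assert t.values[0] == 0.0
        desc = t.extras["descriptives"]
        assert np.isnan(desc.loc[0, "r_index"])
        assert desc.loc[0, "cv_pct"] == 0.0

    def test_both_dispersion_dialects(self):
        m = make_matrix([[10, 12, 14], [11, 11, 12]])
        assert bestkeeper(m, dialect="mad").values[0] == pytest.approx(4 / 3)
        assert bestkeeper(m, dialect="sd").values[0] == pytest.approx(2.0)

    def test_gene_equal_to_index_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        ct = rng.uniform(10, 20, size=(3, 6))
        # replace gene 0 by the geometric mean of the others' grid plus itself:
        # simpler: make all genes equal so each equals the index
        ct = np.tile(ct[1], (3, 1))
        t = bestkeeper(make_matrix(ct))
        np.testing.assert_allclose(t.extras["descriptives"]["r_index"], 1.0)

    def test_index_is_per_sample_geometric_mean(self, worked_matrix):
        from oracles import brute_bestkeeper_index

        t = bestkeeper(worked_matrix)
        np.testing.assert_allclose(
            t.extras["index"], brute_bestkeeper_index(worked_matrix)
        )


class TestDeltaCt:
    def test_identical_profiles_zero(self):
        ct = np.tile(np.array([10.0, 11, 13, 12]), (3, 1))
        t = delta_ct_stability(make_matrix(ct))
        np.testing.assert_allclose(t.values, 0.0)

    def test_gene_shift_invariance(self, worked_matrix):
        base = delta_ct_stability(worked_matrix).values
        ct = worked_matrix.ct.copy()
        ct[1] += 7.0
        shifted = delta_ct_stability(make_matrix(ct, genes=worked_matrix.genes))
        np.testing.assert_allclose(shifted.values, base)

    def test_worked_matrix_matches_oracle(self, worked_matrix):
        t = delta_ct_stability(worked_matrix)
        brute = BRUTE["delta_ct"](worked_matrix)
        for g, v in zip(t.genes, t.values):
            assert v == pytest.approx(brute[g], abs=1e-12)
        # with E = 2 the pairwise Ct SDs coincide with the log-ratio SDs
        for g in t.genes:
            assert brute[g] == pytest.approx(WORKED_M[g])


@pytest.mark.parametrize("algorithm", ALGORITHMS)
def test_brute_force_equivalence(algorithm):
    """Each algorithm matches its loop-based oracle on random matrices."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        m = random_matrix(rng)
        t = stability_table(m, algorithm)
        brute = BRUTE[algorithm](m)
        if algorithm == "genorm":
            got = dict(genorm_m(m))
        else:
            got = dict(zip(t.genes, t.values))
        for g in m.genes:
            assert got[g] == pytest.approx(brute[g], abs=1e-10)


def _worked():
    return make_matrix(
        [[10, 10, 10, 10], [11, 12, 11, 12], [15, 14, 15, 16]],
        genes=["A", "B", "C"],
    )


@given(shift=st.floats(-5, 5), gene=st.integers(0, 2))
@settings(max_examples=25, deadline=None)
def test_gene_shift_leaves_all_values_unchanged(shift, gene):
    """Adding a constant to one gene's Ct leaves all four values unchanged."""
    base_m = _worked()
    ct = base_m.ct.copy()
    ct[gene] += shift
    if not (ct > 0).all() or not (ct <= 45).all():
        return
    shifted = make_matrix(ct, genes=base_m.genes)
    for alg in ALGORITHMS:
        base = stability_table(base_m, alg)
        new = stability_table(shifted, alg)
        np.testing.assert_allclose(new.values, base.values, atol=5e-8)


@given(shift=st.floats(-3, 3), sample=st.integers(0, 3))
@settings(max_examples=25, deadline=None)
def test_sample_shift_invariance_except_bestkeeper(shift, sample):
    """Per-sample shifts cancel for the ratio/model/pairwise algorithms."""
    base_m = _worked()
    ct = base_m.ct.copy()
    ct[:, sample] += shift
    if not (ct > 0).all() or not (ct <= 45).all():
        return
    shifted = make_matrix(ct, genes=base_m.genes)
    for alg in ("genorm", "delta_ct", "normfinder"):
        base = stability_table(base_m, alg)
        new = stability_table(shifted, alg)
        # atol covers sqrt-amplified float noise at exactly-zero variances
        np.testing.assert_allclose(new.values, base.values, atol=5e-8)


def test_spiked_gene_ranks_last_in_all_four():
    """One 5x-noise gene lands last concordantly in >=95% of replicates."""
    hkgs = tuple(GeneSpec(f"G{i}", 15.0, 0.3) for i in range(5))
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        cfg = spiked_instability(
            SynthConfig(hkgs=hkgs, targets=(), conditions=("A", "B", "C"),
                        seed=seed),
            "G2", 5.0,
        )
        m = generate(cfg)
        last_everywhere = True
        for alg in ALGORITHMS:
            t = stability_table(m, alg)
            if alg == "genorm":
                last = t.genes[int(np.argmax(t.ranks))]
            else:
                last = t.genes[int(np.argmax(t.values))]
            last_everywhere &= last == "G2"
        hits += last_everywhere
    assert hits >= 0.95 * n_rep
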