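import numpy as np
import pytest
from scipy.integrate import quad

from pairpot.atoms import N_ORDERED_PAIRS
from pairpot.histogram import (
    PairHistogram,
    count_pairs,
    histogram_structures,
    make_scheme,
)
from pairpot.reference import (
    ReferenceSpec,
    ave_reference,
    build_reference,
    dfire_reference,
    dope_reference,
    expected_counts_kbp,
    fit_alpha,
    gaussian_chain_pdf,
    kbp_reference,
    observed_distribution,
    rw_reference,
    sphere_pair_distance_pdf,
    srs_reference,
)


@pytest.fixture(scope="module")
def hist20(training_set, scheme8):
    return histogram_structures(training_set, scheme8, 2)


def _toy_hist(counts, cutoff=5.0, s_min=0):
    """Histogram with given per-bin counts placed in a single pair cell."""
    scheme = make_scheme(cutoff)
    h = PairHistogram(scheme=scheme, s_min=s_min)
    h.counts[0, 0, :] = counts
    h.atom_counts[0] = 2
    h.separation_weights = {1: int(np.sum(counts))}
    return h


class TestObservedDistribution:
    def test_equal_counts_give_equal_probabilities(self):
        h = _toy_hist([2, 2, 0, 0, 0])
        f = observed_distribution(h, pseudocount=0)
        assert np.allclose(f[0, 0, :2], 0.5)

    def test_laplace_limit_on_empty_counts(self):
        h = _toy_hist([0, 0, 0, 0, 0])
        f = observed_distribution(h, pseudocount=1)
        assert np.allclose(f[0, 0], 1 / 5)

    def test_rows_sum_to_one(self, hist20):
        f = observed_distribution(hist20, pseudocount=1)
        assert np.allclose(f.sum(axis=2), 1.0, atol=1e-9)

    def test_zero_pseudocount_flags_empty_pairs(self):
        h = _toy_hist([1, 1, 0, 0, 0])
        f = observed_distribution(h, pseudocount=0)
        assert np.isnan(f[5, 5]).all()  # pair with no observations
        assert not np.isnan(f[0, 0]).any()


class TestAveReference:
    def test_uniform_pair_distributions_are_a_fixed_point(self):
        h = _toy_hist([4, 4, 4, 4, 4])
        h.counts[1, 1, :] = [4, 4, 4, 4, 4]
        ref = ave_reference(h, pseudocount=1)
        f_obs = observed_distribution(h, pseudocount=1)
        assert np.allclose(ref.full[0, 0], f_obs[0, 0])

    def test_equal_total_pairs_average_their_distributions(self):
        h = _toy_hist([8, 0, 0, 0, 0])
        h.counts[1, 1, :] = [0, 8, 0, 0, 0]
        ref = ave_reference(h, pseudocount=0)
        # pooled mass: bins 0 and 1 each hold half of the counts
        assert ref.full[0, 0, 0] == pytest.approx(0.5)
        assert ref.full[0, 0, 1] == pytest.approx(0.5)

    def test_matches_direct_tensor_sum(self, hist20):
        ref = ave_reference(hist20, pseudocount=1)
        pooled = hist20.counts.sum(axis=(0, 1)) + N_ORDERED_PAIRS
        assert np.allclose(ref.full[0, 0], pooled / pooled.sum())

    def test_constant_across_pairs(self, hist20):
        ref = ave_reference(hist20)
        assert np.allclose(ref.full[3, 7], ref.full[100, 42])


class TestKbpReference:
    def test_single_atom_type_reduces_to_ave(self):
        h = _toy_hist([3, 5, 2, 0, 1])
        ave = ave_reference(h, pseudocount=1)
        kbp = kbp_reference(h, pseudocount=1)
        assert np.allclose(kbp.full, ave.full)
        assert kbp.chi[0] == 1.0

    def test_expected_counts_match_brute_force(self, hist20):
        ref = kbp_reference(hist20)
        E = expected_counts_kbp(ref)
        chi = ref.chi
        n_tot = hist20.bin_totals().astype(float)
        i, j, b = 13, 57, 2
        assert E[i, j, b] == pytest.approx(chi[i] * chi[j] * n_tot[b])
        # expected counts conserve the total over the chi simplex
        assert E.sum() == pytest.approx(n_tot.sum())

    def test_uniform_mole_fractions_split_evenly(self):
        h = _toy_hist([4, 0, 0, 0, 0])
        h.atom_counts[:] = 0
        h.atom_counts[[0, 1]] = 10  # two types, equal abundance
        ref = kbp_reference(h, pseudocount=0)
        E = expected_counts_kbp(ref)
        assert E[0, 0, 0] == pytest.approx(4 * 0.25)
        assert E[0, 1, 0] == pytest.approx(4 * 0.25)


class TestDfireReference:
    def test_alpha_zero_uniform_over_equal_width_bins(self):
        ref = dfire_reference(make_scheme(10.0), alpha=0.0)
        f = ref.full[0, 0]
        assert np.allclose(f[1:], f[1], atol=1e-12)  # equal-width bins equal
        assert f[0] == pytest.approx(6 * f[1])  # bin 0 is 6x wider

    def test_alpha_one_ratio_is_midpoint_ratio(self):
        ref = dfire_reference(make_scheme(10.0), alpha=1.0)
        f = ref.full[0, 0]
        mids = make_scheme(10.0).midpoints
        assert f[2] / f[1] == pytest.approx(mids[2] / mids[1])

    def test_matches_quadrature_of_r_alpha(self):
        """Midpoint bin mass tracks the exact integral of r^1.61 within 1%."""
        scheme = make_scheme(14.5)
        ref = dfire_reference(scheme, alpha=1.61)
        exact = np.array(
            [
                quad(lambda r: r**1.61, lo, hi)[0]
                for lo, hi in zip(scheme.edges[:-1], scheme.edges[1:])
            ]
        )
        exact /= exact.sum()
        assert np.allclose(ref.full[0, 0], exact, rtol=0.01)

    def test_alpha_at_or_above_two_rejected(self):
        with pytest.raises(ValueError):
            dfire_reference(make_scheme(10.0), alpha=2.0)


class TestFitAlpha:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_recovers_exponent_from_synthetic_counts(self, alpha):
        scheme = make_scheme(14.5)
        mass = scheme.midpoints**alpha * scheme.widths
        counts = np.round(1e6 * mass / mass.sum()).astype(int)
        h = _toy_hist(counts, cutoff=14.5)
        assert fit_alpha(h) == pytest.approx(alpha, abs=0.05)

    def test_ideal_gas_counts_clamp_below_two(self):
        scheme = make_scheme(14.5)
        mass = scheme.midpoints**2.0 * scheme.widths
        h = _toy_hist(np.round(1e6 * mass / mass.sum()).astype(int), cutoff=14.5)
        a = fit_alpha(h)
        assert 1.9 < a < 2.0

    def test_flat_density_gives_alpha_near_zero(self):
        scheme = make_scheme(14.5)
        h = _toy_hist(np.round(1e5 * scheme.widths).astype(int), cutoff=14.5)
        assert fit_alpha(h) == pytest.approx(0.0, abs=0.05)

    def test_too_few_bins_raises(self):
        h = _toy_hist([5, 5, 0, 0, 0])
        with pytest.raises(ValueError):
            fit_alpha(h)


class TestDopeReference:
    @pytest.mark.parametrize("R", [5.0, 11.3, 30.0])
    def test_pdf_integrates_to_one(self, R):
        val, _ = quad(lambda r: sphere_pair_distance_pdf(r, R), 0, 2 * R)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_mean_is_36R_over_35(self):
        R = 7.0
        mean, _ = quad(lambda r: r * sphere_pair_distance_pdf(r, R), 0, 2 * R)
        assert mean == pytest.approx(36 * R / 35, rel=1e-8)

    def test_single_structure_reference_is_its_binned_pdf(self, helix25):
        scheme = make_scheme(8.0)
        ref = dope_reference([helix25], scheme)
        from pairpot.reference import _sphere_pair_distance_cdf, sphere_radius

        R = sphere_radius(helix25)
        mass = np.diff(_sphere_pair_distance_cdf(scheme.edges, R))
        assert np.allclose(ref.full[0, 0], mass / mass.sum())

    def test_bin_masses_match_quadrature(self, helix25):
        from pairpot.reference import sphere_radius

        scheme = make_scheme(8.0)
        R = sphere_radius(helix25)
        ref = dope_reference([helix25], scheme)
        exact = np.array(
            [
                quad(lambda r: sphere_pair_distance_pdf(r, R), lo, hi)[0]
                for lo, hi in zip(scheme.edges[:-1], scheme.edges[1:])
            ]
        )
        assert np.allclose(ref.full[0, 0], exact / exact.sum(), atol=1e-8)

    def test_fewer_than_two_atoms_rejected(self):
        from pairpot.structure import AtomSite, StructureModel

        one = StructureModel(
            chain_id="A",
            atoms=[AtomSite(0, "GLY", "CA", 57, np.zeros(3))],
            sequence=["GLY"],
        )
        with pytest.raises(ValueError):
            dope_reference([one], make_scheme(5.0))


class TestRwReference:
    @pytest.mark.parametrize("n,L", [(1, 3.8), (7, 3.8), (20, 1.5)])
    def test_pdf_integrates_to_one(self, n, L):
        val, _ = quad(lambda r: gaussian_chain_pdf(r, n, L), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_L_sqrt_2n_over_3(self):
        n, L = 9, 3.8
        r = np.linspace(0.01, 40, 200001)
        p = gaussian_chain_pdf(r, n, L)
        assert r[np.argmax(p)] == pytest.approx(L * np.sqrt(2 * n / 3), abs=1e-3)

    def test_single_separation_gives_binned_renormalized_pdf(self):
        h = _toy_hist([1, 1, 1, 1, 1], cutoff=5.0)
        h.separation_weights = {4: 5}
        ref = rw_reference(h, step_length=3.8)
        scheme = h.scheme
        exact = np.array(
            [
                quad(lambda r: gaussian_chain_pdf(r, 4, 3.8), lo, hi)[0]
                for lo, hi in zip(scheme.edges[:-1], scheme.edges[1:])
            ]
        )
        assert np.allclose(ref.full[0, 0], exact / exact.sum(), atol=1e-7)

    def test_zero_separation_folded_into_one_step(self):
        h0 = _toy_hist([1, 1, 1, 1, 1])
        h0.separation_weights = {0: 3}
        h1 = _toy_hist([1, 1, 1, 1, 1])
        h1.separation_weights = {1: 3}
        assert np.allclose(
            rw_reference(h0).full[0, 0], rw_reference(h1).full[0, 0]
        )

    def test_empty_separation_weights_rejected(self):
        h = _toy_hist([0, 0, 0, 0, 0])
        h.separation_weights = {}
        with pytest.raises(ValueError):
            rw_reference(h)


class TestSrsReference:
    def test_identity_permutation_reproduces_observed(self, training_set, scheme8):
        sub = training_set[:4]
        hist = histogram_structures(sub, scheme8, 2)
        ref = srs_reference(
            sub, scheme8, 2, permutation_fn=lambda rng, n: np.arange(n)
        )
        f_obs = observed_distribution(hist, pseudocount=1)
        assert np.allclose(ref.f_ref, f_obs, atol=1e-12)

    def test_type_homogeneous_structure_shuffle_is_noop(self):
        from pairpot.structure import AtomSite, StructureModel

        rng = np.random.default_rng(0)
        atoms = [
            AtomSite(i, "GLY", "CA", 57, rng.normal(0, 4, 3)) for i in range(8)
        ]
        m = StructureModel(chain_id="A", atoms=atoms, sequence=["GLY"] * 8)
        scheme = make_scheme(8.0)
        hist = count_pairs(m, scheme, 1)
        ref = srs_reference([m], scheme, 1, shuffle_seed=123)
        f_obs = observed_distribution(hist, pseudocount=1)
        assert np.allclose(ref.f_ref, f_obs)

    def test_fixed_seed_is_bit_reproducible(self, training_set, scheme8):
        sub = training_set[:3]
        r1 = srs_reference(sub, scheme8, 2, shuffle_seed=7, n_shuffles=2)
        r2 = srs_reference(sub, scheme8, 2, shuffle_seed=7, n_shuffles=2)
        assert np.array_equal(r1.f_ref, r2.f_ref)

    def test_many_shuffles_converge_to_ave_on_homogeneous_types(self):
        """Shuffling a single-type dataset cannot change anything, so the
        srs reference equals the averaging reference exactly."""
        from pairpot.structure import AtomSite, StructureModel

        rng = np.random.default_rng(3)
        atoms = [
            AtomSite(i, "ALA", "CA", 1, rng.normal(0, 5, 3)) for i in range(12)
        ]
        m = StructureModel(chain_id="A", atoms=atoms, sequence=["ALA"] * 12)
        scheme = make_scheme(10.0)
        srs = srs_reference([m], scheme, 1, shuffle_seed=1, n_shuffles=5,
                            pseudocount=0)
        hist = count_pairs(m, scheme, 1)
        ave = ave_reference(hist, pseudocount=0)
        assert np.allclose(srs.f_ref[1, 1], ave.full[1, 1], atol=1e-12)


@pytest.mark.parametrize("kind", ["ave", "kbp", "dfire", "dope", "rw", "srs"])
def test_every_reference_is_normalized_per_pair(kind, training_set, scheme8, hist20):
    ref = build_reference(kind, hist20, structures=training_set[:4])
    full = ref.full
    assert np.all(full >= 0)
    assert np.allclose(full.sum(axis=2), 1.0, atol=1e-9)


def test_dfire_alpha_to_two_approaches_ideal_gas_quadrature():
    """As alpha -> 2 the reference converges to the uniform-density r^2 law."""
    scheme = make_scheme(12.0)
    ref = dfire_reference(scheme, alpha=2 - 1e-9)
    exact = np.array(
        [
            quad(lambda r: r**2, lo, hi)[0]
            for lo, hi in zip(scheme.edges[:-1], scheme.edges[1:])
        ]
    )
    assert np.allclose(ref.full[0, 0], exact / exact.sum(), rtol=0.02)


def test_reference_spec_validation():
    with pytest.raises(ValueError):
        ReferenceSpec(kind="nope")
    with pytest.raises(ValueError):
        ReferenceSpec(kind="dfire", alpha=2.5)
    with pytest.raises(ValueError):
        ReferenceSpec(kind="rw", step_length=0.0)
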