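import numpy as np
import pytest

from conftest import feasible_delta
from qgvar.decomposition import (
    COMPONENTS,
    closed_form_two_locus_variances,
    cockerham_d1_d2,
    kempthorne_effects,
    single_locus_inbred_effects,
    variance_components_from_sample,
)
from qgvar.ld import TwoLocusDist


def anova_oracle(grid: np.ndarray, p_a: float, p_b: float) -> dict:
    """Independent decomposition oracle: orthogonal single-locus contrasts
    under the HWE product measure at (p_a, p_b).

    Per locus (dosage order 0, 1, 2) the additive contrast is the breeding
    value (-2p, q-p, 2q) and the dominance contrast (-2p^2, 2pq, -2q^2);
    both have zero mean and are mutually orthogonal under HWE weights.  The
    3x3 grid expands exactly in the tensor basis, giving each component
    value table by projection.
    """
    def basis(p):
        q = 1.0 - p
        w = np.array([q * q, 2 * p * q, p * p])
        u0 = np.ones(3)
        u1 = np.array([-2 * p, q - p, 2 * q])
        u2 = np.array([-2 * p * p, 2 * p * q, -2 * q * q])
        return w, (u0, u1, u2)

    wa, ua = basis(p_a)
    wb, ub = basis(p_b)
    W = np.outer(wa, wb)
    coef = np.zeros((3, 3))
    for r in range(3):
        for s in range(3):
            basis_rs = np.outer(ua[r], ub[s])
            norm = (wa @ ua[r] ** 2) * (wb @ ub[s] ** 2)
            coef[r, s] = np.sum(W * grid * basis_rs) / norm
    out = {
        "M": coef[0, 0],
        "A": coef[1, 0] * np.outer(ua[1], ub[0]) + coef[0, 1] * np.outer(ua[0], ub[1]),
        "D": coef[2, 0] * np.outer(ua[2], ub[0]) + coef[0, 2] * np.outer(ua[0], ub[2]),
        "AA": coef[1, 1] * np.outer(ua[1], ub[1]),
        "AD": coef[1, 2] * np.outer(ua[1], ub[2]),
        "DA": coef[2, 1] * np.outer(ua[2], ub[1]),
        "DD": coef[2, 2] * np.outer(ua[2], ub[2]),
    }
    return out


class TestSingleLocus:
    def test_noninbred_reduces_to_textbook(self):
        e = single_locus_inbred_effects(0.3, 1.0, 0.5, 0.0)
        assert e.alpha_A == pytest.approx(e.q * e.alpha)
        assert e.M_F == pytest.approx(e.M)
        # E(A^(0)) = E(D^(0)) = 0 in HWE
        assert e.genotype_freqs @ e.A0 == pytest.approx(0.0, abs=1e-12)
        assert e.genotype_freqs @ e.D0 == pytest.approx(0.0, abs=1e-12)

    def test_complete_inbreeding_at_half_frequency(self):
        e = single_locus_inbred_effects(0.5, 1.0, 0.4, 1.0)
        d = e.d
        assert np.allclose(e.An - e.A0, d)          # 4Fpqd = d
        assert np.allclose(e.Dn - e.D0, d / 2.0)    # 2Fpqd = d/2

    def test_mean_and_component_expectations(self, rng):
        for _ in range(50):
            p = rng.uniform(0.05, 0.95)
            a, d = rng.uniform(-1, 1, 2)
            F = rng.uniform(0, 1)
            e = single_locus_inbred_effects(p, a, d, F, m=rng.normal())
            w = e.genotype_freqs
            assert w.sum() == pytest.approx(1.0)
            # E(G) = M_F over the inbred genotype distribution
            assert w @ e.genotype_values == pytest.approx(e.M_F, abs=1e-12)
            # E(D^(0)) = -2Fpqd; E(A^(0)) = 0; E(D^(n)) = 0
            assert w @ e.D0 == pytest.approx(-2 * F * p * (1 - p) * d, abs=1e-12)
            assert w @ e.A0 == pytest.approx(0.0, abs=1e-12)
            assert w @ e.Dn == pytest.approx(0.0, abs=1e-12)

    def test_cockerham_components_vanish_at_half_frequency(self):
        effects = [single_locus_inbred_effects(0.5, a, d, 0.0)
                   for a, d in [(1.0, 0.3), (0.7, 0.7)]]
        d1, d2 = cockerham_d1_d2(effects)
        assert d1 == 0.0 and d2 == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            single_locus_inbred_effects(1.5, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            single_locus_inbred_effects(0.5, 1.0, 0.0, 2.0)


class TestKempthorneEffects:
    def test_nonepistatic_grid_has_no_interaction_effects(self, rng):
        for _ in range(10):
            pa, pb = rng.uniform(0.1, 0.9, 2)
            dist = TwoLocusDist.from_margins(pa, pb, feasible_delta(pa, pb, rng))
            a1, d1, a2, d2 = rng.uniform(-1, 1, 4)
            grid = np.add.outer(np.array([-a1, d1, a1]), np.array([-a2, d2, a2]))
            es = kempthorne_effects(dist, grid)
            for c in ("AA", "AD", "DA", "DD"):
                assert np.max(np.abs(es.values[c])) < 1e-9

    def test_fit_reproduces_grid_exactly(self, rng):
        for _ in range(10):
            pa, pb = rng.uniform(0.1, 0.9, 2)
            dist = TwoLocusDist.from_margins(pa, pb, feasible_delta(pa, pb, rng))
            grid = rng.normal(0, 1, (3, 3))
            es = kempthorne_effects(dist, grid)
            assert np.max(np.abs(es.fitted() - grid)) < 1e-9

    def test_matches_orthogonal_contrast_oracle(self, rng):
        for _ in range(20):
            pa, pb = rng.uniform(0.1, 0.9, 2)
            dist = TwoLocusDist.from_margins(pa, pb, feasible_delta(pa, pb, rng))
            grid = rng.normal(0, 1, (3, 3))
            es = kempthorne_effects(dist, grid)
            oracle = anova_oracle(grid, pa, pb)
            assert es.M == pytest.approx(oracle["M"], abs=1e-9)
            for c in COMPONENTS:
                assert np.allclose(es.values[c], oracle[c], atol=1e-9), c

    def test_fixed_allele_rejected(self, rng):
        dist = TwoLocusDist.from_margins(1.0, 0.5, 0.0)
        with pytest.raises(ValueError, match="fixed"):
            kempthorne_effects(dist, rng.normal(0, 1, (3, 3)))


class TestClosedFormVariances:
    def test_hwe_no_ld_reduces_to_classic(self):
        ea = single_locus_inbred_effects(0.3, 1.0, 0.4, 0.0)
        eb = single_locus_inbred_effects(0.6, 0.8, 0.2, 0.0)
        s2a, s2d, sad = closed_form_two_locus_variances(ea, eb, 0.0, 0.2, 0)
        expect_a = 2 * ea.p * ea.q * ea.alpha**2 + 2 * eb.p * eb.q * eb.alpha**2
        expect_d = 4 * (ea.p * ea.q * ea.d) ** 2 + 4 * (eb.p * eb.q * eb.d) ** 2
        assert s2a == pytest.approx(expect_a)
        assert s2d == pytest.approx(expect_d)
        assert sad == 0.0

    def test_ad_covariance_vanishes_at_half_frequencies(self, rng):
        for n in (0, 3, 10):
            ea = single_locus_inbred_effects(0.5, 1.0, 0.7, 0.0)
            eb = single_locus_inbred_effects(0.5, 0.6, 0.2, 0.0)
            _, _, sad = closed_form_two_locus_variances(ea, eb, 0.12, 0.1, n)
            assert sad == pytest.approx(0.0, abs=1e-12)

    def test_agreement_with_enumeration_oracle(self, rng):
        """Printed formulas vs brute-force decomposition over the exact
        selfing distribution, 200 random draws, relative 1e-8."""
        for _ in range(200):
            pa, pb = rng.uniform(0.1, 0.9, 2)
            a1, d1, a2, d2 = rng.uniform(-1, 1, 4)
            delta = feasible_delta(pa, pb, rng)
            r = rng.uniform(0.0, 0.5)
            n = int(rng.integers(0, 11))
            dist = TwoLocusDist.from_margins(pa, pb, delta).self_generations(r, n)
            grid = np.add.outer(np.array([-a1, d1, a1]), np.array([-a2, d2, a2]))
            es = kempthorne_effects(dist, grid)
            vc = es.parametric_components(dist)
            ea = single_locus_inbred_effects(pa, a1, d1, 0.0)
            eb = single_locus_inbred_effects(pb, a2, d2, 0.0)
            s2a, s2d, sad = closed_form_two_locus_variances(ea, eb, delta, r, n)
            scale = max(abs(s2a), abs(s2d), abs(sad), 1e-6)
            assert abs(s2a - vc.variances["A"]) < 1e-8 * scale
            assert abs(s2d - vc.variances["D"]) < 1e-8 * scale
            assert abs(sad - vc.covariances[("A", "D")]) < 1e-8 * scale


class TestSampleComponents:
    def test_identical_individuals_zero_variance(self):
        import pandas as pd

        df = pd.DataFrame(
            {c: np.zeros(10) for c in COMPONENTS} | {"G": np.full(10, 3.0)}
        )
        vc = variance_components_from_sample(df)
        assert all(v == 0 for v in vc.variances.values())
        assert vc.sigma2_G == 0.0

    def test_total_identity_is_algebraic(self, rng):
        import pandas as pd

        data = {c: rng.normal(0, 1, 500) for c in COMPONENTS}
        df = pd.DataFrame(data)
        df["G"] = 5.0 + df[list(COMPONENTS)].sum(axis=1)
        vc = variance_components_from_sample(df)
        assert vc.total == pytest.approx(vc.sigma2_G, abs=1e-10)

    def test_enumerated_population_matches_parametric(self, rng):
        """A population holding every two-locus genotype in exact proportion
        reproduces the parametric EffectSet-based components."""
        pa, pb = 0.5, 0.5
        dist = TwoLocusDist.from_margins(pa, pb, 0.1)
        grid = rng.normal(0, 1, (3, 3))
        es = kempthorne_effects(dist, grid)
        vc_param = es.parametric_components(dist)
        f = dist.f9().ravel()
        # build an exact finite population by weighting each cell
        counts = np.round(f * 1e6).astype(int)
        cv = es.centered_values(dist)
        import pandas as pd

        cols = {c: np.repeat(cv[c].ravel(), counts) for c in COMPONENTS}
        df = pd.DataFrame(cols)
        df["G"] = es.M_F(dist) + df[list(COMPONENTS)].sum(axis=1)
        vc = variance_components_from_sample(df)
        for c in COMPONENTS:
            assert vc.variances[c] == pytest.approx(
                vc_param.variances[c], rel=1e-3, abs=1e-6
            )

    def test_too_few_individuals(self):
        import pandas as pd

        df = pd.DataFrame({c: [0.0] for c in COMPONENTS} | {"G": [0.0]})
        with pytest.raises(ValueError):
            variance_components_from_sample(df)
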