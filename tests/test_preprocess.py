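"""Absolute-value transform, edge-wise residualization, inversion, and
supra-adjacency assembly."""

import numpy as np
import pytest

from topoconnectome.netio import Cohort, SubjectRecord, ValidationError
from topoconnectome.preprocess import (
    absolute_correlations,
    build_supra_adjacency,
    invert_weights,
    preprocess_cohort,
    residualize_edgewise,
)
from topoconnectome.synthetic import (
    CovariateSlopes,
    GroupEffect,
    SyntheticConfig,
    generate_cohort,
)

from conftest import make_network, random_symmetric


def _subject(sid, group, age, sex, gm, dti, fmri):
    return SubjectRecord(
        sid,
        group,
        age,
        sex,
        {
            "GM": make_network(gm, "GM"),
            "DTI": make_network(dti, "DTI"),
            "FMRI": make_network(fmri, "FMRI"),
        },
    )


class TestAbsoluteCorrelations:
    def test_negative_entry_flipped(self):
        net = make_network([[0, -0.3], [-0.3, 0]], modality="FMRI")
        assert absolute_correlations(net).weights[0, 1] == 0.3

    def test_nonnegative_input_identity(self):
        w = random_symmetric(5, np.random.default_rng(0))
        net = make_network(w, modality="FMRI")
        np.testing.assert_array_equal(absolute_correlations(net).weights, w)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(1)
        w = random_symmetric(6, rng) - random_symmetric(6, rng)
        net = make_network(w, modality="FMRI")
        out = absolute_correlations(net).weights
        np.testing.assert_array_equal(out, out.T)


class TestResidualize:
    def _toy_cohort(self, edge_vals, ages, sexes=None):
        """3+ subjects over 3 regions; the (0,1) edge carries edge_vals."""
        sexes = sexes or ["F"] * len(ages)
        subs = []
        for i, (v, age, sex) in enumerate(zip(edge_vals, ages, sexes)):
            w = np.zeros((3, 3))
            w[0, 1] = w[1, 0] = v
            w[0, 2] = w[2, 0] = 0.5
            w[1, 2] = w[2, 1] = 0.5
            group = "HV" if i % 2 == 0 else "PwMS"
            subs.append(_subject(f"s{i}", group, age, sex, w, w, w))
        return Cohort(subs, parcellation_size=3)

    def test_hand_computed_ols_perfect_linear_fit(self):
        # weights 0.2/0.4/0.6 at ages 30/40/50: exact fit, residuals 0,
        # output = edge mean = 0.4 for every subject
        cohort = self._toy_cohort([0.2, 0.4, 0.6], [30.0, 40.0, 50.0])
        out = residualize_edgewise(cohort)
        for s in out.subjects:
            assert s.networks["DTI"].weights[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_constant_covariates_pass_through(self):
        cohort = self._toy_cohort([0.2, 0.7, 0.4], [40.0, 40.0, 40.0])
        out = residualize_edgewise(cohort)
        for a, b in zip(out.subjects, cohort.subjects):
            np.testing.assert_allclose(
                a.networks["GM"].weights, b.networks["GM"].weights, atol=1e-9
            )

    def test_idempotent(self):
        # weights kept away from the [0, 1] boundaries so no clamp engages
        # (clamping is the one deliberately non-linear step)
        from topoconnectome.synthetic import ModalityParams

        params = {m: ModalityParams("truncnorm", loc=0.5, scale=0.05)
                  for m in ("GM", "DTI", "FMRI")}
        cohort = generate_cohort(
            SyntheticConfig(n_hv=6, n_pwms=6, parcellation_size=8, seed=3,
                            signed_fmri=False, modality_params=params)
        )
        once = residualize_edgewise(cohort)
        twice = residualize_edgewise(once)
        for a, b in zip(twice.subjects, once.subjects):
            for mod in ("GM", "DTI", "FMRI"):
                np.testing.assert_allclose(
                    a.networks[mod].weights, b.networks[mod].weights, atol=1e-9
                )

    def test_injected_age_slope_removed(self):
        slopes = {m: CovariateSlopes(age=0.004, sex=0.0) for m in ("GM", "DTI", "FMRI")}
        cfg = SyntheticConfig(
            n_hv=40, n_pwms=40, parcellation_size=10, seed=6,
            covariate_slopes=slopes, group_effect=GroupEffect(delta=0.0),
            signed_fmri=False,
        )
        cohort = generate_cohort(cfg)
        ages = np.array([s.age for s in cohort.subjects])
        iu = np.triu_indices(10, k=1)

        def age_corrs(c):
            W = np.stack([s.networks["DTI"].weights[iu] for s in c.subjects])
            return np.array(
                [abs(np.corrcoef(ages, W[:, j])[0, 1]) for j in range(W.shape[1])]
            )

        assert age_corrs(cohort).mean() > 0.2  # slope visible before
        assert age_corrs(residualize_edgewise(cohort)).max() < 0.12  # gone after

    def test_signed_fmri_rejected_before_abs(self, tiny_cohort):
        with pytest.raises(ValidationError, match="absolute"):
            residualize_edgewise(tiny_cohort)

    def test_preprocess_cohort_chains_abs_then_residualize(self, tiny_cohort):
        out = preprocess_cohort(tiny_cohort)
        for s in out.subjects:
            assert s.networks["FMRI"].weights.min() >= 0


class TestInvertWeights:
    def test_literal_inversion(self):
        net = make_network([[0, 0.37], [0.37, 0]])
        assert invert_weights(net).weights[0, 1] == pytest.approx(0.63)

    def test_absent_edge_maps_to_one(self):
        net = make_network(np.zeros((2, 2)))
        out = invert_weights(net)
        assert out.weights[0, 1] == 1.0 and out.space == "inverted"

    def test_involution_under_force(self):
        w = random_symmetric(6, np.random.default_rng(4))
        net = make_network(w)
        back = invert_weights(invert_weights(net), force=True)
        np.testing.assert_allclose(back.weights, w, atol=1e-15)
        assert back.space == "raw"

    def test_double_inversion_rejected(self):
        net = make_network(random_symmetric(4, np.random.default_rng(5)))
        with pytest.raises(ValidationError):
            invert_weights(invert_weights(net))

    def test_symmetry_and_range_preserved(self):
        w = random_symmetric(8, np.random.default_rng(6))
        out = invert_weights(make_network(w)).weights
        np.testing.assert_array_equal(out, out.T)
        assert out.min() >= 0 and out.max() <= 1


class TestSupraAdjacency:
    def _toy_subject(self, n=3, coupling_blocks=(0.2, 0.5, 0.8)):
        gm_v, dti_v, fmri_v = coupling_blocks
        full = lambda v: v * (1 - np.eye(n))
        return _subject("t", "HV", 40.0, "F", full(gm_v), full(dti_v), full(fmri_v))

    def test_block_assembly_matches_hand_construction(self):
        s = self._toy_subject()
        ml = build_supra_adjacency(s)
        n = 3
        expected = np.zeros((6, 6))
        expected[:n, :n] = s.networks["GM"].weights
        expected[n:, n:] = s.networks["FMRI"].weights
        expected[:n, n:] = s.networks["DTI"].weights
        expected[n:, :n] = s.networks["DTI"].weights.T
        np.testing.assert_array_equal(ml.supra_weights, expected)

    def test_block_extraction_recovers_inputs(self):
        rng = np.random.default_rng(7)
        s = _subject("t", "HV", 40.0, "F", *(random_symmetric(4, rng) for _ in range(3)))
        ml = build_supra_adjacency(s, replica_coupling=0.9)
        blocks = ml.blocks()
        for mod in ("GM", "DTI", "FMRI"):
            np.testing.assert_array_equal(blocks[mod], s.networks[mod].weights)

    def test_supra_order_is_twice_parcellation(self):
        rng = np.random.default_rng(8)
        s = _subject("t", "HV", 40.0, "F", *(random_symmetric(76, rng) for _ in range(3)))
        assert build_supra_adjacency(s).supra_weights.shape == (152, 152)

    def test_replica_coupling_sets_interlayer_diagonal(self):
        s = self._toy_subject()
        ml = build_supra_adjacency(s, replica_coupling=0.7)
        assert ml.supra_weights[0, 3] == 0.7
        assert build_supra_adjacency(s).supra_weights[0, 3] == 0.0

    def test_zero_dti_decouples_layers(self):
        import networkx as nx

        s = self._toy_subject(coupling_blocks=(0.4, 0.0, 0.6))
        ml = build_supra_adjacency(s)
        inv = 1.0 - ml.supra_weights
        np.fill_diagonal(inv, 0.0)
        # threshold just below 1: only intralayer (inverted < 1) edges present
        g = nx.from_numpy_array((inv <= 0.99) & ~np.eye(6, dtype=bool))
        assert nx.number_connected_components(g) == 2
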