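import numpy as np
import pytest

from arrayemg.kinematics import FingerTrajectory
from arrayemg.layout import ArrayLayout, ChannelMask
from arrayemg.preprocess import EnvelopeSet
from arrayemg.sources import (
    ICDecomposition,
    amari_index,
    fit_ica,
    ic_topology,
    rank_components_by_cc,
    select_channels,
)


class TestAmariIndex:
    def test_identity_is_zero(self):
        assert amari_index(np.eye(4), np.eye(4)) == 0.0

    def test_scaled_permutation_is_zero(self):
        P = np.array([[0.0, 3.0, 0.0], [0.0, 0.0, -0.5], [7.0, 0.0, 0.0]])
        assert amari_index(P, np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_2x2_is_one(self):
        assert amari_index(np.ones((2, 2)), np.eye(2)) == pytest.approx(1.0)

    def test_non_square_product_rejected(self):
        with pytest.raises(ValueError):
            amari_index(np.ones((2, 3)), np.ones((3, 3)))


class TestFitIca:
    def test_separates_laplacian_sources(self):
        rng = np.random.default_rng(42)
        S = rng.laplace(size=(3, 30_000))
        A = rng.normal(size=(8, 3))
        while np.linalg.cond(A) > 20:
            A = rng.normal(size=(8, 3))
        decomp = fit_ica(A @ S, n_components=3, seed=0, fs=500.0)
        assert amari_index(decomp.unmixing, A) <= 0.1

    def test_unmixing_mixing_pseudo_inverse_identity(self):
        rng = np.random.default_rng(1)
        X = rng.laplace(size=(4, 5000)) * np.array([[1], [2], [3], [4.0]])
        X = rng.normal(size=(6, 4)) @ X
        decomp = fit_ica(X, seed=0, fs=500.0)
        r = decomp.retained_rank
        assert np.allclose(decomp.unmixing @ decomp.mixing, np.eye(r), atol=1e-6)

    def test_reconstruction_matches_whitened_subspace(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(3, 20_000))
        A = rng.normal(size=(5, 3))
        X = A @ S
        decomp = fit_ica(X, seed=0, fs=500.0)
        recon = decomp.mixing @ decomp.sources + decomp.mean[:, None]
        # full-rank-in-subspace signal: reconstruction is the projection of X
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) <= 1e-6

    def test_duplicated_channel_handled_by_rank_truncation(self):
        rng = np.random.default_rng(3)
        S = rng.laplace(size=(2, 10_000))
        A = rng.normal(size=(3, 2))
        X = A @ S
        X = np.vstack([X, X[0]])  # exact duplicate channel
        decomp = fit_ica(X, seed=0, fs=500.0)
        assert decomp.retained_rank < X.shape[0]

    def test_gaussian_sources_flagged_non_identifiable(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 4)) @ rng.normal(size=(4, 20_000))
        decomp = fit_ica(X, seed=0, fs=500.0, max_iter=60)
        assert not decomp.converged
        assert any("gaussian" in n for n in decomp.notes) or decomp.notes == ()

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3)) @ rng.laplace(size=(3, 15_000))
        a = fit_ica(X, seed=9, fs=500.0)
        b = fit_ica(X, seed=9, fs=500.0)
        assert np.array_equal(a.unmixing, b.unmixing)


def make_decomp(mixing, layout):
    n_comp = mixing.shape[1]
    return ICDecomposition(
        unmixing=np.linalg.pinv(mixing),
        mixing=mixing,
        sources=np.zeros((n_comp, 10)),
        mean=np.zeros(mixing.shape[0]),
        fs=500.0,
        retained_rank=n_comp,
        seed=0,
    )


class TestTopology:
    def test_concentrated_weight_has_minimal_spread_and_no_flags(self, layout):
        M = np.zeros((96, 1))
        M[layout.index_of("A5"), 0] = 1.0
        topo = ic_topology(make_decomp(M, layout), layout, 0)
        assert topo.spread == pytest.approx(1 / 96)
        assert topo.flags == ()

    def test_uniform_weights_flag_motion_noise(self, layout):
        M = np.ones((96, 1))
        topo = ic_topology(make_decomp(M, layout), layout, 0)
        assert topo.spread == 1.0
        assert "motion-noise" in topo.flags

    def test_opposite_sign_neighbor_flags_detach(self, layout):
        M = np.zeros((96, 1))
        M[layout.index_of("A5"), 0] = 1.0
        nb = layout.neighbors("A5")[0]
        M[layout.index_of(nb), 0] = -0.8
        topo = ic_topology(make_decomp(M, layout), layout, 0)
        assert topo.bipolarity == 1
        assert "detach" in topo.flags

    def test_topology_plot_export(self, layout, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from arrayemg.sources import plot_topology

        M = np.zeros((96, 1))
        M[layout.index_of("B9"), 0] = 1.0
        topo = ic_topology(make_decomp(M, layout), layout, 0)
        out = tmp_path / "topo.png"
        fig = plot_topology(topo, out)
        assert out.stat().st_size > 0
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_component_beyond_rank_rejected(self, layout):
        M = np.zeros((96, 2))
        M[0, 0] = M[1, 1] = 1.0
        with pytest.raises(IndexError):
            ic_topology(make_decomp(M, layout), layout, 5)


def traj_with_target(target, fs=25.0):
    angles = np.zeros((5, target.size))
    angles[1] = target  # Index finger
    return FingerTrajectory(angles, fs=fs)


class TestRankComponents:
    def make(self, envs, layout=None):
        n = envs.shape[0]
        M = np.zeros((96, n))
        for i in range(n):
            M[i, i] = 1.0
        decomp = make_decomp(M, ArrayLayout.default())
        env_set = EnvelopeSet(np.clip(envs, 0, None), 25.0, "independent_component")
        return decomp, env_set

    def test_perfect_component_ranked_first_with_cc_one(self):
        rng = np.random.default_rng(0)
        target = np.clip(np.sin(np.linspace(0, 12 * np.pi, 800)), 0, None)
        envs = rng.uniform(0, 1, (5, 800))
        envs[3] = target
        decomp, env_set = self.make(envs)
        res = rank_components_by_cc(decomp, traj_with_target(target), "Index", "flexion",
                                    component_envelopes=env_set)
        assert res.chosen == 3
        assert res.cc == pytest.approx(1.0, abs=1e-9)

    def test_candidate_list_capped_at_16(self):
        rng = np.random.default_rng(1)
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 500)), 0, None)
        envs = rng.uniform(0, 1, (30, 500))
        decomp, env_set = self.make(envs)
        res = rank_components_by_cc(decomp, traj_with_target(target), "Index", "flexion",
                                    component_envelopes=env_set)
        assert len(res.candidates) <= 16

    def test_tie_broken_toward_lower_index(self):
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 500)), 0, None)
        envs = np.vstack([target, target])  # identical CCs
        decomp, env_set = self.make(envs)
        res = rank_components_by_cc(decomp, traj_with_target(target), "Index", "flexion",
                                    component_envelopes=env_set)
        assert res.chosen == 0

    def test_empty_decomposition_rejected(self):
        decomp = make_decomp(np.zeros((96, 1)), ArrayLayout.default())
        decomp.unmixing = np.zeros((0, 96))
        env = EnvelopeSet(np.zeros((1, 100)), 25.0, "independent_component")
        with pytest.raises(ValueError):
            rank_components_by_cc(decomp, traj_with_target(np.linspace(0, 1, 100)),
                                  "Index", "flexion", component_envelopes=env)


class TestSelectChannels:
    def env_set(self, layout, planted_label, target, rng):
        envs = rng.uniform(0, 0.5, (96, target.size))
        envs[layout.index_of(planted_label)] = target
        return EnvelopeSet(envs, 25.0, "raw_channel", layout.labels)

    def test_planted_channel_selected(self, layout, mask, rng):
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 600)), 0, None)
        planted = mask.labels("Index", "flexion")[2]
        env = self.env_set(layout, planted, target, rng)
        res = select_channels(env, traj_with_target(target), mask, "Index", "flexion", layout=layout)
        assert res.chosen == planted

    def test_candidates_restricted_to_mask(self, layout, mask, rng):
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 600)), 0, None)
        # plant the perfect channel OUTSIDE the Index flexion mask
        env = self.env_set(layout, "B1", target, rng)
        res = select_channels(env, traj_with_target(target), mask, "Index", "flexion", layout=layout)
        assert res.chosen in mask.labels("Index", "flexion")

    def test_single_channel_mask_always_selected(self, layout, rng):
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 300)), 0, None)
        one = ChannelMask({("Index", "flexion"): ("A7",)})
        env = self.env_set(layout, "A1", target, rng)
        res = select_channels(env, traj_with_target(target), one, "Index", "flexion", layout=layout)
        assert res.chosen == "A7"

    def test_empty_mask_raises_naming_the_slot(self, layout, rng):
        empty = ChannelMask({})
        env = self.env_set(layout, "A1", np.ones(100), rng)
        with pytest.raises(ValueError, match="Index.*flexion"):
            select_channels(env, traj_with_target(np.linspace(0, 1, 100)), empty, "Index", "flexion")

    def test_selection_invariant_to_positive_envelope_rescaling(self, layout, mask, rng):
        target = np.clip(np.sin(np.linspace(0, 9 * np.pi, 600)), 0, None)
        planted = mask.labels("Ring", "extension")[1]
        env = self.env_set(layout, planted, target, rng)
        scaled = EnvelopeSet(env.envelopes * 37.5, env.fs, env.source_kind, env.ids)
        traj = FingerTrajectory(np.zeros((5, 600)), fs=25.0)
        traj.angles[3] = -target  # Ring extension target
        a = select_channels(env, traj, mask, "Ring", "extension", layout=layout)
        b = select_channels(scaled, traj, mask, "Ring", "extension", layout=layout)
        assert a.chosen == b.chosen
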