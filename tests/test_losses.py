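"""Contrastive and ZINB losses vs hand-computed values and brute force."""

import numpy as np
import pytest
from scipy.special import gammaln

from scgpcl import losses as L
from scgpcl.autodiff import Tensor


# ---------------------------------------------------------------------------
# brute-force oracles (independent double-loop implementations)
# ---------------------------------------------------------------------------

def cos(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def oracle_instance(H1, H2, tau):
    nb = H1.shape[0]
    total = 0.0
    for A, B in ((H1, H2), (H2, H1)):
        for i in range(nb):
            num = np.exp(cos(A[i], B[i]) / tau)
            den = sum(np.exp(cos(A[i], A[j]) / tau)
                      for j in range(nb) if j != i)
            den += sum(np.exp(cos(A[i], B[j]) / tau) for j in range(nb))
            total += np.log(num / den)
    return -total / (2 * nb)


def oracle_prototype(H1, protos, tau, idx=None):
    nb = H1.shape[0]
    idx = np.arange(nb) if idx is None else idx
    total = 0.0
    for i in range(nb):
        for t in range(protos.T):
            Z = protos.prototypes[t]
            a = protos.assignments[t][idx[i]]
            num = np.exp(cos(H1[i], Z[a]) / tau)
            den = sum(np.exp(cos(H1[i], Z[s]) / tau)
                      for s in range(Z.shape[0]))
            total += np.log(num / den) / protos.T
    return -total / nb


def oracle_zinb_nll(x, pi, mu, theta):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            nb = (np.exp(gammaln(x[i, j] + theta[i, j])
                         - gammaln(x[i, j] + 1) - gammaln(theta[i, j]))
                  * (theta[i, j] / (theta[i, j] + mu[i, j])) ** theta[i, j]
                  * (mu[i, j] / (theta[i, j] + mu[i, j])) ** x[i, j])
            p = pi[i, j] * (x[i, j] == 0) + (1 - pi[i, j]) * nb
            total += -np.log(p)
    return total / x.size


# ---------------------------------------------------------------------------

class TestInfoNCE:
    def test_single_pair_is_zero(self):
        h = np.array([1.0, 2.0])
        assert L.infonce_pair(h, h * 2, np.zeros((0, 2)), [h * 2], 0.7) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_cells_hand_value(self):
        H = np.array([[1.0, 0], [0, 1]])
        l = L.infonce_pair(H[0], H[0], H[1:], H, tau=1.0)
        assert l == pytest.approx(1 - np.log(np.e + 2), abs=1e-10)
        loss = L.instance_loss(Tensor(H), Tensor(H.copy()), tau=1.0)
        assert loss.item() == pytest.approx(np.log(np.e + 2) - 1, abs=1e-10)

    def test_scale_invariance(self, rng):
        H1 = rng.normal(size=(4, 3))
        H2 = rng.normal(size=(4, 3))
        a = L.instance_loss(Tensor(H1), Tensor(H2), 0.5).item()
        b = L.instance_loss(Tensor(5 * H1), Tensor(5 * H2), 0.5).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_cell_batch_loss_is_zero(self):
        H = np.array([[0.3, -0.7]])
        assert L.instance_loss(Tensor(H), Tensor(H * 3), 0.5).item() == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_bruteforce(self, trial):
        rng = np.random.default_rng(trial)
        H1 = rng.normal(size=(8, 4))
        H2 = rng.normal(size=(8, 4))
        got = L.instance_loss(Tensor(H1), Tensor(H2), 0.5).item()
        assert got == pytest.approx(oracle_instance(H1, H2, 0.5), abs=1e-9)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group
        H1 = rng.normal(size=(5, 4))
        H2 = rng.normal(size=(5, 4))
        R = ortho_group.rvs(4, random_state=0)
        a = L.instance_loss(Tensor(H1), Tensor(H2), 0.5).item()
        b = L.instance_loss(Tensor(H1 @ R), Tensor(H2 @ R), 0.5).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            L.instance_loss(Tensor(np.zeros((2, 2))),
                            Tensor(np.ones((2, 2))), 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.instance_loss(Tensor(np.ones((2, 2))),
                            Tensor(np.ones((3, 2))), 0.5)


class TestPrototypes:
    def test_k1_prototype_is_mean(self, rng):
        H = rng.normal(size=(6, 3))
        ps = L.compute_prototypes(H, [1], seed=0)
        np.testing.assert_allclose(ps.prototypes[0][0], H.mean(axis=0),
                                   atol=1e-9)

    def test_separated_clouds_recover_means(self, rng):
        a = rng.normal(size=(10, 2)) * 0.01 + [10, 0]
        b = rng.normal(size=(10, 2)) * 0.01 + [-10, 0]
        H = np.vstack([a, b])
        ps = L.compute_prototypes(H, [2], seed=0)
        got = sorted(ps.prototypes[0].tolist())
        want = sorted([b.mean(axis=0).tolist(), a.mean(axis=0).tolist()])
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_k_equals_n_each_cell_own_prototype(self, rng):
        H = rng.normal(size=(5, 2))
        ps = L.compute_prototypes(H, [5], seed=0)
        assert len(set(ps.assignments[0].tolist())) == 5

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            L.compute_prototypes(rng.normal(size=(3, 2)), [4])


class TestPrototypeLoss:
    def test_single_prototype_zero_loss(self, rng):
        H = rng.normal(size=(4, 3))
        ps = L.compute_prototypes(H, [1], seed=0)
        assert L.prototype_loss(Tensor(H), ps, 0.5).item() == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_value_two_prototypes(self):
        ps = L.PrototypeSet(Ks=[2],
                            prototypes=[np.array([[1.0, 0], [0, 1]])],
                            assignments=[np.array([0])])
        got = L.prototype_loss(Tensor(np.array([[1.0, 0]])), ps, 1.0).item()
        assert got == pytest.approx(np.log(np.e + 1) - 1, abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_bruteforce(self, trial):
        rng = np.random.default_rng(trial + 10)
        H2 = rng.normal(size=(8, 4))
        ps = L.compute_prototypes(H2, [2, 3, 4][: 1 + trial % 3], seed=trial)
        H1 = rng.normal(size=(8, 4))
        got = L.prototype_loss(Tensor(H1), ps, 0.5).item()
        assert got == pytest.approx(oracle_prototype(H1, ps, 0.5), abs=1e-9)

    def test_empty_prototypes_rejected(self, rng):
        ps = L.PrototypeSet(Ks=[], prototypes=[], assignments=[])
        with pytest.raises(ValueError):
            L.prototype_loss(Tensor(rng.normal(size=(2, 2))), ps, 0.5)


class TestZINBDecoder:
    def _params(self, pi, mu, theta):
        return L.ZINBParams(M=Tensor(np.asarray(mu, float)),
                            Theta=Tensor(np.asarray(theta, float)),
                            Pi=Tensor(np.asarray(pi, float)))

    def test_decode_shapes_and_trivial_values(self, rng):
        dec = L.init_decoder(4, 6, hidden_dim=5, seed=0)
        # zero weights in the heads -> exp(0) = 1, sigmoid(0) = 0.5
        for W in (dec.W_mu, dec.W_theta, dec.W_pi):
            W.data[:] = 0.0
        out = L.decode_zinb(Tensor(rng.normal(size=(3, 4))), dec,
                            size_factors=np.array([2.0, 1.0, 0.5]))
        np.testing.assert_allclose(out.M.data[0], 2.0)
        np.testing.assert_allclose(out.Theta.data, 1.0)
        np.testing.assert_allclose(out.Pi.data, 0.5)

    def test_decoded_ranges(self, rng):
        dec = L.init_decoder(4, 6, seed=1)
        out = L.decode_zinb(Tensor(rng.normal(size=(5, 4)) * 10), dec,
                            size_factors=np.ones(5))
        assert np.all(out.Theta.data > 0) and np.all(out.M.data > 0)
        assert np.all((out.Pi.data > 0) & (out.Pi.data < 1))

    def test_pure_zero_inflation_term(self):
        p = self._params([[1.0 - 1e-15]], [[3.0]], [[1.0]])
        assert L.zinb_nll(np.array([[0]]), p).item() == \
            pytest.approx(0.0, abs=1e-9)

    def test_hand_value_zero_count(self):
        # x=0, pi=0.5, mu=1, theta=1: NB(0)=0.5, ZINB=0.75
        p = self._params([[0.5]], [[1.0]], [[1.0]])
        assert L.zinb_nll(np.array([[0]]), p).item() == \
            pytest.approx(-np.log(0.75), abs=1e-10)

    def test_hand_value_positive_count(self):
        # x=2, pi=0, mu=2, theta=1: NB = (1/3)*(2/3)^2 = 4/27
        p = self._params([[1e-15]], [[2.0]], [[1.0]])
        assert L.zinb_nll(np.array([[2]]), p).item() == \
            pytest.approx(-np.log(4 / 27), abs=1e-7)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_bruteforce(self, trial):
        rng = np.random.default_rng(trial + 30)
        x = rng.integers(0, 10, size=(6, 5)).astype(float)
        pi = rng.uniform(0.05, 0.95, size=x.shape)
        mu = rng.uniform(0.2, 8, size=x.shape)
        th = rng.uniform(0.3, 5, size=x.shape)
        got = L.zinb_nll(x, self._params(pi, mu, th)).item()
        assert got == pytest.approx(oracle_zinb_nll(x, pi, mu, th), abs=1e-9)

    def test_pi_to_zero_recovers_pure_nb(self, rng):
        x = rng.integers(0, 6, size=(4, 4)).astype(float)
        mu = rng.uniform(0.5, 5, size=x.shape)
        th = rng.uniform(0.5, 5, size=x.shape)
        zinb = L.zinb_nll(x, self._params(np.full_like(mu, 1e-12), mu, th))
        lognb = (gammaln(x + th) - gammaln(x + 1) - gammaln(th)
                 + th * np.log(th / (th + mu)) + x * np.log(mu / (th + mu)))
        assert zinb.item() == pytest.approx(-lognb.mean(), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            L.zinb_nll(np.array([[-1]]), self._params([[0.5]], [[1.0]],
                                                      [[1.0]]))

    @pytest.mark.parametrize("pi,mu,theta", [
        (0.1, 0.5, 0.5), (0.5, 1.0, 1.0), (0.9, 5.0, 2.0), (0.3, 20.0, 0.7),
    ])
    def test_pmf_normalizes_over_truncated_support(self, pi, mu, theta):
        x = np.arange(2001, dtype=float)
        total = np.exp(L.zinb_logpmf(x, pi, mu, theta)).sum()
        assert 1 - 1e-6 <= total <= 1 + 1e-9


class TestPretrainLoss:
    def test_zero_coefficients_leave_only_zinb(self):
        got = L.pretrain_loss(1.0, 2.0, (0.4, 0.6), 0.0, 0.0)
        assert got == pytest.approx(0.5)

    def test_default_balance_arithmetic(self):
        got = L.pretrain_loss(1.0, 2.0, (0.4, 0.6))
        assert got == pytest.approx(1.0 * 1.0 + 0.05 * 2.0 + 0.5)

    def test_identical_views_average_to_single_view(self):
        assert L.pretrain_loss(0.0, 0.0, (0.7, 0.7), 0, 0) == \
            pytest.approx(0.7)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            L.pretrain_loss(1.0, 1.0, (0.5, 0.5), -1.0, 0.05)
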