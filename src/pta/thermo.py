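"""The joint Gaussian over concentrations and Gibbs reaction energies.

Gibbs reaction energies decompose as

    dgr = dgr0 + RT * S_Gamma^T * ln c

so log-normal concentration priors and Gaussian standard-energy priors
induce a joint Gaussian over the stacked vector ``t = [ln c, dgr0, dgr]``.
Because group-contribution covariances are typically rank-deficient and the
identity above ties the three blocks together, the joint covariance has
rank ``q`` far below its dimension.  We therefore work in the coordinates
``t = mu_t + Q m`` where ``Sigma_t = Q Q^T`` and ``m`` is a standard
multivariate normal of dimension ``q``: the confidence region
``(t - mu_t)^T Sigma_t^+ (t - mu_t) <= chi2(q, alpha)`` becomes the ball
``||m||^2 <= chi2(q, alpha)``.

A *reduced* form restricted to the energies ``dgr`` (dimension ``q_r``)
drives the samplers; concentrations and standard energies are recovered
afterwards by Gaussian conditioning on ``dgr`` (the Schur complement of
the reduced covariance in the joint one).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import MetabolicNetwork, ThermoPriors

__all__ = [
    "ThermoSpace",
    "ConditionalGaussian",
    "assemble_R",
    "build_joint",
    "factorize",
    "chi2_threshold",
]

DEFAULT_ALPHA = 0.95
RANK_TOL = 1e-9


def assemble_R(network: MetabolicNetwork, priors: ThermoPriors) -> np.ndarray:
    """The linear map ``[ln c; dgr0] -> dgr``: ``R = [RT * S_Gamma^T, I]``."""
    gamma = network.n_gamma
    return np.hstack([priors.RT * network.S_gamma.T, np.eye(gamma)])


def factorize(Sigma: np.ndarray, rank_tol: float = RANK_TOL) -> tuple[np.ndarray, int]:
    """Low-rank square root ``Sigma = Q Q^T`` with whitening columns.

    Eigenvalues below ``rank_tol * max_eigenvalue`` are treated as zero;
    a significantly negative eigenvalue is an error.  Columns of ``Q`` are
    eigenvectors scaled by the square roots of the eigenvalues, so a
    standard normal ``m`` maps to a draw with covariance ``Sigma`` and the
    Mahalanobis form reduces to ``||m||^2``.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Sigma.size == 0:
        return np.zeros((Sigma.shape[0], 0)), 0
    w, V = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    scale = max(float(w.max()), 0.0)
    if scale == 0.0:
        return np.zeros((Sigma.shape[0], 0)), 0
    if w.min() < -1e-6 * scale:
        raise ValueError(
            f"matrix has significantly negative eigenvalue {w.min():.3e}"
        )
    keep = w > rank_tol * scale
    # descending order for a deterministic, dominant-first basis
    order = np.argsort(w[keep])[::-1]
    w_k = w[keep][order]
    V_k = V[:, keep][:, order]
    # fix sign convention: largest-magnitude entry of each column positive
    for k in range(V_k.shape[1]):
        i = np.argmax(np.abs(V_k[:, k]))
        if V_k[i, k] < 0:
            V_k[:, k] = -V_k[:, k]
    Q = V_k * np.sqrt(w_k)
    return Q, Q.shape[1]


def chi2_threshold(q: int, alpha: float) -> float:
    """alpha-quantile of the chi-squared distribution with q dof."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(alpha, df=q))


@dataclass
class ConditionalGaussian:
    """Gaussian over ``[ln c, dgr0]`` given a value of ``dgr``."""

    mean: np.ndarray
    cov: np.ndarray
    n_mets: int
    Q: np.ndarray  # factor of cov
    rank: int

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        z = rng.standard_normal((size, self.rank))
        return self.mean[None, :] + z @ self.Q.T


@dataclass
class ThermoSpace:
    """Joint and reduced Gaussian descriptions of the thermodynamic space."""

    network: MetabolicNetwork
    priors: ThermoPriors
    R_mat: np.ndarray
    mu_t: np.ndarray
    Sigma_t: np.ndarray
    Q: np.ndarray
    q: int
    alpha: float
    # reduced form over dgr only
    mu_r: np.ndarray
    Sigma_r: np.ndarray
    Q_r: np.ndarray
    q_r: int

    # -- thresholds --------------------------------------------------------
    @property
    def chi2(self) -> float:
        """Confidence threshold for the full space (q dof)."""
        return chi2_threshold(self.q, self.alpha)

    @property
    def chi2_r(self) -> float:
        """Confidence threshold for the reduced energy space (q_r dof)."""
        return chi2_threshold(self.q_r, self.alpha)

    @property
    def n_mets(self) -> int:
        return self.network.n_metabolites

    @property
    def n_gamma(self) -> int:
        return self.network.n_gamma

    # -- coordinate maps ---------------------------------------------------
    def to_t(self, m_vec: np.ndarray) -> np.ndarray:
        """Map full-space coordinates ``m`` (q entries) to ``t``."""
        m_vec = np.asarray(m_vec, dtype=float)
        if m_vec.shape[-1] != self.q:
            raise ValueError(f"expected {self.q} coordinates, got {m_vec.shape}")
        return self.mu_t + m_vec @ self.Q.T

    def to_dg(self, m_r: np.ndarray) -> np.ndarray:
        """Map reduced coordinates (q_r entries) to reaction energies."""
        m_r = np.asarray(m_r, dtype=float)
        if m_r.shape[-1] != self.q_r:
            raise ValueError(f"expected {self.q_r} coordinates, got {m_r.shape}")
        return self.mu_r + m_r @ self.Q_r.T

    def reduced_coords(self, dg: np.ndarray) -> np.ndarray:
        """Pseudo-inverse map from reaction energies to reduced coordinates.

        Valid for energies in the support of the reduced distribution;
        ``to_dg(reduced_coords(dg)) == dg`` there.
        """
        dg = np.asarray(dg, dtype=float)
        return (dg - self.mu_r) @ np.linalg.pinv(self.Q_r).T

    def split_t(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Split ``t`` into ``(ln c, dgr0, dgr)``."""
        m, g = self.n_mets, self.n_gamma
        return t[..., :m], t[..., m : m + g], t[..., m + g :]

    def contains(self, m_vec: np.ndarray, reduced: bool = False) -> bool:
        thr = self.chi2_r if reduced else self.chi2
        return float(np.sum(np.square(m_vec))) <= thr + 1e-9

    # -- conditioning ------------------------------------------------------
    def condition_on_dg(self, dg: np.ndarray) -> ConditionalGaussian:
        """Distribution of ``[ln c, dgr0]`` given reaction energies ``dg``.

        Uses the cross-covariance block ``B = [RT Sigma_c S_Gamma; Sigma_0]``
        and a generalized inverse of the (possibly singular) reduced
        covariance; valid for ``dg`` in the support of the reduced
        distribution.
        """
        dg = np.asarray(dg, dtype=float)
        if dg.shape != (self.n_gamma,):
            raise ValueError("dg must be a gamma-vector")
        B = self._cross_cov()
        Sr_pinv = self._Sigma_r_pinv()
        resid = dg - self.mu_r
        # reject values outside the support of the reduced Gaussian
        proj = self.Sigma_r @ (Sr_pinv @ resid)
        scale = max(1.0, float(np.abs(dg).max()))
        if np.abs(proj - resid).max() > 1e-6 * scale:
            raise ValueError("dg is not in the support of the reduced distribution")
        mean = np.concatenate([self.priors.mu_c, self.priors.mu_0]) + B @ (
            Sr_pinv @ resid
        )
        prior_cov = _blockdiag(self.priors.Sigma_c, self.priors.Sigma_0)
        cov = prior_cov - B @ Sr_pinv @ B.T
        Qc, rank = factorize(cov)
        return ConditionalGaussian(
            mean=mean, cov=cov, n_mets=self.n_mets, Q=Qc, rank=rank
        )

    def _cross_cov(self) -> np.ndarray:
        SG = self.network.S_gamma
        RT = self.priors.RT
        return np.vstack([RT * self.priors.Sigma_c @ SG, self.priors.Sigma_0])

    def _Sigma_r_pinv(self) -> np.ndarray:
        # generalized inverse through the same rank-revealing factorization
        w, V = np.linalg.eigh((self.Sigma_r + self.Sigma_r.T) / 2.0)
        scale = max(float(w.max()), 0.0) if w.size else 0.0
        if scale == 0.0:
            return np.zeros_like(self.Sigma_r)
        keep = w > RANK_TOL * scale
        return (V[:, keep] / w[keep]) @ V[:, keep].T

    # -- serialization -----------------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        """Archive means, factors, rank and alpha for reuse across runs."""
        header = {
            "alpha": self.alpha,
            "q": self.q,
            "q_r": self.q_r,
            "reaction_ids": self.network.reaction_ids,
            "metabolite_ids": self.network.metabolite_ids,
            "gamma": self.network.gamma,
        }
        np.savez_compressed(
            path,
            header=json.dumps(header),
            R_mat=self.R_mat,
            mu_t=self.mu_t,
            Sigma_t=self.Sigma_t,
            Q=self.Q,
            mu_r=self.mu_r,
            Sigma_r=self.Sigma_r,
            Q_r=self.Q_r,
        )


def build_joint(
    network: MetabolicNetwork,
    priors: ThermoPriors,
    alpha: float = DEFAULT_ALPHA,
    rank_tol: float = RANK_TOL,
) -> ThermoSpace:
    """Assemble the joint Gaussian over ``t = [ln c, dgr0, dgr]``.

    The mean is ``[mu_c, mu_0, R [mu_c; mu_0]]``; the covariance is the
    block matrix induced by pushing the priors through the linear energy
    decomposition, so every point of the space satisfies it exactly.
    """
    if not network.gamma:
        raise ValueError("network has an empty thermodynamically constrained set")
    R = assemble_R(network, priors)
    mu_prior = np.concatenate([priors.mu_c, priors.mu_0])
    mu_r = R @ mu_prior
    prior_cov = _blockdiag(priors.Sigma_c, priors.Sigma_0)
    Sigma_r = R @ prior_cov @ R.T
    Sigma_r = (Sigma_r + Sigma_r.T) / 2.0

    SG = network.S_gamma
    RT = priors.RT
    cross_c = RT * priors.Sigma_c @ SG  # cov(ln c, dgr)
    cross_0 = priors.Sigma_0  # cov(dgr0, dgr)
    mu_t = np.concatenate([mu_prior, mu_r])
    Sigma_t = np.block(
        [
            [priors.Sigma_c, np.zeros((len(priors.mu_c), len(priors.mu_0))), cross_c],
            [np.zeros((len(priors.mu_0), len(priors.mu_c))), priors.Sigma_0, cross_0],
            [cross_c.T, cross_0.T, Sigma_r],
        ]
    )
    Sigma_t = (Sigma_t + Sigma_t.T) / 2.0
    # Factor the prior covariance and push it through the linear map: with
    # Q = [P; R P] the identity dgr = dgr0 + RT S^T ln c holds exactly for
    # every m, and ||m||^2 still equals the Mahalanobis form because Q has
    # full column rank.
    P, q = factorize(prior_cov, rank_tol)
    Q = np.vstack([P, R @ P])
    Q_r, q_r = factorize(Sigma_r, rank_tol)
    return ThermoSpace(
        network=network,
        priors=priors,
        R_mat=R,
        mu_t=mu_t,
        Sigma_t=Sigma_t,
        Q=Q,
        q=q,
        alpha=alpha,
        mu_r=mu_r,
        Sigma_r=Sigma_r,
        Q_r=Q_r,
        q_r=q_r,
    )


def _blockdiag(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    out = np.zeros((A.shape[0] + B.shape[0], A.shape[1] + B.shape[1]))
    out[: A.shape[0], : A.shape[1]] = A
    out[A.shape[0] :, A.shape[1] :] = B
    return out
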