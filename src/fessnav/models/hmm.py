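"""First-order hidden Markov model with Gaussian emissions (Baum-Welch).

The class-level HMM baseline observes landmark-combination class ids
encoded on the real line as their integer index, with one univariate
Gaussian emission density per hidden state.  Fitting uses the Baum-Welch
(EM) algorithm with per-step scaling; the total log-likelihood is
non-decreasing over iterations and fitting stops when its increase falls
below the convergence threshold (default 0.01) or after the iteration cap
(default 500).

Next-step prediction advances the filtering distribution over hidden
states one transition and emits the class whose encoded value maximizes the
predictive observation density (greedy decoding; ties broken by the lowest
class id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMMConfig", "GaussianHMM"]

_VAR_FLOOR = 1e-3
_PROB_FLOOR = 1e-10


def encode_classes(sequence: list[int]) -> np.ndarray:
    """Map class ids to real-valued observations (the 1-D integer encoding).

    Kept as a separate function so the observation encoding can be swapped
    without touching the model.
    """
    return np.asarray(sequence, dtype=float)


@dataclass
class HMMConfig:
    n_hidden_states: int = 12
    max_iter: int = 500
    tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_states < 1:
            raise ValueError("n_hidden_states must be >= 1")


class GaussianHMM:
    """Gaussian-emission HMM over 1-D encoded class sequences."""

    def __init__(self, config: HMMConfig):
        self.config = config
        self.startprob: np.ndarray | None = None
        self.transmat: np.ndarray | None = None
        self.means: np.ndarray | None = None
        self.variances: np.ndarray | None = None
        self.log_likelihoods: list[float] = []
        self.n_classes: int | None = None
        self.converged = False

    # -- initialization ----------------------------------------------------
    def _init_params(self, all_obs: np.ndarray) -> None:
        K = self.config.n_hidden_states
        rng = np.random.default_rng(self.config.seed)
        lo, hi = all_obs.min(), all_obs.max()
        if K == 1:
            self.means = np.array([all_obs.mean()])
        else:
            self.means = np.linspace(lo, hi, K) + rng.normal(0, 1e-3, K)
        var = max(all_obs.var(), _VAR_FLOOR)
        self.variances = np.full(K, var)
        self.startprob = np.full(K, 1.0 / K)
        A = np.full((K, K), 1.0) + rng.uniform(0, 0.1, size=(K, K))
        self.transmat = A / A.sum(axis=1, keepdims=True)

    def _log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(T, K) log densities of each observation under each state."""
        mu = self.means[None, :]
        var = self.variances[None, :]
        return -0.5 * (np.log(2 * np.pi * var) + (obs[:, None] - mu) ** 2 / var)

    # -- EM ------------------------------------------------------------------
    def _forward_backward(self, log_b: np.ndarray):
        T, K = log_b.shape
        b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
        alpha = np.zeros((T, K))
        scale = np.zeros(T)
        alpha[0] = self.startprob * b[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ self.transmat) * b[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.ones((T, K))
        for t in range(T - 2, -1, -1):
            beta[t] = (self.transmat @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
        loglik = float(np.log(scale).sum() + log_b.max(axis=1).sum())
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi = np.zeros((K, K))
        for t in range(T - 1):
            m = (
                np.outer(alpha[t], b[t + 1] * beta[t + 1])
                * self.transmat
                / scale[t + 1]
            )
            xi += m
        return loglik, gamma, xi

    def fit(self, sequences: list[list[int]]) -> "GaussianHMM":
        """Baum-Welch over one or more class-id sequences."""
        if not sequences:
            raise ValueError("need at least one sequence")
        for s in sequences:
            if len(s) < 2:
                raise ValueError("each sequence needs at least 2 observations")
        obs_seqs = [encode_classes(s) for s in sequences]
        all_obs = np.concatenate(obs_seqs)
        self.n_classes = int(all_obs.max()) + 1
        self._init_params(all_obs)
        K = self.config.n_hidden_states
        self.log_likelihoods = []
        prev_ll = -np.inf
        for _ in range(self.config.max_iter):
            total_ll = 0.0
            gamma_sum = np.zeros(K)
            gamma0_sum = np.zeros(K)
            xi_sum = np.zeros((K, K))
            mean_num = np.zeros(K)
            var_num = np.zeros(K)
            gammas = []
            for obs in obs_seqs:
                ll, gamma, xi = self._forward_backward(self._log_emission(obs))
                total_ll += ll
                gammas.append(gamma)
                gamma0_sum += gamma[0]
                gamma_sum += gamma.sum(axis=0)
                xi_sum += xi
                mean_num += gamma.T @ obs
            self.log_likelihoods.append(total_ll)
            if total_ll - prev_ll < self.config.tol:
                self.converged = True
                break
            prev_ll = total_ll
            # M-step; probabilities floored so filtering never hits an
            # exact zero on observations outside the training support
            self.startprob = gamma0_sum / gamma0_sum.sum()
            self.startprob = np.maximum(self.startprob, _PROB_FLOOR)
            self.startprob /= self.startprob.sum()
            denom = xi_sum.sum(axis=1, keepdims=True)
            self.transmat = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), self.transmat)
            self.transmat = np.maximum(self.transmat, _PROB_FLOOR)
            self.transmat /= self.transmat.sum(axis=1, keepdims=True)
            means = mean_num / np.maximum(gamma_sum, 1e-300)
            # variances against the updated means
            var_num = np.zeros(K)
            for obs, gamma in zip(obs_seqs, gammas):
                var_num += (gamma * (obs[:, None] - means[None, :]) ** 2).sum(axis=0)
            self.means = means
            self.variances = np.maximum(var_num / np.maximum(gamma_sum, 1e-300), _VAR_FLOOR)
        return self

    # -- prediction ----------------------------------------------------------
    def filter(self, sequence: list[int]) -> np.ndarray:
        """Posterior over hidden states after the observed sequence."""
        if not sequence:
            raise ValueError("empty observation sequence")
        obs = encode_classes(sequence)
        log_b = self._log_emission(obs)
        b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
        alpha = self.startprob * b[0]
        alpha /= alpha.sum()
        for t in range(1, len(obs)):
            alpha = (alpha @ self.transmat) * b[t]
            alpha /= alpha.sum()
        return alpha

    def predict_next_distribution(self, sequence: list[int]) -> np.ndarray:
        """Predictive density over class encodings, one step ahead."""
        alpha = self.filter(sequence)
        pred_hidden = alpha @ self.transmat
        classes = encode_classes(list(range(self.n_classes)))
        dens = np.exp(self._log_emission(classes))  # (C, K)
        scores = dens @ pred_hidden
        return scores

    def predict_next(self, sequence: list[int]) -> int:
        """Greedy next class: argmax predictive density, lowest-id ties."""
        return int(np.argmax(self.predict_next_distribution(sequence)))
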