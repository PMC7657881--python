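"""Unconstrained log-posterior and analytic gradient for the probit models.

The multilevel model is parameterized non-centered: participant deviation
vectors are ``diag(sd) @ L @ z`` with ``z`` standard normal and ``L`` the
Cholesky factor of the participant correlation matrix; stimulus intercepts
are ``sd_stim * v``.  Positive scales live on the log scale; the
correlation Cholesky factor is mapped from unconstrained space through
tanh partial correlations and stick-breaking rows on the unit sphere, with
the LKJ prior and the transform's log-Jacobian included in the target
density.  Gradients are exact and fully vectorized over trials.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

from .models import DataError, ModelSpec, PriorSpec, design_arrays

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _inv_mills(x: np.ndarray) -> np.ndarray:
    """phi(x) / Phi(x), stable for very negative x."""
    return np.exp(-0.5 * x * x - _LOG_SQRT_2PI - log_ndtr(x))


def corr_free_size(k: int) -> int:
    return k * (k - 1) // 2


class CorrCholeskyTransform:
    """Unconstrained vector -> correlation Cholesky factor, with LKJ prior.

    Row ``i`` of ``L`` is built by stick-breaking from the tanh-transformed
    partial correlations: ``L[i, j] = z_j * prod_{k<j} sqrt(1 - z_k^2)`` and
    ``L[i, i] = prod_{k<i} sqrt(1 - z_k^2)``.  ``log_density`` returns the
    LKJ(eta) log-density over the free coordinates of ``L`` plus the
    transform's log-Jacobian, so sampling the unconstrained vector targets
    LKJ-distributed correlation matrices.
    """

    def __init__(self, k: int, eta: float = 2.0):
        self.k = k
        self.eta = eta
        self.n_free = corr_free_size(k)
        # padded (k-1, k-1) layout: padded[r, j] holds z for row i = r+1, col j <= r
        rows, cols = np.tril_indices(k - 1)
        self._rows, self._cols = rows, cols
        self._mask = np.zeros((max(k - 1, 1), max(k - 1, 1)), dtype=bool)
        self._mask[rows, cols] = True
        i = np.arange(1, k)[:, None]
        j = np.arange(max(k - 1, 1))[None, :]
        # per-element weight of -t in the analytic terms: LKJ exponent on the
        # row diagonal, the stick log-Jacobian count, and d log(1 - z^2)
        self._a_row = k - np.arange(1, k) + 2.0 * eta - 3.0
        self._analytic = np.where(self._mask, self._a_row[:, None] + (i - 1 - j) + 2.0, 0.0)
        self._r0 = np.arange(max(k - 1, 0))
        self._ridx = np.arange(1, k)
        self._eye = np.eye(k)
        self._ones_col = np.ones((max(k - 1, 1), 1))

    def forward(self, y: np.ndarray):
        k = self.k
        if k == 1:
            return np.eye(1), np.empty(0), 0.0
        z = np.tanh(y)
        zm = np.zeros_like(self._mask, dtype=float)
        zm[self._rows, self._cols] = z
        s2 = np.where(self._mask, 1.0 - zm * zm, 1.0)
        cum = np.cumprod(np.sqrt(s2), axis=1)
        cfull = np.concatenate([self._ones_col, cum], axis=1)  # cfull[r, j]
        chol = self._eye.copy()
        chol[1:, : k - 1][self._mask] = (zm * cfull[:, :-1])[self._mask]
        diag = cfull[self._r0, self._ridx]
        chol[self._ridx, self._ridx] = diag
        logdens = float(
            self._a_row @ np.log(diag)
            + np.log(cfull[:, :-1][self._mask]).sum()
            + np.log(s2[self._mask]).sum()
        )
        self._cache = (zm, s2, cfull)
        return chol, z, logdens

    def backward(self, y: np.ndarray, z: np.ndarray, chol: np.ndarray, g_chol: np.ndarray) -> np.ndarray:
        """Gradient wrt the unconstrained y of (upstream(L) + log_density)."""
        k = self.k
        if k == 1:
            return np.empty(0)
        zm, s2, cfull = self._cache
        t = np.where(self._mask, zm / s2, 0.0)
        # arr[r, j] = G_L[i, j] * L[i, j] for j <= i (diagonal included at j = i)
        arr = np.zeros((k - 1, k))
        gl = g_chol[1:, :]
        arr[:, : k - 1] = np.where(self._mask, gl[:, : k - 1] * chol[1:, : k - 1], 0.0)
        arr[self._r0, self._ridx] = gl[self._r0, self._ridx] * chol[self._ridx, self._ridx]
        suffix = np.cumsum(arr[:, ::-1], axis=1)[:, ::-1]  # suffix[r, j] = sum_{m>=j}
        g_z = gl[:, : k - 1] * cfull[:, :-1] - t * (suffix[:, 1:] + self._analytic)
        g_z = g_z * s2
        return g_z[self._rows, self._cols]


class ProbitPosterior:
    """Joint log-density and gradient over the unconstrained parameter vector.

    Layout: beta (K) | log participant sds (K) | correlation free (K(K-1)/2)
    | participant z (P*K) | log stimulus sd (1) | stimulus v (S); the random
    effect blocks are absent when ``random_effects=False`` (complete
    pooling, used for the no-pooling SDT limit).
    """

    def __init__(
        self,
        model: ModelSpec,
        trials,
        priors: PriorSpec,
        random_effects: bool = True,
    ):
        self.model = model
        self.priors = priors
        self.random_effects = random_effects
        x, y, pidx, sidx, participants, stimuli = design_arrays(model, trials)
        if y.min() == y.max():
            raise DataError(
                "degenerate data: all responses are "
                f"{int(y[0])}; both response values must be present"
            )
        self.x, self.y, self.pidx, self.sidx = x, y, pidx, sidx
        self._iy1 = np.flatnonzero(y == 1.0)
        self._iy0 = np.flatnonzero(y == 0.0)
        self._wbuf = np.empty(len(y))
        self.participants, self.stimuli = participants, stimuli
        self.n_trials = len(y)
        self.k = model.n_terms
        self.n_participants = len(participants)
        self.n_stimuli = len(stimuli)
        self.beta_scale = priors.beta_scales(model.fixed_terms)
        self.corr = CorrCholeskyTransform(self.k, priors.corr_concentration)
        if random_effects:
            self.n_params = (
                self.k
                + self.k
                + self.corr.n_free
                + self.n_participants * self.k
                + 1
                + self.n_stimuli
            )
        else:
            self.n_params = self.k
        self._slices = self._make_slices()

    def _make_slices(self):
        k = self.k
        sl = {"beta": slice(0, k)}
        if self.random_effects:
            o = k
            sl["log_sd_p"] = slice(o, o + k)
            o += k
            sl["corr"] = slice(o, o + self.corr.n_free)
            o += self.corr.n_free
            sl["z"] = slice(o, o + self.n_participants * k)
            o += self.n_participants * k
            sl["log_sd_s"] = slice(o, o + 1)
            o += 1
            sl["v"] = slice(o, o + self.n_stimuli)
        return sl

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.01 * rng.standard_normal(self.n_params)
        if self.random_effects:
            theta[self._slices["log_sd_p"]] = np.log(0.2) + 0.05 * rng.standard_normal(self.k)
            theta[self._slices["log_sd_s"]] = np.log(0.2)
        return theta

    def unpack(self, theta: np.ndarray) -> dict:
        """Constrained view of one unconstrained point."""
        sl = self._slices
        out = {"beta": theta[sl["beta"]].copy()}
        if self.random_effects:
            sd_p = np.exp(theta[sl["log_sd_p"]])
            chol, _, _ = self.corr.forward(theta[sl["corr"]])
            z = theta[sl["z"]].reshape(self.n_participants, self.k)
            sd_s = float(np.exp(theta[sl["log_sd_s"]][0]))
            v = theta[sl["v"]]
            a = sd_p[:, None] * chol
            out.update(
                sd_participant=sd_p,
                corr_chol=chol,
                corr=chol @ chol.T,
                participant_effects=z @ a.T,
                sd_stimulus=sd_s,
                stimulus_intercepts=sd_s * v,
            )
        return out

    def eta(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        eta = self.x @ p["beta"]
        if self.random_effects:
            eta = eta + np.einsum(
                "nk,nk->n", self.x, p["participant_effects"][self.pidx]
            )
            eta = eta + p["stimulus_intercepts"][self.sidx]
        return eta

    def logp_grad(self, theta: np.ndarray):
        sl = self._slices
        k = self.k
        beta = theta[sl["beta"]]
        grad = np.empty_like(theta)

        if self.random_effects:
            lsp = theta[sl["log_sd_p"]]
            sd_p = np.exp(lsp)
            ycorr = theta[sl["corr"]]
            chol, zcorr, corr_logdens = self.corr.forward(ycorr)
            z = theta[sl["z"]].reshape(self.n_participants, k)
            lss = theta[sl["log_sd_s"]][0]
            sd_s = np.exp(lss)
            v = theta[sl["v"]]
            a = sd_p[:, None] * chol
            effects = z @ a.T
            eta = (
                self.x @ beta
                + np.einsum("nk,nk->n", self.x, effects[self.pidx])
                + sd_s * v[self.sidx]
            )
        else:
            eta = self.x @ beta

        # Bernoulli-probit likelihood and its eta-gradient, split by response
        eta1 = eta[self._iy1]
        eta0 = -eta[self._iy0]
        l1 = log_ndtr(eta1)
        l0 = log_ndtr(eta0)
        logp = float(l1.sum() + l0.sum())
        w = self._wbuf
        w[self._iy1] = np.exp(-0.5 * eta1 * eta1 - _LOG_SQRT_2PI - l1)
        w[self._iy0] = -np.exp(-0.5 * eta0 * eta0 - _LOG_SQRT_2PI - l0)

        # fixed-effect prior
        logp += float(-0.5 * ((beta / self.beta_scale) ** 2).sum())
        grad[sl["beta"]] = self.x.T @ w - beta / self.beta_scale**2

        if not self.random_effects:
            return logp, grad

        tau = self.priors.re_sd_scale
        # participant block
        m = np.empty((self.n_participants, k))
        for j in range(k):
            m[:, j] = np.bincount(
                self.pidx, weights=w * self.x[:, j], minlength=self.n_participants
            )
        g_a = m.T @ z
        logp += float(-0.5 * (z * z).sum())
        grad[sl["z"]] = (m @ a - z).ravel()
        g_sd = np.einsum("km,km->k", g_a, chol)
        logp += float((-0.5 * sd_p**2 / tau**2 + lsp).sum())
        grad[sl["log_sd_p"]] = g_sd * sd_p - sd_p**2 / tau**2 + 1.0
        logp += corr_logdens
        grad[sl["corr"]] = self.corr.backward(ycorr, zcorr, chol, sd_p[:, None] * g_a)

        # stimulus block
        ws = np.bincount(self.sidx, weights=w, minlength=self.n_stimuli)
        logp += float(-0.5 * (v * v).sum())
        grad[sl["v"]] = sd_s * ws - v
        logp += float(-0.5 * sd_s**2 / tau**2 + lss)
        grad[sl["log_sd_s"]] = sd_s * float(ws @ v) - sd_s**2 / tau**2 + 1.0
        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]
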