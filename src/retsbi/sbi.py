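"""Multi-round simulation-based posterior estimation.

The engine trains a conditional mixture-density network (MDN) on pairs of
parameters and summary statistics: in round 1 parameters are drawn from a
truncated-normal prior, in later rounds from the current (truncated)
posterior estimate, with importance weights ``p(theta)/p_tilde(theta)``
keeping the procedure Bayesian.  Samples are additionally weighted by a
product Gaussian kernel over the summary vector whose first dimension (the
trace discrepancy) has an adaptive centre and bandwidth: the round's minimum
sampled value and the spread up to its 20th percentile.  After training, the
network is conditioned at the boundary target ``[min d1, 0, ..., 0]`` and
the resulting Gaussian mixture is truncated to the prior box.

The MDN is a small tanh MLP with a Gaussian-mixture head (Cholesky-of-
covariance parameterisation), trained full-batch with Adam on the weighted
negative log-likelihood.  Gradients are computed by hand-written
backpropagation (checked against numerical differentiation in the test
suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "TruncatedNormalPrior",
    "GaussianMixture",
    "KernelSpec",
    "RoundRecord",
    "MDN",
    "normalize_params",
    "denormalize_params",
    "sample_truncated",
    "kernel_update",
    "kernel_weights",
    "train_mdn",
    "evaluate_posterior",
    "run_inference",
]


# ---------------------------------------------------------------------------
# Parameter-space utilities
# ---------------------------------------------------------------------------


def normalize_params(theta: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Affine map of physical parameters to the unit box given ``bounds``
    of shape (d, 2).  Raises if any value falls outside its bounds."""
    was_1d = np.asarray(theta).ndim == 1
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    bounds = np.asarray(bounds, dtype=float)
    a, b = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    if np.any(theta < a - 1e-12) or np.any(theta > b + 1e-12):
        raise ValueError("parameter outside bounds")
    out = (theta - a) / (b - a)
    return out[0] if was_1d else out


def denormalize_params(u: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    a, b = bounds[:, 0], bounds[:, 1]
    return a + u * (b - a)


# ---------------------------------------------------------------------------
# Truncated normal prior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """Independent truncated normal over a box.

    ``mean``/``std`` are per-dimension; ``box`` has shape (d, 2) and may use
    infinities.  The default std of 0.3 matches a unit-normalised parameter
    space.
    """

    mean: np.ndarray
    std: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(self, "std", np.atleast_1d(np.asarray(self.std, float)))
        object.__setattr__(self, "box", np.atleast_2d(np.asarray(self.box, float)))
        if np.any(self.std <= 0):
            raise ValueError("std must be > 0")
        if self.box.shape != (self.dim, 2):
            raise ValueError("box must have shape (d, 2)")

    @property
    def dim(self) -> int:
        return len(self.mean)

    @classmethod
    def unit_box(cls, dim: int, mean=0.5, std=0.3) -> "TruncatedNormalPrior":
        return cls(np.full(dim, mean), np.full(dim, std),
                   np.tile([0.0, 1.0], (dim, 1)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_truncated(self, n, rng)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        a = (self.box[:, 0] - self.mean) / self.std
        b = (self.box[:, 1] - self.mean) / self.std
        z = (theta - self.mean) / self.std
        lp = norm.logpdf(z) - np.log(self.std) \
            - np.log(norm.cdf(b) - norm.cdf(a))
        lp = lp.sum(axis=1)
        inside = np.all((theta >= self.box[:, 0]) & (theta <= self.box[:, 1]),
                        axis=1)
        return np.where(inside, lp, -np.inf)

    def var(self) -> np.ndarray:
        """Per-dimension variance of the truncated distribution."""
        a = (self.box[:, 0] - self.mean) / self.std
        b = (self.box[:, 1] - self.mean) / self.std
        z = norm.cdf(b) - norm.cdf(a)
        pa, pb = norm.pdf(a), norm.pdf(b)
        # standard truncated-normal moments (guard infinite bounds)
        ta = np.where(np.isfinite(a), a * pa, 0.0)
        tb = np.where(np.isfinite(b), b * pb, 0.0)
        m1 = (pa - pb) / z
        v = 1.0 + (ta - tb) / z - m1 ** 2
        return v * self.std ** 2


def sample_truncated(prior: TruncatedNormalPrior, n: int,
                     rng: np.random.Generator,
                     min_acceptance: float = 1e-4) -> np.ndarray:
    """Rejection sampling: draw from the untruncated normal and resample
    anything outside the box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((n, prior.dim))
    filled = 0
    drawn = 0
    while filled < n:
        m = max(n - filled, 64)
        cand = rng.normal(prior.mean, prior.std, size=(m, prior.dim))
        drawn += m
        ok = np.all((cand >= prior.box[:, 0]) & (cand <= prior.box[:, 1]), axis=1)
        good = cand[ok]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
        if drawn > 1000 and filled / drawn < min_acceptance:
            raise RuntimeError(
                "truncated-normal acceptance rate below 1e-4; "
                "check that the prior mean lies inside the box")
    return out


# ---------------------------------------------------------------------------
# Gaussian mixture (the posterior representation)
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixture:
    """Mixture of full-covariance Gaussians, optionally truncated to a box.

    When ``box`` is set, sampling rejects draws outside it and ``log_prob``
    subtracts a Monte-Carlo estimate of the log truncated mass (estimated
    once with a fixed internal seed, so densities are reproducible).
    """

    weights: np.ndarray
    means: np.ndarray          # (K, d)
    covs: np.ndarray           # (K, d, d)
    box: np.ndarray | None = None
    _log_mass: float | None = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covs = np.asarray(self.covs, float)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def truncated(self, box: np.ndarray) -> "GaussianMixture":
        return GaussianMixture(self.weights.copy(), self.means.copy(),
                               self.covs.copy(), box=np.asarray(box, float))

    def _sample_raw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ks = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.dim))
        for k in range(self.n_components):
            m = int(np.sum(ks == k))
            if m:
                out[ks == k] = rng.multivariate_normal(
                    self.means[k], self.covs[k], size=m,
                    method="cholesky")
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.box is None:
            return self._sample_raw(n, rng)
        out = np.empty((n, self.dim))
        filled = 0
        drawn = 0
        while filled < n:
            cand = self._sample_raw(max(n - filled, 64), rng)
            drawn += len(cand)
            ok = np.all((cand >= self.box[:, 0]) & (cand <= self.box[:, 1]),
                        axis=1)
            good = cand[ok]
            take = min(len(good), n - filled)
            out[filled:filled + take] = good[:take]
            filled += take
            if drawn > 5000 and filled == 0:
                raise RuntimeError("truncated posterior mass < 1e-6 in box")
        return out

    def log_mass(self) -> float:
        """log of the mixture mass inside the truncation box (MC, fixed seed)."""
        if self.box is None:
            return 0.0
        if self._log_mass is None:
            rng = np.random.default_rng(1234567)
            cand = self._sample_raw(20000, rng)
            frac = float(np.mean(np.all(
                (cand >= self.box[:, 0]) & (cand <= self.box[:, 1]), axis=1)))
            if frac < 1e-6:
                raise RuntimeError("truncated posterior mass < 1e-6 in box")
            self._log_mass = math.log(frac)
        return self._log_mass

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        n = len(theta)
        comp = np.empty((n, self.n_components))
        for k in range(self.n_components):
            d = self.dim
            chol = np.linalg.cholesky(self.covs[k])
            z = np.linalg.solve(chol, (theta - self.means[k]).T).T
            comp[:, k] = (-0.5 * np.sum(z ** 2, axis=1)
                          - np.sum(np.log(np.diag(chol)))
                          - 0.5 * d * math.log(2 * math.pi)
                          + math.log(self.weights[k]))
        from scipy.special import logsumexp
        lp = logsumexp(comp, axis=1)
        if self.box is not None:
            inside = np.all((theta >= self.box[:, 0]) &
                            (theta <= self.box[:, 1]), axis=1)
            lp = np.where(inside, lp - self.log_mass(), -np.inf)
        return lp

    def marginal_interval(self, dim: int, level: float = 0.9,
                          n_mc: int = 20000, seed: int = 0):
        """Equal-tailed marginal credible interval from (truncated) samples."""
        rng = np.random.default_rng(seed)
        s = self.sample(n_mc, rng)[:, dim]
        lo = (1.0 - level) / 2
        return float(np.quantile(s, lo)), float(np.quantile(s, 1.0 - lo))

    def marginal_var(self, n_mc: int = 20000, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.sample(n_mc, rng).var(axis=0)


# ---------------------------------------------------------------------------
# Summary kernel
# ---------------------------------------------------------------------------


@dataclass
class KernelSpec:
    """Product Gaussian kernel over the summary vector.

    Dimension 0 (the trace discrepancy) is centred at ``mu0`` with adaptive
    bandwidth ``sigma0``; all other dimensions use zero-centred kernels of
    bandwidth ``sigma_rest`` (default 0.25)."""

    mu0: float = 0.0
    sigma0: float = 0.25
    sigma_rest: float = 0.25
    sigma_floor: float = 1e-3

    def __post_init__(self):
        self.sigma0 = max(self.sigma0, self.sigma_floor)


def kernel_update(summaries: np.ndarray, valid: np.ndarray | None = None,
                  sigma_rest: float = 0.25) -> KernelSpec:
    """Adaptive kernel for the round: centre at the round's minimum sampled
    trace discrepancy, bandwidth the 20th-percentile spread above it."""
    x = np.atleast_2d(np.asarray(summaries, float))
    if valid is not None:
        x = x[np.asarray(valid, bool)]
    if len(x) < 5:
        raise ValueError("need at least 5 valid summaries for kernel update")
    d1 = x[:, 0]
    mu = float(np.min(d1))
    q20 = float(np.percentile(d1, 20))
    return KernelSpec(mu0=mu, sigma0=q20 - mu, sigma_rest=sigma_rest)


def kernel_weights(summaries: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """K(x) in (0, 1]: product of the per-dimension Gaussian kernels."""
    x = np.atleast_2d(np.asarray(summaries, float))
    k0 = np.exp(-0.5 * ((x[:, 0] - spec.mu0) / spec.sigma0) ** 2)
    if x.shape[1] > 1:
        krest = np.exp(-0.5 * (x[:, 1:] / spec.sigma_rest) ** 2).prod(axis=1)
    else:
        krest = 1.0
    return k0 * krest


# ---------------------------------------------------------------------------
# Mixture-density network
# ---------------------------------------------------------------------------


def _head_slices(k: int, d: int):
    q = d * (d - 1) // 2
    n_logit = k
    n_mean = k * d
    n_ldiag = k * d
    n_off = k * q
    i0 = 0
    sl_logit = slice(i0, i0 + n_logit); i0 += n_logit
    sl_mean = slice(i0, i0 + n_mean); i0 += n_mean
    sl_ldiag = slice(i0, i0 + n_ldiag); i0 += n_ldiag
    sl_off = slice(i0, i0 + n_off); i0 += n_off
    return sl_logit, sl_mean, sl_ldiag, sl_off, i0


class MDN:
    """Conditional Gaussian-mixture density ``q_phi(theta | x)``.

    A tanh MLP maps the (standardised) summary vector to mixture logits,
    component means and Cholesky factors of the component covariances.
    ``n_components=1`` is the configuration used for cell inference;
    stimulus search uses 2.  With ``use_summaries=False`` the head ignores
    its input and the model reduces to an unconditional mixture.
    """

    def __init__(self, x_dim: int, theta_dim: int, n_components: int = 1,
                 hidden: Sequence[int] = (50, 50), use_summaries: bool = True,
                 seed: int = 0):
        self.x_dim = x_dim
        self.d = theta_dim
        self.K = n_components
        self.hidden = tuple(hidden)
        self.use_summaries = use_summaries
        (self.sl_logit, self.sl_mean, self.sl_ldiag, self.sl_off,
         self.out_dim) = _head_slices(self.K, self.d)
        rng = np.random.default_rng(seed)
        sizes = [x_dim, *self.hidden, self.out_dim]
        self.W = [rng.normal(0, 1.0 / math.sqrt(sizes[i]),
                             (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.W[-1] *= 0.1
        self.b = [np.zeros(s) for s in sizes[1:]]
        self.x_mean = np.zeros(x_dim)
        self.x_std = np.ones(x_dim)

    # -- parameter vector helpers -------------------------------------
    def get_flat(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.W]
                              + [b.ravel() for b in self.b])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for w in self.W:
            w[...] = flat[i:i + w.size].reshape(w.shape)
            i += w.size
        for b in self.b:
            b[...] = flat[i:i + b.size].reshape(b.shape)
            i += b.size

    def init_head(self, theta: np.ndarray, weights: np.ndarray,
                  rng: np.random.Generator) -> None:
        """Bias the head at the weighted sample moments (spread for K>1)."""
        w = np.asarray(weights, float)
        w = w / w.sum()
        mu = w @ theta
        var = w @ (theta - mu) ** 2
        sd = np.sqrt(np.maximum(var, 1e-8))
        b_out = self.b[-1]
        for k in range(self.K):
            jitter = rng.normal(0, 0.1 * sd) if self.K > 1 else 0.0
            b_out[self.sl_mean][k * self.d:(k + 1) * self.d] = mu + jitter
            b_out[self.sl_ldiag][k * self.d:(k + 1) * self.d] = np.log(sd)

    # -- forward -------------------------------------------------------
    def _features(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if not self.use_summaries:
            return np.zeros((len(x), self.x_dim))
        return (x - self.x_mean) / self.x_std

    def _forward(self, xf: np.ndarray):
        h = [xf]
        a = xf
        for i in range(len(self.W) - 1):
            a = np.tanh(a @ self.W[i] + self.b[i])
            h.append(a)
        out = a @ self.W[-1] + self.b[-1]
        return out, h

    def _mixture_params(self, out: np.ndarray):
        n = len(out)
        K, d = self.K, self.d
        logits = out[:, self.sl_logit]
        logits = logits - logits.max(axis=1, keepdims=True)
        logw = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        mu = out[:, self.sl_mean].reshape(n, K, d)
        ldiag = np.clip(out[:, self.sl_ldiag].reshape(n, K, d), -12.0, 12.0)
        off = out[:, self.sl_off].reshape(n, K, -1)
        L = np.zeros((n, K, d, d))
        ii = np.arange(d)
        L[:, :, ii, ii] = np.exp(ldiag)
        if d > 1:
            tri = np.tril_indices(d, k=-1)
            L[:, :, tri[0], tri[1]] = off
        return logw, mu, ldiag, L

    def log_prob(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        out, _ = self._forward(self._features(x))
        logw, mu, ldiag, L = self._mixture_params(out)
        return self._mixture_logpdf(np.atleast_2d(theta), logw, mu, ldiag, L)[0]

    @staticmethod
    def _mixture_logpdf(theta, logw, mu, ldiag, L):
        n, K, d = mu.shape
        u = theta[:, None, :] - mu                       # (n, K, d)
        z = np.linalg.solve(L, u[..., None])[..., 0]      # (n, K, d)
        logdet = ldiag.sum(axis=2)                        # (n, K)
        comp = (-0.5 * (z ** 2).sum(axis=2) - logdet
                - 0.5 * d * math.log(2 * math.pi))
        m = (logw + comp).max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logw + comp - m).sum(axis=1))
        gamma = np.exp(logw + comp - lse[:, None])
        return lse, (u, z, gamma)

    # -- loss and gradient ---------------------------------------------
    def loss_and_grad(self, theta: np.ndarray, x: np.ndarray,
                      weights: np.ndarray):
        """Weighted NLL ``-(1/N) sum_n c_n log q(theta_n|x_n)`` and its
        gradient with respect to the flattened network parameters."""
        n = len(theta)
        c = np.asarray(weights, float)
        xf = self._features(x)
        out, h = self._forward(xf)
        logw, mu, ldiag, L = self._mixture_params(out)
        lse, (u, z, gamma) = self._mixture_logpdf(theta, logw, mu, ldiag, L)
        loss = -float(np.sum(c * lse)) / n

        K, d = self.K, self.d
        # d log q / d head outputs
        w_soft = np.exp(logw)
        g_logit = gamma - w_soft                                   # (n, K)
        alpha = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
        g_mu = gamma[..., None] * alpha                            # (n, K, d)
        ii = np.arange(d)
        Ldiag = L[:, :, ii, ii]
        g_ldiag = gamma[..., None] * (alpha * z * Ldiag - 1.0)
        if d > 1:
            tri = np.tril_indices(d, k=-1)
            # alpha_i z_j for strict lower entries
            az = alpha[..., :, None] * z[..., None, :]             # (n,K,d,d)
            g_off = gamma[..., None] * az[:, :, tri[0], tri[1]]
        else:
            g_off = np.zeros((n, K, 0))

        g_out = np.zeros_like(out)
        g_out[:, self.sl_logit] = g_logit
        g_out[:, self.sl_mean] = g_mu.reshape(n, K * d)
        g_out[:, self.sl_ldiag] = g_ldiag.reshape(n, K * d)
        g_out[:, self.sl_off] = g_off.reshape(n, -1)
        g_out *= (-c / n)[:, None]                                 # loss grad

        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = g_out
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = h[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - h[i] ** 2)
        grad = np.concatenate([g.ravel() for g in gW]
                              + [g.ravel() for g in gb])
        return loss, grad

    # -- training -------------------------------------------------------
    def fit(self, theta: np.ndarray, x: np.ndarray, weights: np.ndarray,
            epochs: int = 1200, lr: float = 0.02, seed: int = 0,
            val_frac: float = 0.15, patience: int = 150,
            grad_clip: float = 25.0) -> list:
        """Full-batch Adam on the weighted NLL; returns the loss history.

        Samples with zero weight contribute neither loss nor gradient.  A
        random ``val_frac`` of the data is held out; training keeps the
        parameters with the best held-out loss and stops early when it has
        not improved for ``patience`` epochs.  Raises if the loss diverges.
        """
        theta = np.atleast_2d(np.asarray(theta, float))
        x = np.atleast_2d(np.asarray(x, float))
        c = np.asarray(weights, float)
        keep = c > 0
        if keep.sum() < 2:
            raise ValueError("need at least 2 positively weighted samples")
        theta, x, c = theta[keep], x[keep], c[keep]
        c = c / c.mean()

        if self.use_summaries:
            self.x_mean = x.mean(axis=0)
            self.x_std = np.maximum(x.std(axis=0), 1e-6)
        rng = np.random.default_rng(seed)
        self.init_head(theta, c / c.sum(), rng)

        n = len(theta)
        n_val = int(round(val_frac * n)) if n >= 40 else 0
        perm = rng.permutation(n)
        vi, ti = perm[:n_val], perm[n_val:]

        b1, b2, eps = 0.9, 0.999, 1e-8
        history = []
        best = [math.inf, self.get_flat()]

        def phase(flat, lr_phase, n_epochs):
            m = np.zeros_like(flat)
            v = np.zeros_like(flat)
            since_best = 0
            for ep in range(1, n_epochs + 1):
                self.set_flat(flat)
                loss, grad = self.loss_and_grad(theta[ti], x[ti], c[ti])
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"MDN training diverged at epoch {ep}: loss={loss}")
                history.append(loss)
                if n_val:
                    val, _ = self.loss_and_grad(theta[vi], x[vi], c[vi])
                else:
                    val = loss
                if val < best[0] - 1e-9:
                    best[0] = val
                    best[1] = flat.copy()
                    since_best = 0
                else:
                    since_best += 1
                    if since_best > patience:
                        break
                gn = float(np.linalg.norm(grad))
                if gn > grad_clip:
                    grad = grad * (grad_clip / gn)
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad ** 2
                mh = m / (1 - b1 ** ep)
                vh = v / (1 - b2 ** ep)
                flat = flat - lr_phase * mh / (np.sqrt(vh) + eps)

        # main phase, then a fine-tune phase restarted from the best
        # parameters at reduced step size
        phase(self.get_flat(), lr, epochs)
        phase(best[1].copy(), lr * 0.2, max(epochs // 2, 200))
        self.set_flat(best[1])
        return history

    # -- conditioning ---------------------------------------------------
    def condition(self, x_target: np.ndarray,
                  box: np.ndarray | None = None) -> GaussianMixture:
        """Evaluate the network at one summary vector; optionally truncate
        the resulting mixture to ``box``."""
        out, _ = self._forward(self._features(np.atleast_2d(x_target)))
        logw, mu, ldiag, L = self._mixture_params(out)
        covs = L[0] @ np.swapaxes(L[0], -1, -2)
        gm = GaussianMixture(np.exp(logw[0]), mu[0], covs)
        if box is not None:
            gm = gm.truncated(box)
            gm.log_mass()  # fail early on negligible mass
        return gm


# ---------------------------------------------------------------------------
# The multi-round loop
# ---------------------------------------------------------------------------


@dataclass
class RoundRecord:
    """Audit trail of one inference round."""

    round_index: int
    thetas: np.ndarray
    summaries: np.ndarray
    valid: np.ndarray
    kernel: KernelSpec
    weights: np.ndarray
    proposal: str
    x_target: np.ndarray
    seed: int


def train_mdn(thetas: np.ndarray, summaries: np.ndarray,
              weights: np.ndarray, *, n_components: int = 1,
              hidden: Sequence[int] = (50, 50), use_summaries: bool = True,
              epochs: int = 1200, lr: float = 0.02, seed: int = 0) -> MDN:
    """Train an MDN on one round's weighted (theta, summary) pairs."""
    thetas = np.atleast_2d(np.asarray(thetas, float))
    summaries = np.atleast_2d(np.asarray(summaries, float))
    if np.sum(np.asarray(weights) > 0) < 50:
        raise ValueError("need at least 50 positively weighted samples")
    net = MDN(summaries.shape[1], thetas.shape[1], n_components=n_components,
              hidden=hidden, use_summaries=use_summaries, seed=seed)
    net.fit(thetas, summaries, weights, epochs=epochs, lr=lr, seed=seed)
    return net


def evaluate_posterior(net: MDN, summaries: np.ndarray,
                       valid: np.ndarray | None = None,
                       box: np.ndarray | None = None) -> tuple:
    """Condition the trained network at the boundary target
    ``[min sampled d1, 0, ..., 0]`` and truncate to ``box``.

    Returns ``(posterior, x_target)``.
    """
    x = np.atleast_2d(np.asarray(summaries, float))
    if valid is not None:
        x = x[np.asarray(valid, bool)]
    if len(x) == 0:
        raise ValueError("no valid summaries")
    x_target = np.zeros(x.shape[1])
    x_target[0] = float(np.min(x[:, 0]))
    return net.condition(x_target, box=box), x_target


def run_inference(simulator: Callable[[np.ndarray, int], tuple],
                  prior: TruncatedNormalPrior, rounds: int,
                  n_per_round: int, seed: int, *,
                  n_components: int = 1, hidden: Sequence[int] = (50, 50),
                  epochs: int = 1200, lr: float = 0.02,
                  truncate: bool = True,
                  sigma_rest: float = 0.25) -> tuple:
    """Multi-round posterior estimation.

    ``simulator(theta, sim_seed)`` must be total: it returns
    ``(status, summary_vector)`` with status ``'ok'`` or a failure label;
    failed samples receive kernel weight zero.  Round 1 samples from the
    prior, later rounds from the truncated intermediate posterior with
    importance weights ``p/p_tilde``.  Returns ``(posterior, records)``.
    """
    master = np.random.SeedSequence(seed)
    round_seeds = master.spawn(rounds)
    proposal: GaussianMixture | None = None
    records: list[RoundRecord] = []
    posterior = None
    box = prior.box if truncate else None

    for j in range(rounds):
        ss = round_seeds[j]
        rng = np.random.default_rng(ss)
        if proposal is None:
            thetas = prior.sample(n_per_round, rng)
            prop_name = "prior"
        else:
            thetas = proposal.sample(n_per_round, rng)
            prop_name = f"posterior_round_{j - 1}"

        sim_seeds = rng.integers(0, 2 ** 31 - 1, size=n_per_round)
        summaries = None
        valid = np.zeros(n_per_round, dtype=bool)
        for i in range(n_per_round):
            status, xvec = simulator(thetas[i], int(sim_seeds[i]))
            xvec = np.asarray(xvec, float)
            if summaries is None:
                summaries = np.zeros((n_per_round, len(xvec)))
            summaries[i] = xvec
            valid[i] = (status == "ok") and np.all(np.isfinite(xvec))
        if not valid.any():
            raise RuntimeError(
                f"all samples invalid in round {j}; records dumped: "
                f"{len(records)} earlier rounds available")

        kern = kernel_update(summaries, valid, sigma_rest=sigma_rest)
        kw = kernel_weights(summaries, kern)
        kw[~valid] = 0.0
        if proposal is None:
            iw = np.ones(n_per_round)
        else:
            lp_prior = prior.log_prob(thetas)
            lp_prop = proposal.log_prob(thetas)
            iw = np.exp(lp_prior - lp_prop)
            iw[~np.isfinite(iw)] = 0.0
        weights = kw * iw

        train_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31 - 1))
        net = MDN(summaries.shape[1], prior.dim, n_components=n_components,
                  hidden=hidden, seed=train_seed)
        net.fit(thetas, summaries, weights, epochs=epochs, lr=lr,
                seed=train_seed)
        posterior, x_target = evaluate_posterior(net, summaries, valid,
                                                 box=box)
        records.append(RoundRecord(
            round_index=j, thetas=thetas, summaries=summaries, valid=valid,
            kernel=kern, weights=weights, proposal=prop_name,
            x_target=x_target, seed=int(sim_seeds[0])))
        proposal = posterior

    return posterior, records
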