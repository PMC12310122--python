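"""Minimal dense neural networks with hand-coded reverse-mode gradients.

The operator nets used here are small (a few hundred weights to a few
hundred thousand), batch sizes are tens of rows, and every gradient we need
is a straightforward chain through ``tanh`` MLPs, so the networks and their
vector-Jacobian products are implemented directly on numpy arrays.  This
keeps the training loops dependency-free and bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "ScaledMLP", "NodalReactionNet", "Adam", "softplus",
           "softplus_inv", "sigmoid"]


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv requires positive input")
    return y + np.log(-np.expm1(-y))


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class MLP:
    """Fully connected tanh network operating on row-batched inputs.

    Parameters are kept as a single flat vector (``theta``) so optimizers
    and serialization deal with one array.  ``forward`` optionally returns
    the cache needed by :meth:`vjp`.
    """

    def __init__(self, sizes: list[int], seed: int = 0,
                 final_scale: float = 0.1):
        self.sizes = list(sizes)
        rng = np.random.default_rng(seed)
        self._shapes: list[tuple[tuple[int, int], tuple[int]]] = []
        chunks = []
        n_layers = len(sizes) - 1
        for k in range(n_layers):
            fan_in, fan_out = sizes[k], sizes[k + 1]
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            if k == n_layers - 1:
                scale *= final_scale  # start close to the zero operator
            W = rng.normal(0.0, scale, size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            self._shapes.append(((fan_in, fan_out), (fan_out,)))
            chunks.extend([W.ravel(), b])
        self.theta = np.concatenate(chunks)

    # --- parameter bookkeeping -------------------------------------------
    @property
    def n_params(self) -> int:
        return self.theta.size

    def _unpack(self, theta: np.ndarray):
        params = []
        pos = 0
        for wshape, bshape in self._shapes:
            wn = wshape[0] * wshape[1]
            W = theta[pos : pos + wn].reshape(wshape)
            pos += wn
            b = theta[pos : pos + bshape[0]]
            pos += bshape[0]
            params.append((W, b))
        return params

    # --- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray, theta: np.ndarray | None = None,
                need_cache: bool = False):
        """Evaluate on (B, d_in); returns (B, d_out) [and a cache]."""
        theta = self.theta if theta is None else theta
        params = self._unpack(theta)
        squeeze = X.ndim == 1
        h = np.atleast_2d(np.asarray(X, dtype=float))
        cache = [h]
        for k, (W, b) in enumerate(params):
            z = h @ W + b
            h = np.tanh(z) if k < len(params) - 1 else z
            cache.append(h)
        out = h[0] if squeeze else h
        if need_cache:
            return out, cache
        return out

    def vjp(self, cache, dY: np.ndarray, theta: np.ndarray | None = None,
            need_param_grads: bool = True):
        """Backpropagate cotangent ``dY`` through a cached forward pass.

        Returns ``(dX, dtheta)``; ``dtheta`` is None when param grads are
        not requested (e.g. when the net is frozen and only input
        sensitivities are needed).
        """
        theta = self.theta if theta is None else theta
        params = self._unpack(theta)
        n_layers = len(params)
        grads = [None] * n_layers if need_param_grads else None
        delta = np.atleast_2d(np.asarray(dY, dtype=float))
        for k in range(n_layers - 1, -1, -1):
            W, _ = params[k]
            h_in, h_out = cache[k], cache[k + 1]
            if k < n_layers - 1:
                delta = delta * (1.0 - h_out**2)
            if need_param_grads:
                gW = h_in.T @ delta
                gb = delta.sum(axis=0)
                grads[k] = (gW, gb)
            delta = delta @ W.T
        if need_param_grads:
            flat = np.concatenate([np.concatenate([gW.ravel(), gb])
                                   for gW, gb in grads])
            return delta, flat
        return delta, None

    def jacobian(self, x: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """Analytic Jacobian d out / d in at a single input point."""
        theta = self.theta if theta is None else theta
        params = self._unpack(theta)
        h = np.asarray(x, dtype=float)
        J = np.eye(h.shape[0])
        for k, (W, b) in enumerate(params):
            z = h @ W + b
            J = J @ W
            if k < len(params) - 1:
                h = np.tanh(z)
                J = J * (1.0 - h**2)[None, :]
            else:
                h = z
        return J.T  # (d_out, d_in)


class ScaledMLP:
    """An :class:`MLP` with frozen input standardization and output scale.

    ``f(x) = s * net((x - mu) / sigma)``.  The affine wrappers are fixed at
    construction (from training-data statistics) and are not trainable;
    they make optimization insensitive to the widely different magnitudes
    of low- and high-frequency spectral coefficients.
    """

    def __init__(self, net: MLP, mu: np.ndarray | None = None,
                 sigma: np.ndarray | None = None, out_scale: float = 1.0):
        self.net = net
        d_in = net.sizes[0]
        self.mu = np.zeros(d_in) if mu is None else np.asarray(mu, float)
        self.sigma = np.ones(d_in) if sigma is None else np.asarray(sigma, float)
        self.out_scale = float(out_scale)

    @property
    def sizes(self):
        return self.net.sizes

    @property
    def theta(self) -> np.ndarray:
        return self.net.theta

    @theta.setter
    def theta(self, value: np.ndarray) -> None:
        self.net.theta = value

    def forward(self, X, theta=None, need_cache: bool = False):
        Xn = (np.asarray(X, float) - self.mu) / self.sigma
        out = self.net.forward(Xn, theta=theta, need_cache=need_cache)
        if need_cache:
            y, cache = out
            return self.out_scale * y, cache
        return self.out_scale * out

    def vjp(self, cache, dY, theta=None, need_param_grads: bool = True):
        dXn, g = self.net.vjp(cache, np.asarray(dY, float) * self.out_scale,
                              theta=theta, need_param_grads=need_param_grads)
        return dXn / self.sigma, g

    def jacobian(self, x, theta=None) -> np.ndarray:
        J = self.net.jacobian((np.asarray(x, float) - self.mu) / self.sigma,
                              theta=theta)
        return self.out_scale * J / self.sigma[None, :]

    @staticmethod
    def fit_scaling(X: np.ndarray, velocities: np.ndarray | None = None):
        """Standardization statistics from training inputs.

        Near-constant input dimensions get a floored sigma so they are not
        amplified into noise.  The output scale is the RMS data velocity.
        """
        X = np.asarray(X, float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        floor = max(1e-8, 0.05 * float(sd.mean()))
        sigma = np.maximum(sd, floor)
        if velocities is not None and velocities.size:
            out_scale = float(np.sqrt(np.mean(velocities**2))) or 1.0
        else:
            out_scale = 1.0
        return mu, sigma, out_scale


class NodalReactionNet:
    """Spectral reaction operator realized as a shared pointwise network.

    ``G(beta) = Phi^T M f((Phi beta_1, ..., Phi beta_v))`` where ``f`` is a
    small network applied independently at every node/region with the
    co-located values of the input variables as features.  Reactions in
    reaction-diffusion systems are local, so tying the weights across nodes
    builds that inductive bias in: the operator generalizes across spatial
    patterns instead of memorizing the training cohort's trajectories.
    Spatially heterogeneous kinetics are outside this function class; the
    dense spectral MLP (:class:`ScaledMLP`) remains available for that.

    The interface mirrors :class:`ScaledMLP` (forward / vjp / jacobian on
    concatenated spectral coefficient rows).
    """

    def __init__(self, net: MLP, phi: np.ndarray, phi_t_m: np.ndarray,
                 n_vars: int, mu: np.ndarray | None = None,
                 sigma: np.ndarray | None = None, out_scale: float = 1.0):
        if net.sizes[0] != n_vars or net.sizes[-1] != 1:
            raise ValueError("pointwise net must map n_vars -> 1")
        self.net = net
        self.phi = phi                # (n, P) eigenvectors
        self.phi_t_m = phi_t_m        # (P, n) projection rows (Phi^T M)
        self.n_vars = n_vars
        self.n, self.P = phi.shape
        self.mu = np.zeros(n_vars) if mu is None else np.asarray(mu, float)
        self.sigma = np.ones(n_vars) if sigma is None \
            else np.asarray(sigma, float)
        self.out_scale = float(out_scale)

    @property
    def sizes(self):
        return self.net.sizes

    @property
    def theta(self) -> np.ndarray:
        return self.net.theta

    @theta.setter
    def theta(self, value: np.ndarray) -> None:
        self.net.theta = value

    def _features(self, X: np.ndarray) -> np.ndarray:
        B = X.shape[0]
        feats = np.empty((B, self.n, self.n_vars))
        for j in range(self.n_vars):
            feats[:, :, j] = X[:, j * self.P : (j + 1) * self.P] @ self.phi.T
        return feats

    def forward(self, X, theta=None, need_cache: bool = False):
        squeeze = np.ndim(X) == 1
        X2 = np.atleast_2d(np.asarray(X, float))
        B = X2.shape[0]
        F = (self._features(X2) - self.mu) / self.sigma
        out = self.net.forward(F.reshape(B * self.n, self.n_vars),
                               theta=theta, need_cache=need_cache)
        if need_cache:
            y, cache = out
        else:
            y = out
        G = self.out_scale * (y.reshape(B, self.n) @ self.phi_t_m.T)
        G = G[0] if squeeze else G
        return (G, cache) if need_cache else G

    def vjp(self, cache, dY, theta=None, need_param_grads: bool = True):
        dY2 = np.atleast_2d(np.asarray(dY, float))
        B = dY2.shape[0]
        dnodal = self.out_scale * (dY2 @ self.phi_t_m)      # (B, n)
        dF, g = self.net.vjp(cache, dnodal.reshape(B * self.n, 1),
                             theta=theta, need_param_grads=need_param_grads)
        dF = (dF / self.sigma).reshape(B, self.n, self.n_vars)
        dX = np.empty((B, self.n_vars * self.P))
        for j in range(self.n_vars):
            dX[:, j * self.P : (j + 1) * self.P] = dF[:, :, j] @ self.phi
        return dX, g

    def jacobian(self, x, theta=None) -> np.ndarray:
        """d out / d in at one concatenated-coefficient state, (P, v*P)."""
        x = np.asarray(x, float)
        F = (self._features(x[None, :])[0] - self.mu) / self.sigma  # (n, v)
        # pointwise derivatives of f at every node
        deriv = np.empty((self.n, self.n_vars))
        for i in range(self.n):
            deriv[i] = self.net.jacobian(F[i], theta=theta)[0] / self.sigma
        J = np.empty((self.P, self.n_vars * self.P))
        for j in range(self.n_vars):
            J[:, j * self.P : (j + 1) * self.P] = \
                self.out_scale * (self.phi_t_m * deriv[:, j]) @ self.phi
        return J


class PooledScalarNet:
    """Permutation-invariant scalar read-out of a nodal field.

    ``y(beta) = h( mean_i g(u_i) )`` with ``u = Phi beta`` the nodal
    reconstruction, ``g`` a shared per-node feature map and ``h`` a small
    head.  Aggregate quantities of a field (domain means and nonlinear
    summaries) are exactly of this form, and the node-shared weights make
    the read-out generalize across spatial patterns.
    Interface mirrors :class:`ScaledMLP` for (B, P) inputs -> (B, 1).
    """

    def __init__(self, inner: MLP, head: MLP, phi: np.ndarray,
                 mu: float = 0.0, sigma: float = 1.0, out_scale: float = 1.0):
        if inner.sizes[0] != 1 or head.sizes[0] != inner.sizes[-1] \
                or head.sizes[-1] != 1:
            raise ValueError("inner must map 1 -> d and head d -> 1")
        self.inner = inner
        self.head = head
        self.phi = phi
        self.n = phi.shape[0]
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.out_scale = float(out_scale)

    @property
    def sizes(self):
        return self.inner.sizes + self.head.sizes

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.inner.theta, self.head.theta])

    @theta.setter
    def theta(self, value: np.ndarray) -> None:
        k = self.inner.theta.size
        self.inner.theta = value[:k].copy()
        self.head.theta = value[k:].copy()

    def _split(self, theta):
        if theta is None:
            return None, None
        k = self.inner.theta.size
        return theta[:k], theta[k:]

    def forward(self, X, theta=None, need_cache: bool = False):
        th_i, th_h = self._split(theta)
        X2 = np.atleast_2d(np.asarray(X, float))
        B = X2.shape[0]
        U = ((X2 @ self.phi.T) - self.mu) / self.sigma        # (B, n)
        feats, cache_i = self.inner.forward(U.reshape(B * self.n, 1),
                                            theta=th_i, need_cache=True)
        pooled = feats.reshape(B, self.n, -1).mean(axis=1)    # (B, d)
        y, cache_h = self.head.forward(pooled, theta=th_h, need_cache=True)
        out = self.out_scale * y
        if need_cache:
            return out, (cache_i, cache_h, B)
        return out

    def vjp(self, cache, dY, theta=None, need_param_grads: bool = True):
        th_i, th_h = self._split(theta)
        cache_i, cache_h, B = cache
        dpool, g_h = self.head.vjp(cache_h,
                                   np.atleast_2d(dY) * self.out_scale,
                                   theta=th_h,
                                   need_param_grads=need_param_grads)
        dfeats = np.repeat(dpool / self.n, self.n, axis=0)    # (B*n, d)
        dU, g_i = self.inner.vjp(cache_i, dfeats, theta=th_i,
                                 need_param_grads=need_param_grads)
        dX = (dU.reshape(B, self.n) / self.sigma) @ self.phi
        if need_param_grads:
            return dX, np.concatenate([g_i, g_h])
        return dX, None


class Adam:
    """Standard Adam on a flat parameter vector."""

    def __init__(self, n: int, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + self.eps)
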