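"""Intrinsic GMRF prior and logistic-binomial likelihood on the torus lattice.

The model: one latent value phi_xy per memory-probe node; neighbour
differences get a zero-mean Gaussian prior with scale sigma (an intrinsic,
translation-invariant prior, improper along the constant direction),

    log p(Phi) = -(1 / 2 sigma^2) * sum_{i~j} (phi_i - phi_j)^2 + const,

with the sum over undirected edges, each counted once.  The change-report
probability is theta_xy = logistic(phi_xy) and observed counts are
k_xy ~ Binomial(n_xy, theta_xy).  Both the log density (up to constants in
phi) and its gradient are available in closed form; the prior's negative
Hessian is (1/sigma^2) times the graph Laplacian of the torus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import expit, log_expit

from .lattice import CountLattice, TorusLattice

__all__ = [
    "GMRFSpec",
    "inv_logit",
    "log_prior",
    "log_likelihood",
    "log_posterior_and_grad",
    "build_precision",
    "laplace_approximation",
]


@dataclass(frozen=True)
class GMRFSpec:
    """Prior scale sigma on neighbour differences, in logit units.

    The study fixed sigma = 2; that calibration is tied to counting each
    undirected edge once in the prior sum.
    """

    sigma: float = 2.0

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be finite and positive, got {self.sigma!r}")


def inv_logit(phi):
    """Numerically stable logistic function 1 / (1 + exp(-phi))."""
    return expit(phi)


def _as_field(phi, lattice: TorusLattice) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.size != lattice.n_nodes:
        raise ValueError(
            f"field has {phi.size} values but lattice has {lattice.n_nodes} nodes")
    return phi.reshape(lattice.L, lattice.L)


def log_prior(phi, spec: GMRFSpec, lattice: TorusLattice) -> float:
    """Intrinsic GMRF log prior, up to an additive constant.

    Each undirected torus edge contributes -(phi_i - phi_j)^2 / (2 sigma^2);
    the wrap-around differences along both axes cover every edge exactly once.
    """
    f = _as_field(phi, lattice)
    dx = f - np.roll(f, -1, axis=0)
    dy = f - np.roll(f, -1, axis=1)
    return float(-(np.sum(dx * dx) + np.sum(dy * dy)) / (2.0 * spec.sigma**2))


def log_likelihood(phi, counts: CountLattice) -> float:
    """Binomial log likelihood sum_xy [k log theta + (n-k) log(1-theta)].

    The binomial coefficient is constant in phi and omitted.  Nodes with
    n = 0 contribute exactly zero.  Stable for extreme phi via log_expit.
    """
    f = _as_field(phi, counts.lattice)
    n, k = counts.n, counts.k
    # log(theta) = log_expit(phi), log(1-theta) = log_expit(-phi)
    terms = k * log_expit(f) + (n - k) * log_expit(-f)
    return float(terms[n > 0].sum())


def log_posterior_and_grad(phi, counts: CountLattice, spec: GMRFSpec,
                           lattice: TorusLattice):
    """Unnormalised log posterior and its gradient as a flat (L^2,) array.

    grad_i = (k_i - n_i * theta_i) - (1/sigma^2) * sum_{j~i} (phi_i - phi_j)
    """
    f = _as_field(phi, lattice)
    value = log_prior(f, spec, lattice) + log_likelihood(f, counts)
    theta = expit(f)
    lap = (4.0 * f
           - np.roll(f, 1, axis=0) - np.roll(f, -1, axis=0)
           - np.roll(f, 1, axis=1) - np.roll(f, -1, axis=1))
    grad = (counts.k - counts.n * theta) - lap / spec.sigma**2
    return value, grad.ravel()


def laplace_approximation(counts: CountLattice, spec: GMRFSpec,
                          lattice: TorusLattice, tol: float = 1e-8,
                          max_iter: int = 100):
    """Posterior mode and curvature of the log-concave posterior.

    Newton iteration on the penalised logistic objective; returns
    ``(mode, P)`` with ``P = Q + diag(n * theta * (1 - theta))`` the negative
    Hessian at the mode (sparse).  The posterior is strictly log-concave
    whenever at least one node is observed, so the mode is unique.
    """
    Q = build_precision(lattice, spec)
    n = counts.n.ravel().astype(float)
    k = counts.k.ravel().astype(float)
    if n.sum() == 0:
        raise ValueError("no observed nodes: posterior mode undefined")
    phi = np.asarray(
        np.log((k + 0.5) / (n - k + 0.5 + (n == 0))), dtype=float)
    phi = np.where(n > 0, phi, 0.0)
    for _ in range(max_iter):
        theta = expit(phi)
        grad = (k - n * theta) - Q @ phi
        w = n * theta * (1.0 - theta)
        P = (Q + sp.diags(w)).tocsc()
        step = sp.linalg.spsolve(P, grad)
        # damped Newton: halve until the objective does not decrease
        val0 = _objective(phi, Q, n, k)
        t = 1.0
        while t > 1e-4:
            cand = phi + t * step
            if _objective(cand, Q, n, k) >= val0:
                break
            t /= 2.0
        phi = phi + t * step
        if np.max(np.abs(grad)) < tol * (1.0 + np.max(np.abs(k - n))):
            break
    theta = expit(phi)
    P = (Q + sp.diags(n * theta * (1.0 - theta))).tocsr()
    return phi, P


def _objective(phi, Q, n, k):
    return float((k * log_expit(phi) + (n - k) * log_expit(-phi)).sum()
                 - 0.5 * phi @ (Q @ phi))


def build_precision(lattice: TorusLattice, spec: GMRFSpec) -> sp.csr_matrix:
    """Prior precision (1/sigma^2) * torus graph Laplacian, shape (L^2, L^2).

    Row sums are zero (rank deficiency 1: the constant field is the flat
    direction of the intrinsic prior), and phi^T Q phi == -2 log_prior(phi).
    """
    A = lattice.adjacency()
    lap = sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return (lap / spec.sigma**2).tocsr()
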