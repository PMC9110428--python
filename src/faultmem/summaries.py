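"""Posterior summaries: HDCIs, mean surfaces, difference maps, critical-trial
aggregates and marginal sensitivity curves.

All functions operate on raw draw arrays so they can be checked against
brute-force recomputation; the ``GMRFResults`` object delegates here.
Probabilities are always transformed before averaging (mean of theta draws,
not the logistic of mean phi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BoundaryType, crosses_boundary
from .lattice import TorusLattice

__all__ = [
    "hdci",
    "SummarySurface",
    "CriticalTrialSummary",
    "mean_surface",
    "difference_map",
    "boundary_mask",
    "critical_trial_aggregate",
    "critical_trial_summary",
    "critical_trial_difference",
    "marginal_sensitivity",
]


def hdci(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density credible interval of a unimodal sample.

    The shortest contiguous window of the sorted samples containing
    ``ceil(mass * N)`` of them; ties broken by the lowest lower bound.
    Requires at least 20 samples for a meaningful interval.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdci of empty sample")
    if n < 20:
        raise ValueError(f"hdci needs >= 20 samples, got {n}")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first = lowest lower bound
    return float(x[i]), float(x[i + m - 1])


@dataclass
class SummarySurface:
    """Per-node posterior mean (and optional HDCI bounds) on the lattice."""

    mean: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def to_frame(self, lattice: TorusLattice) -> pd.DataFrame:
        """Tidy table: memory_rake, probe_rake, mean[, hdci_lo, hdci_hi]."""
        L = lattice.L
        xi, yi = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        cols = {
            "memory_rake": lattice.angles[xi.ravel()],
            "probe_rake": lattice.angles[yi.ravel()],
            "mean": self.mean.ravel(),
        }
        if self.lower is not None:
            cols["hdci_lo"] = self.lower.ravel()
            cols["hdci_hi"] = self.upper.ravel()
        return pd.DataFrame(cols)


@dataclass
class CriticalTrialSummary:
    """Posterior mean and 95% HDCI of the category-crossing aggregate.

    ``draw_aggregates`` keeps the per-draw aggregate samples so that
    between-condition differences can be formed draw-by-draw.
    """

    boundary: BoundaryType
    mean: float
    hdci_lower: float
    hdci_upper: float
    draw_aggregates: np.ndarray
    condition: str | None = None


def _flat_draws(theta_draws: np.ndarray) -> np.ndarray:
    """(chains, samples, L, L) or (S, L, L) -> (S_total, L, L)."""
    t = np.asarray(theta_draws, dtype=float)
    if t.ndim == 4:
        t = t.reshape(-1, t.shape[2], t.shape[3])
    if t.ndim != 3 or t.shape[1] != t.shape[2]:
        raise ValueError("theta draws must have shape (..., L, L)")
    return t


def mean_surface(theta_draws, mass: float | None = 0.95) -> SummarySurface:
    """Per-node posterior mean of theta, with HDCIs unless ``mass`` is None."""
    t = _flat_draws(theta_draws)
    mean = t.mean(axis=0)
    if mass is None:
        return SummarySurface(mean=mean)
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for i in range(mean.shape[0]):
        for j in range(mean.shape[1]):
            lo[i, j], hi[i, j] = hdci(t[:, i, j], mass)
    return SummarySurface(mean=mean, lower=lo, upper=hi)


def difference_map(theta_draws_a, theta_draws_b, mass: float = 0.95) -> SummarySurface:
    """Mean and HDCI of theta_A - theta_B, draws paired by index.

    The two fits are independent, so the pairing is arbitrary; equal-length
    streams are paired by index after truncating to the shorter one.
    """
    a = _flat_draws(theta_draws_a)
    b = _flat_draws(theta_draws_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("difference_map requires matching lattices")
    s = min(a.shape[0], b.shape[0])
    return mean_surface(a[:s] - b[:s], mass)


def boundary_mask(lattice: TorusLattice, boundary: BoundaryType) -> np.ndarray:
    """Boolean (L, L) mask of off-diagonal nodes whose memory and probe
    angles fall on opposite sides of the named category boundary."""
    ang = lattice.angles
    mask = np.zeros((lattice.L, lattice.L), dtype=bool)
    for i, ax in enumerate(ang):
        for j, ay in enumerate(ang):
            if i != j and crosses_boundary(ax, ay, boundary):
                mask[i, j] = True
    return mask


def critical_trial_aggregate(theta_draws, lattice: TorusLattice,
                             boundary: BoundaryType,
                             weights: np.ndarray | None = None) -> np.ndarray:
    """Per-draw average of theta over boundary-crossing nodes.

    ``weights=None`` averages cells uniformly (a property of the estimated
    surface); passing the per-node trial counts gives trial-weighted
    averaging instead.
    """
    t = _flat_draws(theta_draws)
    mask = boundary_mask(lattice, boundary)
    if not mask.any():
        raise ValueError(f"no lattice nodes cross boundary {boundary}")
    if weights is None:
        return t[:, mask].mean(axis=1)
    w = np.asarray(weights, dtype=float)[mask]
    if w.sum() <= 0:
        raise ValueError("trial weights are all zero on the crossing set")
    return t[:, mask] @ (w / w.sum())


def critical_trial_summary(theta_draws, lattice: TorusLattice,
                           boundary: BoundaryType,
                           weights: np.ndarray | None = None,
                           mass: float = 0.95,
                           condition: str | None = None) -> CriticalTrialSummary:
    """Summarise the per-draw critical-trial aggregate by mean and HDCI."""
    agg = critical_trial_aggregate(theta_draws, lattice, boundary, weights)
    lo, hi = hdci(agg, mass)
    return CriticalTrialSummary(boundary=boundary, mean=float(agg.mean()),
                                hdci_lower=lo, hdci_upper=hi,
                                draw_aggregates=agg, condition=condition)


def critical_trial_difference(theta_draws_a, theta_draws_b,
                              lattice: TorusLattice, boundary: BoundaryType,
                              mass: float = 0.95):
    """Mean and HDCI of the between-condition critical-trial difference,
    formed draw-by-draw on index-paired independent streams."""
    a = critical_trial_aggregate(theta_draws_a, lattice, boundary)
    b = critical_trial_aggregate(theta_draws_b, lattice, boundary)
    s = min(a.size, b.size)
    d = a[:s] - b[:s]
    lo, hi = hdci(d, mass)
    return float(d.mean()), lo, hi


def marginal_sensitivity(theta_draws, lattice: TorusLattice,
                         axis: str = "memory", include_diagonal: bool = True,
                         mass: float = 0.95) -> pd.DataFrame:
    """Mean detection probability per rake angle on one axis, averaging the
    surface over the other axis ("all possible paired stimuli").

    Returns a tidy frame with columns angle, mean, hdci_lo, hdci_hi.  The
    same-stimulus diagonal is included by default; exclude it to average
    over change trials only.
    """
    t = _flat_draws(theta_draws)
    L = t.shape[1]
    if axis not in ("memory", "probe"):
        raise ValueError("axis must be 'memory' or 'probe'")
    other = 2 if axis == "memory" else 1
    if include_diagonal:
        curves = t.mean(axis=other)  # (S, L)
    else:
        off_diag = ~np.eye(L, dtype=bool)  # symmetric, works for both axes
        curves = np.nanmean(np.where(off_diag, t, np.nan), axis=other)
    rows = []
    for j in range(L):
        lo, hi = hdci(curves[:, j], mass)
        rows.append((lattice.angles[j], curves[:, j].mean(), lo, hi))
    return pd.DataFrame(rows, columns=["angle", "mean", "hdci_lo", "hdci_hi"])
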