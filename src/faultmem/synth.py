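"""Synthetic change-detection study generator.

Emulates the study design — three training conditions (control,
train-left/right, train-normal/reverse), ~100–118 participants each, 50
trials per participant, half change trials with a uniformly sampled probe —
on top of a known ground-truth detection surface, so that the whole pipeline
(exclusions → aggregation → GMRF fit → summaries) can be exercised and
parameter recovery measured against the generating truth.

The true surface is additive on the logit scale: a false-alarm baseline on
the no-change diagonal, a saturating psychometric ramp in circular angular
difference, cosine bumps at the four cardinal angles on either axis (the
oblique effect), condition-gated ridges where the probe is the mirror image
of the memory stimulus, and condition-gated boosts for category-boundary
crossings.  Smooth kernels keep the surface in (0, 1) by construction and
make it a fair target for GMRF smoothing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import CONDITIONS, validate_trials, write_trials
from .geometry import BoundaryType, circular_distance, mirror_of
from .lattice import TorusLattice
from .summaries import boundary_mask

__all__ = ["EffectConfig", "StudyDesign", "true_surface", "simulate_trials",
           "simulate_study"]

_CARDINALS = (0.0, 90.0, 180.0, 270.0)


def _cos_bump(dist, width):
    """Smooth unit bump: cos^2(pi d / 2w) inside |d| < w, else 0."""
    d = np.asarray(dist, dtype=float)
    out = np.where(d < width, np.cos(np.pi * d / (2.0 * width)) ** 2, 0.0)
    return out


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect structure, all amplitudes in logit units.

    Boundary boosts are nonzero even in the control condition (untrained
    observers retain some category sensitivity); training raises the boost
    for the trained distinction by 2-3 logit units, which translates to a
    boundary effect of at least 0.15 probability units averaged over the
    crossing set (the probability-scale effect saturates near the
    psychometric ceiling, so the logit amplitudes look large).
    """

    false_alarm_rate: float = 0.10
    psychometric_slope: float = 0.03      # logit units per degree
    psychometric_asymptote: float = 0.85  # ramp ceiling (probability)
    oblique_amplitude: float = 0.8
    oblique_width: float = 20.0           # degrees
    mirror_width: float = 15.0            # degrees
    mirror_amplitude: dict = field(default_factory=lambda: {
        "control": {},
        "train_left_right": {"left_right": 1.0},
        "train_normal_reverse": {"normal_reverse": 1.0},
    })
    boundary_boost: dict = field(default_factory=lambda: {
        "control": {"left_right": 0.2, "normal_reverse": 0.4},
        "train_left_right": {"left_right": 2.4, "normal_reverse": 0.4},
        "train_normal_reverse": {"left_right": 0.2, "normal_reverse": 3.0},
    })
    participant_heterogeneity_sd: float = 0.5

    def __post_init__(self):
        for p in (self.false_alarm_rate, self.psychometric_asymptote):
            if not 0 < p < 1:
                raise ValueError(f"probabilities must be in (0,1), got {p}")
        if self.psychometric_asymptote <= self.false_alarm_rate:
            raise ValueError("asymptote must exceed the false-alarm rate")
        if min(self.oblique_width, self.mirror_width) <= 0:
            raise ValueError("kernel widths must be positive")
        if self.participant_heterogeneity_sd < 0:
            raise ValueError("heterogeneity SD must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Study layout and nuisance-process settings.

    Participant counts default to the study's condition sizes (100 control,
    118 train-left/right, 115 train-normal/reverse); the full-scale stimulus
    grid has 180 angles in 2-degree steps.  Contamination rates are sized so
    that every exclusion rule fires on generated data: lag spikes on 5% of
    trials, a few seconds of lag on most trials of a small fraction of
    "laggy" participants, slow responses on 2% of trials, and 5% of
    participants responding at chance.
    """

    participants: dict = field(default_factory=lambda: {
        "control": 100, "train_left_right": 118, "train_normal_reverse": 115})
    trials_per_participant: int = 50
    p_change: float = 0.5
    lattice_L: int = 180
    lag_mean_s: float = 0.5
    lag_sd_s: float = 0.3
    rt_log_mean: float = 0.2
    rt_log_sd: float = 0.35
    lag_contamination_rate: float = 0.05   # isolated laggy trials, 3-6 s
    rt_contamination_rate: float = 0.02    # slow responses, 5.5-8 s
    laggy_participant_rate: float = 0.02   # participants laggy on ~70% of trials
    chance_responder_rate: float = 0.05

    def __post_init__(self):
        if not 0 < self.p_change < 1:
            raise ValueError("p_change must be in (0, 1)")
        if self.trials_per_participant <= 0:
            raise ValueError("trials_per_participant must be positive")
        if any(v <= 0 for v in self.participants.values()):
            raise ValueError("participant counts must be positive")
        for r in (self.lag_contamination_rate, self.rt_contamination_rate,
                  self.laggy_participant_rate, self.chance_responder_rate):
            if not 0 <= r < 1:
                raise ValueError("contamination rates must be in [0, 1)")

    @property
    def lattice(self) -> TorusLattice:
        return TorusLattice(self.lattice_L)


def true_surface(config: EffectConfig, lattice: TorusLattice,
                 condition: str) -> np.ndarray:
    """Ground-truth detection-probability surface theta*(memory, probe).

    Diagonal (no-change) nodes equal the false-alarm rate exactly; all
    change-structure terms are gated off the diagonal.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    ang = lattice.angles
    L = lattice.L
    x = ang[:, None] * np.ones((1, L))
    y = np.ones((L, 1)) * ang[None, :]
    d = np.abs(x - y)
    delta = np.minimum(d, 360.0 - d)  # circular angular difference

    base = logit(config.false_alarm_rate)
    ramp_cap = logit(config.psychometric_asymptote) - base
    ramp = np.minimum(config.psychometric_slope * delta, ramp_cap)

    card = np.stack([np.minimum(np.abs(ang - c), 360.0 - np.abs(ang - c))
                     for c in _CARDINALS]).min(axis=0)
    bump_1d = _cos_bump(card, config.oblique_width)
    oblique = config.oblique_amplitude * (bump_1d[:, None] + bump_1d[None, :])

    ridge = np.zeros((L, L))
    for axis_label, amp in config.mirror_amplitude.get(condition, {}).items():
        axis = BoundaryType(axis_label)
        mirror_y = np.array([mirror_of(a, axis) for a in ang])
        dist = np.array([[circular_distance(y_ang, my)
                          for y_ang in ang] for my in mirror_y])
        ridge += amp * _cos_bump(dist, config.mirror_width)

    boost = np.zeros((L, L))
    for b_label, amp in config.boundary_boost.get(condition, {}).items():
        boost += amp * boundary_mask(lattice, BoundaryType(b_label))

    off_diag = ~np.eye(L, dtype=bool)
    lin = base + off_diag * (ramp + oblique + ridge + boost)
    return expit(lin)


def simulate_trials(surface: np.ndarray, design: StudyDesign, condition: str,
                    seed: int, heterogeneity_sd: float = 0.0) -> pd.DataFrame:
    """Simulate one condition's trial records from a detection surface.

    Memory angles are uniform on the grid; with probability ``p_change`` the
    probe is uniform over the remaining angles, otherwise it repeats the
    memory stimulus.  Responses are Bernoulli in the surface probability
    shifted by a per-participant logit offset; chance responders ignore the
    stimulus entirely.  Identical seeds give identical datasets.
    """
    lattice = design.lattice
    L = lattice.L
    surface = np.asarray(surface, dtype=float)
    if surface.shape != (L, L):
        raise ValueError(f"surface shape {surface.shape} != lattice ({L}, {L})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    n_p = design.participants[condition]
    T = design.trials_per_participant
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        logit_surface = logit(surface)
    for p in range(n_p):
        pid = f"{condition}_p{p:04d}"
        offset = rng.normal(0.0, heterogeneity_sd) if heterogeneity_sd > 0 else 0.0
        is_chance = rng.random() < design.chance_responder_rate
        is_laggy = rng.random() < design.laggy_participant_rate
        lag_rate = 0.7 if is_laggy else design.lag_contamination_rate
        for _ in range(T):
            xi = int(rng.integers(L))
            change = bool(rng.random() < design.p_change)
            if change:
                yi = int(rng.integers(L - 1))
                if yi >= xi:
                    yi += 1
            else:
                yi = xi
            theta = float(expit(logit_surface[xi, yi] + offset))
            if is_chance:
                theta = 0.5
            resp = "change" if rng.random() < theta else "same"
            if rng.random() < lag_rate:
                lag = rng.uniform(3.0, 6.0)
            else:
                lag = abs(rng.normal(design.lag_mean_s, design.lag_sd_s))
            if rng.random() < design.rt_contamination_rate:
                rt = rng.uniform(5.5, 8.0)
            else:
                rt = float(np.exp(rng.normal(design.rt_log_mean,
                                             design.rt_log_sd)))
            rows.append((pid, condition, lattice.angles[xi], lattice.angles[yi],
                         change, resp, rt, lag))
    df = pd.DataFrame(rows, columns=[
        "participant_id", "condition", "memory_rake", "probe_rake",
        "is_change", "response", "response_time_s", "lag_s"])
    return validate_trials(df, step=lattice.step)


def simulate_study(effects: EffectConfig, design: StudyDesign, seed: int,
                   out_dir=None):
    """Simulate all three conditions; returns (trials, surfaces) dicts.

    ``trials[condition]`` is a validated trial table and
    ``surfaces[condition]`` the generating theta* (ground truth for recovery
    tests).  If ``out_dir`` is given, writes ``trials_<condition>.csv`` per
    condition plus ``manifest.json`` with every generator parameter and the
    seed; outputs are byte-identical for a fixed seed.
    """
    lattice = design.lattice
    trials, surfaces = {}, {}
    for i, condition in enumerate(c for c in CONDITIONS
                                  if c in design.participants):
        surfaces[condition] = true_surface(effects, lattice, condition)
        trials[condition] = simulate_trials(
            surfaces[condition], design, condition,
            seed=int(seed) * 4 + i + 1,
            heterogeneity_sd=effects.participant_heterogeneity_sd)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for condition, df in trials.items():
            write_trials(df, out / f"trials_{condition}.csv")
        manifest = {"seed": int(seed), "effects": asdict(effects),
                    "design": asdict(design)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                           encoding="utf-8")
    return trials, surfaces
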