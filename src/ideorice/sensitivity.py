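"""Morris elementary-effects screening with a relative sensitivity index.

One trajectory through a k-dimensional coefficient space visits k+1 points,
each consecutive pair differing in exactly one coefficient by its step
delta. The elementary effect of a move is the raw change in each model
output channel. Per output, the relative sensitivity index (RSI) of a
coefficient is its mean absolute effect divided by the pooled maximum
absolute effect across all coefficients, so RSI lies in [0, 1] with 0 for
no influence and 1 for the dominant coefficient. Screening is replicated
with independent random sequences to attach t-based confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ideorice.crop_model import (
    DEFAULT_COEFFICIENTS,
    EnvironmentScenario,
    GeneticCoefficients,
    SimulatorConfig,
    DEFAULT_CONFIG,
    simulate,
)

__all__ = [
    "ParameterSpace",
    "MorrisTrajectory",
    "ElementaryEffectSet",
    "RSIMatrix",
    "build_trajectory",
    "elementary_effects",
    "rsi",
    "replicate_screening",
    "select_targets",
    "default_space",
    "make_simulator",
    "OUTPUT_CHANNELS",
]

OUTPUT_CHANNELS = ("biomass", "yield", "grains", "tillers", "anthesis", "maturity")

#: Documented default bounds per coefficient (physiological ranges).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "P1": (150.0, 800.0),
    "P2O": (11.0, 13.0),
    "P2R": (5.0, 200.0),
    "P5": (150.0, 550.0),
    "PHINT": (55.0, 90.0),
    "G1": (40.0, 80.0),
    "G2": (0.015, 0.035),
    "G3": (0.3, 2.0),
    "THOT": (32.0, 40.0),
    "TCLDP": (10.0, 18.0),
    "TCLDF": (8.0, 16.0),
}


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered, bounded coefficient space with per-coefficient step sizes."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    delta: np.ndarray | None = None  # defaults to a quarter of each range
    levels: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if len(self.names) != self.lower.size or self.lower.size != self.upper.size:
            raise ValueError("names/lower/upper size mismatch")
        if np.any(self.lower >= self.upper):
            raise ValueError("require lower < upper for every coefficient")
        if self.delta is None:
            object.__setattr__(self, "delta", 0.25 * (self.upper - self.lower))
        else:
            d = np.asarray(self.delta, dtype=float)
            if d.size != self.lower.size:
                raise ValueError("delta size mismatch")
            if np.any(d <= 0) or np.any(d > self.upper - self.lower):
                raise ValueError("require 0 < delta <= range")
            object.__setattr__(self, "delta", d)

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "ParameterSpace":
        idx = [self.names.index(n) for n in names]
        return ParameterSpace(
            names=tuple(names),
            lower=self.lower[idx],
            upper=self.upper[idx],
            delta=self.delta[idx],
        )


def default_space(names: Sequence[str] | None = None) -> ParameterSpace:
    names = tuple(names) if names is not None else tuple(DEFAULT_BOUNDS)
    lo = np.array([DEFAULT_BOUNDS[n][0] for n in names])
    hi = np.array([DEFAULT_BOUNDS[n][1] for n in names])
    return ParameterSpace(names=names, lower=lo, upper=hi)


@dataclass(frozen=True)
class MorrisTrajectory:
    """k+1 points; consecutive points differ in one coordinate by +/-delta."""

    points: np.ndarray                      # (k+1, k)
    moves: tuple[tuple[int, float], ...]    # (coefficient index, signed step)
    base: np.ndarray                        # the random base point x*

    @property
    def n_evaluations(self) -> int:
        """Model evaluations consumed by this trajectory (one per point)."""
        return self.points.shape[0]


def build_trajectory(space: ParameterSpace, rng: np.random.Generator) -> MorrisTrajectory:
    """Random one-at-a-time trajectory; steps reflect off the bounds.

    The base point is uniform within bounds; coefficients are perturbed in a
    random order with a random step sign, flipped whenever the chosen sign
    would leave the bounds (delta <= range guarantees one sign is feasible).
    """
    k = space.k
    # draw each coordinate's step sign first and sample the base from the
    # interval where that step fits: for delta > range/2 a mid-interval base
    # can make BOTH directions infeasible, so reflection alone is not enough
    signs = np.where(rng.uniform(size=k) < 0.5, 1.0, -1.0)
    slack = (space.upper - space.lower) - space.delta
    base = np.where(
        signs > 0,
        space.lower + rng.uniform(size=k) * slack,
        space.lower + space.delta + rng.uniform(size=k) * slack,
    )
    order = rng.permutation(k)
    points = np.empty((k + 1, k))
    points[0] = base
    current = base.copy()
    moves = []
    for step_i, j in enumerate(order):
        step = signs[j] * space.delta[j]
        if current[j] + step > space.upper[j] or current[j] + step < space.lower[j]:
            step = -step  # reflect to stay feasible (e.g. base on a bound)
        current = current.copy()
        current[j] += step
        points[step_i + 1] = current
        moves.append((int(j), float(step)))
    return MorrisTrajectory(points=points, moves=tuple(moves), base=base)


@dataclass
class ElementaryEffectSet:
    """Per-(coefficient, output) raw effects and step-normalized effects.

    ``raw[channel]`` has shape (r, k): one signed output change per completed
    trajectory and coefficient. ``normalized`` divides each effect by the
    coefficient's step size.
    """

    names: tuple[str, ...]
    channels: tuple[str, ...]
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]

    @property
    def r(self) -> int:
        return next(iter(self.raw.values())).shape[0]

    def extend(self, other: "ElementaryEffectSet") -> "ElementaryEffectSet":
        if self.names != other.names or self.channels != other.channels:
            raise ValueError("incompatible effect sets")
        return ElementaryEffectSet(
            names=self.names,
            channels=self.channels,
            raw={c: np.vstack([self.raw[c], other.raw[c]]) for c in self.channels},
            normalized={
                c: np.vstack([self.normalized[c], other.normalized[c]])
                for c in self.channels
            },
        )


def elementary_effects(
    traj: MorrisTrajectory,
    outputs: Sequence[Mapping[str, float]],
    names: Sequence[str],
    channels: Sequence[str] = OUTPUT_CHANNELS,
) -> ElementaryEffectSet:
    """Signed output change per move, for every output channel."""
    if len(outputs) != traj.points.shape[0]:
        raise ValueError(
            f"{len(outputs)} outputs for {traj.points.shape[0]} trajectory points"
        )
    k = traj.points.shape[1]
    raw = {c: np.zeros((1, k)) for c in channels}
    norm = {c: np.zeros((1, k)) for c in channels}
    for i, (j, step) in enumerate(traj.moves):
        for c in channels:
            dy = outputs[i + 1][c] - outputs[i][c]
            raw[c][0, j] = dy
            norm[c][0, j] = dy / step
    return ElementaryEffectSet(
        names=tuple(names), channels=tuple(channels), raw=raw, normalized=norm
    )


def rsi(effects: ElementaryEffectSet, channel: str) -> np.ndarray:
    """RSI per coefficient for one output channel.

    Mean absolute effect divided by the pooled maximum absolute effect over
    all coefficients for that channel; all zeros when nothing moves the
    output.
    """
    abs_eff = np.abs(effects.raw[channel])
    if abs_eff.size == 0:
        raise ValueError("empty effect set")
    pooled_max = abs_eff.max()
    if pooled_max == 0.0:
        return np.zeros(abs_eff.shape[1])
    return abs_eff.mean(axis=0) / pooled_max


@dataclass(frozen=True)
class RSIMatrix:
    """Replication summary of RSI values: coefficients x output channels."""

    names: tuple[str, ...]
    channels: tuple[str, ...]
    mean: np.ndarray       # (k, c)
    sd: np.ndarray         # (k, c)
    ci95: np.ndarray       # (k, c) half-widths
    reps: int
    replicates: np.ndarray = field(repr=False, default=None)  # (reps, k, c)

    def ci_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """95% CI bounds clipped to the admissible [0, 1] range."""
        return (
            np.clip(self.mean - self.ci95, 0.0, 1.0),
            np.clip(self.mean + self.ci95, 0.0, 1.0),
        )

    def max_rsi(self) -> np.ndarray:
        """Max over output channels of the mean RSI, per coefficient."""
        return self.mean.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            for j, channel in enumerate(self.channels):
                rows.append(
                    {
                        "coefficient": name,
                        "output": channel,
                        "mean": self.mean[i, j],
                        "sd": self.sd[i, j],
                        "ci95": self.ci95[i, j],
                    }
                )
        return pd.DataFrame(rows)


def make_simulator(
    env: EnvironmentScenario,
    base: GeneticCoefficients = DEFAULT_COEFFICIENTS,
    names: Sequence[str] | None = None,
    config: SimulatorConfig = DEFAULT_CONFIG,
) -> Callable[[np.ndarray], dict[str, float]]:
    """Adapter: coefficient vector (ordered as ``names``) -> output channels."""
    names = tuple(names) if names is not None else tuple(DEFAULT_BOUNDS)

    def run(vector: np.ndarray) -> dict[str, float]:
        coeffs = base.with_values(names, vector)
        return simulate(coeffs, env, config).channels()

    return run


def screen_once(
    space: ParameterSpace,
    simulator: Callable[[np.ndarray], Mapping[str, float]],
    r: int,
    rng: np.random.Generator,
    channels: Sequence[str] = OUTPUT_CHANNELS,
) -> ElementaryEffectSet:
    """r trajectories -> pooled elementary-effect set (n = r per pair)."""
    combined: ElementaryEffectSet | None = None
    for _ in range(r):
        traj = build_trajectory(space, rng)
        outputs = [simulator(p) for p in traj.points]
        eff = elementary_effects(traj, outputs, space.names, channels)
        combined = eff if combined is None else combined.extend(eff)
    return combined


def replicate_screening(
    space: ParameterSpace,
    simulator: Callable[[np.ndarray], Mapping[str, float]],
    r: int = 10,
    reps: int = 20,
    seed: int = 0,
    channels: Sequence[str] = OUTPUT_CHANNELS,
) -> RSIMatrix:
    """Replicated Morris screening with t-based 95% confidence intervals.

    Each replicate runs ``r`` independent trajectories with its own random
    sequence and produces one RSI matrix; mean, sd and the Student-t 95% CI
    half-width (reps - 1 df) are reported per cell.
    """
    if reps < 2:
        raise ValueError("reps >= 2 required for confidence intervals")
    channels = tuple(channels)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**63 - 1, size=reps)
    values = np.empty((reps, space.k, len(channels)))
    for rep in range(reps):
        rep_rng = np.random.default_rng(rep_seeds[rep])
        effects = screen_once(space, simulator, r, rep_rng, channels)
        for j, c in enumerate(channels):
            values[rep, :, j] = rsi(effects, c)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.975, df=reps - 1)
    ci95 = tcrit * sd / np.sqrt(reps)
    return RSIMatrix(
        names=space.names,
        channels=channels,
        mean=mean,
        sd=sd,
        ci95=ci95,
        reps=reps,
        replicates=values,
    )


def select_targets(
    matrix: RSIMatrix,
    top_n: int = 8,
    min_rsi: float = 0.05,
) -> list[str]:
    """Coefficients ranked by max-over-outputs mean RSI.

    Keeps the top ``top_n`` and always drops coefficients whose maximum RSI
    falls below ``min_rsi``. Ties break by declared coefficient order.
    """
    score = matrix.max_rsi()
    order = sorted(range(len(matrix.names)), key=lambda i: (-score[i], i))
    kept = [i for i in order if score[i] >= min_rsi][:top_n]
    return [matrix.names[i] for i in kept]
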