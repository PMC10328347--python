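"""History matching: implausibility, waves, diagnostics, region intersection.

The implausibility of a parameter point x against a target (mu_i,
sigma_i) for output i is

    I_i^2(x) = (E[f_i(x)|D] - mu_i)^2 / (sigma^2[f_i(x)|D] + sigma_i^2)
    I(x)     = max_i I_i(x),

with E and sigma^2 the emulator posterior mean and variance.  A wave
trains per-output emulators on the cumulative successful simulations,
evaluates the implausibility on a fresh Latin-hypercube test cloud,
splits it at the threshold I_th, and picks the next batch of simulation
points from the non-implausible region.  The final threshold defaults to
3 (the three-sigma rule for unimodal distributions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .emulator import EmulatorModel, fit_gpe
from .parameter_space import (
    DesignMatrix,
    ParameterDef,
    ParameterSpace,
    SimulationBatch,
    latin_hypercube,
    subsample_space_filling,
)

__all__ = [
    "Target",
    "RegionDiagnostics",
    "WaveState",
    "implausibility",
    "run_wave",
    "wave_diagnostics",
    "intersect_regions",
    "final_threshold_check",
]


@dataclass(frozen=True)
class Target:
    """Measured / literature value and standard deviation for one output."""

    name: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"target {self.name!r}: sigma must be > 0")


@dataclass
class RegionDiagnostics:
    percent_plausible: float
    mean_I: float
    max_I: float
    mean_vratio: float
    max_vratio: float

    def to_dict(self) -> dict:
        return {
            "percent_plausible": self.percent_plausible,
            "mean_I": self.mean_I,
            "max_I": self.max_I,
            "mean_vratio": self.mean_vratio,
            "max_vratio": self.max_vratio,
        }


@dataclass
class WaveState:
    """One history-matching iteration."""

    wave: int
    batch: SimulationBatch
    models: dict[str, EmulatorModel]
    test_cloud: DesignMatrix
    I: np.ndarray
    plausible: np.ndarray
    diagnostics: RegionDiagnostics
    I_th: float
    exhausted: bool = False

    @property
    def plausible_cloud(self) -> DesignMatrix:
        return DesignMatrix(
            self.test_cloud.values[self.plausible],
            self.test_cloud.space,
            kind="cloud",
        )


def implausibility(
    means: np.ndarray, sds: np.ndarray, targets: Sequence[Target]
) -> np.ndarray:
    """Max-over-outputs implausibility for each prediction row.

    ``means`` and ``sds`` have one column per target, aligned by order.
    """
    means = np.atleast_2d(np.asarray(means, float))
    sds = np.atleast_2d(np.asarray(sds, float))
    if means.shape[1] != len(targets):
        raise ValueError(
            f"{means.shape[1]} predicted outputs vs {len(targets)} targets"
        )
    mus = np.array([t.mu for t in targets])
    sig2 = np.array([t.sigma**2 for t in targets])
    I2 = (means - mus) ** 2 / (sds**2 + sig2)
    return np.sqrt(I2.max(axis=1))


def _emulate_cloud(
    models: Mapping[str, EmulatorModel],
    targets: Sequence[Target],
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    means = np.column_stack([models[t.name].predict(X).mean for t in targets])
    sds = np.column_stack([models[t.name].predict(X).sd for t in targets])
    return means, sds


def run_wave(
    prev: "WaveState | SimulationBatch",
    simulator: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    targets: Sequence[Target],
    I_th: float = 3.0,
    n_test: int = 100000,
    n_simul: int | None = None,
    seed: int = 0,
    fit_kwargs: dict | None = None,
    from_implausible: bool = False,
) -> WaveState:
    """Run one history-matching wave.

    ``prev`` is either the previous wave (its batch is extended with the
    simulations chosen at its end) or an initial :class:`SimulationBatch`.
    ``simulator`` maps design rows (N, D) to ``(outputs (N, M), success
    (N,))`` with output columns aligned to ``targets``.  New simulation
    points for the next wave are a space-filling subset of the
    non-implausible test points (set ``from_implausible=True`` for the
    literal implausible-region reading).
    """
    fit_kwargs = dict(fit_kwargs or {})
    if isinstance(prev, WaveState):
        wave_idx = prev.wave + 1
        batch = prev.batch
        space = batch.design.space
        n_simul = n_simul or max(space.D + 2, 10)
        source = prev.test_cloud.values[
            prev.plausible if not from_implausible else ~prev.plausible
        ]
        if len(source) == 0:
            warnings.warn("empty selection region; wave marks exhaustion")
            return WaveState(
                wave_idx, batch, prev.models, prev.test_cloud, prev.I,
                prev.plausible, prev.diagnostics, I_th, exhausted=True,
            )
        pick = subsample_space_filling(
            DesignMatrix(source, space, kind="cloud"),
            min(n_simul, len(source)),
            seed,
        )
        Y, ok = simulator(pick.values)
        if np.mean(~np.asarray(ok, bool)) > 0.5:
            warnings.warn("simulator failure rate above 50% in this wave")
        batch = batch.extend(
            SimulationBatch(pick, Y, batch.output_names, ok)
        )
    else:
        wave_idx = 1
        batch = prev
        space = batch.design.space
        n_simul = n_simul or max(space.D + 2, 10)
    if batch.success.sum() < space.D + 2:
        raise ValueError("fewer than D+2 successful runs available for training")

    models: dict[str, EmulatorModel] = {}
    for t in targets:
        models[t.name] = fit_gpe(
            batch.X_ok, batch.y_ok(t.name), bounds=space.bounds,
            seed=seed, **fit_kwargs,
        )
    cloud = latin_hypercube(space, n_test, seed + 1)
    means, sds = _emulate_cloud(models, targets, cloud.values)
    I = implausibility(means, sds, targets)
    plausible = I <= I_th
    diag = _diagnostics(I, sds, targets, I_th)
    exhausted = not plausible.any()
    if exhausted:
        warnings.warn("no plausible test points at this threshold")
    return WaveState(
        wave_idx, batch, models, cloud, I, plausible, diag, I_th, exhausted
    )


def _diagnostics(I, sds, targets, I_th) -> RegionDiagnostics:
    sig = np.array([t.sigma for t in targets])
    vratio = (sds / sig) ** 2
    return RegionDiagnostics(
        percent_plausible=float(100.0 * np.mean(I <= I_th)),
        mean_I=float(I.mean()),
        max_I=float(I.max()),
        mean_vratio=float(vratio.mean()),
        max_vratio=float(vratio.max()),
    )


def wave_diagnostics(
    state: WaveState, targets: Sequence[Target] | None = None
) -> RegionDiagnostics:
    """Summary statistics over a wave's evaluated test cloud.

    Without ``targets`` the diagnostics computed when the wave ran are
    returned; with them the four summaries are recomputed from scratch.
    """
    if targets is None:
        return state.diagnostics
    means, sds = _emulate_cloud(state.models, targets, state.test_cloud.values)
    I = implausibility(means, sds, targets)
    return _diagnostics(I, sds, targets, state.I_th)


def intersect_regions(
    clouds: Sequence[DesignMatrix],
    extra_lhs: DesignMatrix | None = None,
    seed: int = 0,
) -> DesignMatrix:
    """Pair plausible clouds over disjoint parameter blocks into joint rows.

    Each cloud's rows are independently shuffled (seeded) and the clouds
    are concatenated column-wise, truncated to the smallest cloud, so
    each block keeps its marginal distribution while the joint rows are
    random pairings.
    """
    all_clouds = list(clouds) + ([extra_lhs] if extra_lhs is not None else [])
    if not all_clouds:
        raise ValueError("no clouds to intersect")
    seen: set[str] = set()
    for c in all_clouds:
        names = set(c.space.names)
        if seen & names:
            raise ValueError(f"overlapping parameter blocks: {seen & names}")
        seen |= names
    n = min(len(c) for c in all_clouds)
    rng = np.random.default_rng(seed)
    cols = []
    params: list[ParameterDef] = []
    for c in all_clouds:
        perm = rng.permutation(len(c))[:n]
        cols.append(c.values[perm])
        params.extend(c.space.free)
    space = ParameterSpace(tuple(params))
    return DesignMatrix(np.hstack(cols), space, kind="cloud", seed=seed)


def final_threshold_check(I_th_schedule: Sequence[float]) -> list[float]:
    """Validate a per-wave implausibility-threshold schedule.

    The schedule must be non-increasing; if the final value is above 3,
    a final threshold of 3 is appended with a warning.
    """
    sched = [float(v) for v in I_th_schedule]
    if not sched:
        raise ValueError("empty threshold schedule")
    if any(b > a for a, b in zip(sched, sched[1:])):
        raise ValueError(f"threshold schedule must be non-increasing: {sched}")
    if sched[-1] > 3.0:
        warnings.warn("final implausibility threshold above 3; appending 3")
        sched.append(3.0)
    return sched
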