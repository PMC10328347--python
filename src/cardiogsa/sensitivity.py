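"""Sobol variance-based sensitivity analysis from emulators.

Total effects are estimated with the Jansen formulation on a Saltelli
radial design,

    S_T,i = [ (1/2N) sum (f(A) - f(AB_i))^2 ] / Var[f],

posterior-averaged over draws of each emulator.  Parameter ranking takes
the maximum total effect across outputs, normalises the maxima to sum to
one, and retains the shortest prefix whose cumulative share reaches the
threshold (default 90% of output variance).  Signed effects attach the
sign of the linear prior-mean coefficient beta_i of each emulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .emulator import EmulatorModel
from .history_matching import Target, implausibility
from .parameter_space import (
    DesignMatrix,
    ParameterSpace,
    latin_hypercube,
    saltelli_design,
)

__all__ = [
    "SobolResult",
    "RankingResult",
    "ConstraintSet",
    "total_effects",
    "rank_and_retain",
    "signed_effects",
    "screen_samples",
    "generate_plausible_base",
]


@dataclass
class SobolResult:
    """Posterior-draw mean and sd of total effects (parameters x outputs)."""

    total_effects: np.ndarray
    total_effects_sd: np.ndarray
    first_order: np.ndarray
    param_names: list[str]
    output_names: list[str]
    n_base: int
    n_draws: int
    seed: int


@dataclass
class RankingResult:
    """Parameters ordered by max-across-outputs total effect."""

    order: list[str]
    normalized_max: np.ndarray  # aligned with `order`, sums to 1
    retained: list[str]
    threshold: float


def _evaluate(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean/sd of an emulator, or exact values of a callable."""
    if isinstance(model, EmulatorModel):
        pred = model.predict(X)
        return pred.mean, pred.sd
    vals = np.asarray(model(X), float).ravel()
    return vals, np.zeros_like(vals)


def _jansen(fA, fB, fAB):
    """Jansen total and first-order estimators from block evaluations.

    fA, fB: (..., n); fAB: (..., D, n).  Returns (S_T, S1) with leading
    batch dimensions preserved.
    """
    allf = np.concatenate([fA, fB], axis=-1)
    var = allf.var(axis=-1)
    var = np.where(var > 0, var, np.inf)
    st = 0.5 * np.mean((fA[..., None, :] - fAB) ** 2, axis=-1) / var[..., None]
    s1 = 1.0 - 0.5 * np.mean((fB[..., None, :] - fAB) ** 2, axis=-1) / var[..., None]
    return st, s1


def total_effects(
    models: Sequence[EmulatorModel | Callable],
    space: ParameterSpace,
    n_base: int,
    n_draws: int = 1000,
    seed: int = 0,
    output_names: Sequence[str] | None = None,
    design: DesignMatrix | None = None,
    base_keep: np.ndarray | None = None,
) -> SobolResult:
    """Posterior-averaged Sobol total effects of every model output.

    Each model is evaluated on the same Saltelli design; ``n_draws``
    posterior samples are drawn (marginally, per design point) and the
    Jansen estimator is applied per draw, reporting the across-draw mean
    and standard deviation.  Callables are treated as exact simulators
    (zero posterior sd).  A constant output yields zero total effects
    and a warning.  ``base_keep`` (length n_base) restricts the
    estimator to base samples that passed plausibility screening.
    """
    D = space.D
    if design is None:
        design = saltelli_design(space, n_base, seed)
    n = design.n_base
    X = design.values
    M = len(models)
    names = list(output_names) if output_names else [f"y{j}" for j in range(M)]
    rng = np.random.default_rng(seed)

    ST = np.zeros((D, M))
    ST_sd = np.zeros((D, M))
    S1 = np.zeros((D, M))
    for j, model in enumerate(models):
        mean, sd = _evaluate(model, X)
        if np.ptp(mean) == 0.0 and sd.max() == 0.0:
            warnings.warn(f"output {names[j]!r} is constant; total effects set to 0")
            continue
        st_draws = []
        s1_draws = []
        ndr = n_draws if sd.max() > 0 else 1
        chunk = max(1, int(2e6 // max(len(X), 1)))
        done = 0
        while done < ndr:
            b = min(chunk, ndr - done)
            f = mean[None, :] + sd[None, :] * rng.standard_normal((b, len(X)))
            fA = f[:, :n]
            fB = f[:, n : 2 * n]
            fAB = f[:, 2 * n :].reshape(b, D, n)
            if base_keep is not None:
                keep = np.asarray(base_keep, bool)
                fA, fB, fAB = fA[:, keep], fB[:, keep], fAB[:, :, keep]
            st, s1 = _jansen(fA, fB, fAB)
            st_draws.append(st)
            s1_draws.append(s1)
            done += b
        st_all = np.vstack(st_draws)
        s1_all = np.vstack(s1_draws)
        ST[:, j] = st_all.mean(0)
        ST_sd[:, j] = st_all.std(0)
        S1[:, j] = s1_all.mean(0)
    return SobolResult(
        ST, ST_sd, S1, space.names, names, n, n_draws, seed
    )


def rank_and_retain(result: SobolResult, threshold: float = 0.90) -> RankingResult:
    """Rank parameters by max total effect and retain the 90% prefix.

    The per-parameter score is the maximum total effect across outputs
    (negative Monte-Carlo estimates clipped to zero for ranking only);
    scores are normalised to sum to one and the minimal prefix whose
    cumulative share reaches ``threshold`` is retained.  Ties keep the
    stable parameter order.
    """
    scores = np.clip(result.total_effects, 0.0, None).max(axis=1)
    total = scores.sum()
    if total <= 0:
        raise ValueError("all total effects are zero; nothing to rank")
    shares = scores / total
    order_idx = np.argsort(-shares, kind="stable")
    ordered_shares = shares[order_idx]
    cum = np.cumsum(ordered_shares)
    n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    names = [result.param_names[i] for i in order_idx]
    return RankingResult(names, ordered_shares, names[:n_keep], threshold)


def signed_effects(
    result: SobolResult, models: Sequence[EmulatorModel]
) -> np.ndarray:
    """Total effects multiplied by the sign of each emulator's beta_i."""
    D, M = result.total_effects.shape
    signed = np.array(result.total_effects, copy=True)
    for j, model in enumerate(models):
        betas = np.asarray(model.beta[1:], float)
        signed[:, j] *= np.sign(betas[:D])
    return signed


# ---------------------------------------------------------------------------
# plausibility screening of GSA samples
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Emulators + targets over a block of design columns.

    ``columns`` indexes into the screened design's free parameters; the
    emulators were trained on exactly those columns (in order).
    """

    models: Sequence[EmulatorModel]
    targets: Sequence[Target]
    columns: Sequence[int]
    name: str = ""


def _block_implausibility(design_values: np.ndarray, cset: ConstraintSet):
    Xb = design_values[:, list(cset.columns)]
    means = np.column_stack([m.predict(Xb).mean for m in cset.models])
    sds = np.column_stack([m.predict(Xb).sd for m in cset.models])
    return implausibility(means, sds, cset.targets)


def screen_samples(
    design: DesignMatrix,
    constraints: Sequence[ConstraintSet],
    I_th: float = 3.0,
) -> np.ndarray:
    """Mask of rows whose every constraint block is non-implausible."""
    cols_seen: set[int] = set()
    for c in constraints:
        block = set(int(i) for i in c.columns)
        if cols_seen & block:
            raise ValueError("constraint blocks overlap")
        cols_seen |= block
    mask = np.ones(len(design), dtype=bool)
    for c in constraints:
        mask &= _block_implausibility(design.values, c) <= I_th
    return mask


def generate_plausible_base(
    space: ParameterSpace,
    constraints: Sequence[ConstraintSet],
    n_required: int = 2000,
    I_th: float = 3.0,
    seed: int = 0,
    max_iter: int = 8,
) -> DesignMatrix:
    """Resample an LHS base until more than ``n_required`` rows pass screening.

    The base size is doubled each round; if the plausible fraction stays
    below 0.1% after ``max_iter`` rounds a ValueError reports the
    observed fractions.
    """
    n = max(n_required, 2)
    fractions = []
    for it in range(max_iter):
        base = latin_hypercube(space, n, seed + it)
        mask = screen_samples(base, constraints, I_th)
        fractions.append(mask.mean())
        if mask.sum() > n_required:
            return DesignMatrix(
                base.values[mask], space, kind="subset", seed=seed
            )
        n *= 2
    if max(fractions) < 1e-3:
        raise ValueError(
            f"plausible fraction below 0.1% after {max_iter} rounds: {fractions}"
        )
    # plausible rows exist but accumulate too slowly: pool what we have
    raise ValueError(
        f"could not accumulate {n_required} plausible rows; fractions={fractions}"
    )
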