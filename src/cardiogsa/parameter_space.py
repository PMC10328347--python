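"""Parameter tables, bounds and experimental designs.

The sampling domain for every design is a *parameter space*: an ordered
list of named parameters, each either free (with box bounds) or fixed
(with a single value).  Parameters whose bounds are only known implicitly
through a history-matching cloud carry the role ``hm-constrained`` and
must declare explicit fallback bounds.  Designs (Latin hypercube,
Saltelli and space-filling subsets) are always generated in the unit box
and rescaled to native units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

ROLES = ("free", "fixed", "data-derived", "hm-constrained")
SUBMODELS = (
    "tissue-ep",
    "ventricular-cell",
    "atrial-cell",
    "passive",
    "circulation",
    "boundary",
)

#: roles that contribute a sampling dimension
_SAMPLED_ROLES = ("free", "hm-constrained")


@dataclass(frozen=True)
class ParameterDef:
    """One named simulator parameter.

    ``bounds`` is a ``(lower, upper)`` pair for sampled parameters and a
    single value for fixed / data-derived ones.
    """

    name: str
    role: str
    bounds: tuple[float, float] | float
    unit: str = ""
    submodel: str = "circulation"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"parameter {self.name!r}: unknown role {self.role!r}")
        if self.submodel not in SUBMODELS:
            raise ValueError(
                f"parameter {self.name!r}: unknown submodel {self.submodel!r}"
            )
        if self.is_sampled:
            lo, hi = self.bounds  # type: ignore[misc]
            if not np.isfinite([lo, hi]).all() or lo >= hi:
                raise ValueError(
                    f"parameter {self.name!r}: inverted or degenerate bounds "
                    f"({lo}, {hi})"
                )
        else:
            if np.ndim(self.bounds) != 0:
                raise ValueError(
                    f"parameter {self.name!r}: fixed parameters carry exactly "
                    "one value"
                )

    @property
    def is_sampled(self) -> bool:
        return self.role in _SAMPLED_ROLES

    @property
    def value(self) -> float:
        """Fixed value (fixed / data-derived parameters only)."""
        if self.is_sampled:
            raise AttributeError(f"parameter {self.name!r} is not fixed")
        return float(self.bounds)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of parameters; the sampling box has D dimensions."""

    params: tuple[ParameterDef, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate parameter names: {sorted(dupes)}")

    @property
    def free(self) -> tuple[ParameterDef, ...]:
        return tuple(p for p in self.params if p.is_sampled)

    @property
    def D(self) -> int:
        return len(self.free)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.free]

    @property
    def fixed_values(self) -> dict[str, float]:
        return {p.name: p.value for p in self.params if not p.is_sampled}

    @property
    def bounds(self) -> np.ndarray:
        """(D, 2) array of lower/upper bounds of the sampled parameters."""
        return np.array([p.bounds for p in self.free], dtype=float)

    def subspace(self, names: Sequence[str]) -> "ParameterSpace":
        by_name = {p.name: p for p in self.params}
        return ParameterSpace(tuple(by_name[n] for n in names))

    def to_unit(self, X: np.ndarray) -> np.ndarray:
        b = self.bounds
        return (np.asarray(X, dtype=float) - b[:, 0]) / (b[:, 1] - b[:, 0])

    def from_unit(self, U: np.ndarray) -> np.ndarray:
        b = self.bounds
        return b[:, 0] + np.asarray(U, dtype=float) * (b[:, 1] - b[:, 0])

    def row_dict(self, row: np.ndarray) -> dict[str, float]:
        """Map one design row to {name: value}, including fixed values."""
        out = dict(self.fixed_values)
        out.update({n: float(v) for n, v in zip(self.names, row)})
        return out


@dataclass
class DesignMatrix:
    """N x D design in native units over a parameter space."""

    values: np.ndarray
    space: ParameterSpace
    kind: str = "lhs"
    seed: int | None = None
    n_base: int | None = None  # Saltelli designs only

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.space.D:
            raise ValueError(
                f"design has {self.values.shape[1]} columns, space has "
                f"D={self.space.D}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def unit_values(self) -> np.ndarray:
        return self.space.to_unit(self.values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.space.names).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, space: ParameterSpace, kind: str = "lhs"
    ) -> "DesignMatrix":
        df = pd.read_csv(path)
        return cls(df[space.names].to_numpy(float), space, kind=kind)


@dataclass
class SimulationBatch:
    """Design rows paired with simulator outputs and success flags.

    Rows with ``success == False`` carry undefined outputs and are
    excluded from emulator training.
    """

    design: DesignMatrix
    outputs: np.ndarray
    output_names: list[str]
    success: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        if self.success is None:
            self.success = np.ones(len(self.design), dtype=bool)
        self.success = np.asarray(self.success, dtype=bool)
        if self.outputs.shape[0] != len(self.design):
            raise ValueError("outputs and design row counts differ")
        if self.outputs.shape[1] != len(self.output_names):
            raise ValueError("outputs and output_names differ in width")

    @property
    def X_ok(self) -> np.ndarray:
        return self.design.values[self.success]

    def y_ok(self, name: str) -> np.ndarray:
        j = self.output_names.index(name)
        return self.outputs[self.success, j]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.design.values, columns=self.design.space.names)
        for j, n in enumerate(self.output_names):
            df[n] = self.outputs[:, j]
        df["success"] = self.success.astype(int)
        df.to_csv(path, index=False)

    def extend(self, other: "SimulationBatch") -> "SimulationBatch":
        if other.output_names != self.output_names:
            raise ValueError("output name mismatch")
        design = DesignMatrix(
            np.vstack([self.design.values, other.design.values]),
            self.design.space,
            kind="subset",
        )
        return SimulationBatch(
            design,
            np.vstack([self.outputs, other.outputs]),
            self.output_names,
            np.concatenate([self.success, other.success]),
        )


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

def _parse_entry(entry: dict) -> ParameterDef:
    name = entry.get("name")
    if name is None:
        raise ValueError(f"parameter entry without a name: {entry!r}")
    role = entry.get("role", "free")
    if "value" in entry and "bounds" not in entry:
        bounds: tuple[float, float] | float = float(entry["value"])
    elif "bounds" in entry:
        lo, hi = entry["bounds"]
        bounds = (float(lo), float(hi))
    else:
        raise ValueError(f"parameter {name!r}: needs 'value' or 'bounds'")
    return ParameterDef(
        name=name,
        role=role,
        bounds=bounds,
        unit=entry.get("unit", ""),
        submodel=entry.get("submodel", "circulation"),
    )


def load_parameter_table(config_path: str | Path) -> ParameterSpace:
    """Read a YAML/JSON parameter table into a :class:`ParameterSpace`.

    The file holds a list of entries (optionally under a ``parameters``
    key) with fields ``name``, ``role``, ``value`` or ``bounds``,
    ``unit`` and ``submodel``.
    """
    path = Path(config_path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = data["parameters"]
    return ParameterSpace(tuple(_parse_entry(e) for e in data))


def space_from_table(rows: Iterable[dict]) -> ParameterSpace:
    """Build a space from in-memory table rows (same schema as the file)."""
    return ParameterSpace(tuple(_parse_entry(dict(r)) for r in rows))


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def latin_hypercube(space: ParameterSpace, n: int, seed: int) -> DesignMatrix:
    """Stratified Latin hypercube design with n rows.

    Each dimension receives exactly one point per equal-width stratum of
    the unit interval before rescaling to the native bounds.
    """
    if n < 1:
        raise ValueError("latin_hypercube requires n >= 1")
    sampler = qmc.LatinHypercube(d=space.D, seed=seed)
    U = sampler.random(n)
    return DesignMatrix(space.from_unit(U), space, kind="lhs", seed=seed)


def saltelli_design(space: ParameterSpace, n_base: int, seed: int) -> DesignMatrix:
    """Saltelli radial design: blocks A, B and AB_i stacked row-wise.

    Rows ``[0:n]`` are A, ``[n:2n]`` are B and ``[(2+i)n:(3+i)n]`` is
    AB_i (= A with column i replaced by B's column i), giving
    ``n_base * (D + 2)`` rows.  The base sample is a scrambled Sobol'
    sequence in 2D dimensions, so ``n_base`` must be a power of two.
    """
    if n_base < 2:
        raise ValueError("saltelli_design requires n_base >= 2")
    if n_base & (n_base - 1):
        raise ValueError("n_base must be a power of two")
    D = space.D
    sampler = qmc.Sobol(d=2 * D, scramble=True, seed=seed)
    base = sampler.random(n_base)
    A, B = base[:, :D], base[:, D:]
    blocks = [A, B]
    for i in range(D):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    U = np.vstack(blocks)
    return DesignMatrix(
        space.from_unit(U), space, kind="saltelli", seed=seed, n_base=n_base
    )


def saltelli_blocks(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (A, B, AB) blocks from a flat Saltelli design.

    Returns A (n, D), B (n, D) and AB with shape (D, n, D).
    """
    if design.kind != "saltelli" or design.n_base is None:
        raise ValueError("not a Saltelli design")
    n, D = design.n_base, design.space.D
    V = design.values
    return V[:n], V[n : 2 * n], V[2 * n :].reshape(D, n, D)


def subsample_space_filling(
    cloud: DesignMatrix, n: int, seed: int
) -> DesignMatrix:
    """Greedy maximin (farthest point) subset of n rows of a cloud.

    Distances are measured in the unit-scaled box.  The seed selects the
    starting row; subsequent picks maximise the minimum distance to the
    already-selected set, ties broken by lowest row index.
    """
    N = len(cloud)
    if n > N:
        raise ValueError(f"requested {n} rows from a cloud of {N}")
    U = cloud.unit_values
    rng = np.random.default_rng(seed)
    selected = [int(rng.integers(N))]
    mind = np.linalg.norm(U - U[selected[0]], axis=1)
    for _ in range(1, n):
        mind[selected] = -np.inf
        nxt = int(np.argmax(mind))
        selected.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(U - U[nxt], axis=1))
    return DesignMatrix(
        cloud.values[selected], cloud.space, kind="subset", seed=seed
    )
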