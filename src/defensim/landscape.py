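"""Fitness landscapes over the (PCD, immunity) strategy grid.

For a fixed ecological regime the fitness of every strategy ``(a, r)`` on a
grid ({0} plus a uniform grid on [1-T, 1]) x (uniform on [0, E]) is the
equilibrium population size from :func:`defensim.chemostat.run_to_equilibrium`.
The landscape's optimum, its PCD-sensitivity
``1 - n(a=0, r_opt) / n(a_opt, r_opt)`` and one-parameter ecological sweeps
(viral pressure psi0, acquisition rate C, immunity cap E, replication rate
F, ...) are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .chemostat import Environment, Strategy, run_to_equilibrium

__all__ = [
    "FitnessLandscape",
    "SweepResult",
    "default_a_grid",
    "default_r_grid",
    "evaluate_landscape",
    "pcd_sensitivity",
    "classify_sensitivity",
    "moi_index",
    "sweep_parameter",
    "SENSITIVITY_THRESHOLD",
]

#: landscapes with sensitivity strictly above this are "PCD-sensitive"
SENSITIVITY_THRESHOLD = 0.1


@dataclass
class FitnessLandscape:
    """Fitness over the (a, r) strategy grid with optimum and sensitivity."""

    a_grid: np.ndarray
    r_grid: np.ndarray
    fitness: np.ndarray  # shape (len(a_grid), len(r_grid))
    env: Environment
    optimum: tuple[int, int] = (0, 0)
    sensitivity: float = float("nan")
    sensitivity_defined: bool = False

    @property
    def a_opt(self) -> float:
        return float(self.a_grid[self.optimum[0]])

    @property
    def r_opt(self) -> float:
        return float(self.r_grid[self.optimum[1]])

    @property
    def r_opt_scaled(self) -> float:
        return self.r_opt / self.env.E if self.env.E > 0 else 0.0

    @property
    def sensitive(self) -> bool:
        return classify_sensitivity(self.sensitivity)

    def to_frame(self):
        import pandas as pd

        aa, rr = np.meshgrid(self.a_grid, self.r_grid, indexing="ij")
        return pd.DataFrame(
            {
                "a": aa.ravel(),
                "r": rr.ravel(),
                "r_over_E": rr.ravel() / self.env.E if self.env.E > 0 else 0.0,
                "fitness": self.fitness.ravel(),
            }
        )

    def plot(self, ax=None):
        """Heatmap of fitness over the strategy grid with the optimum
        marked; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rr = (self.r_grid / self.env.E) if self.env.E > 0 else self.r_grid
        mesh = ax.pcolormesh(self.a_grid, rr, self.fitness.T, shading="nearest")
        ax.plot([self.a_opt], [self.r_opt_scaled], "r*", markersize=12)
        ax.set_xlabel("PCD investment a")
        ax.set_ylabel("immunity investment r / E")
        ax.set_title(f"sensitivity = {self.sensitivity:.2f}")
        plt.colorbar(mesh, ax=ax, label="fitness")
        return ax


@dataclass
class SweepResult:
    """Per-value optima and sensitivities of a one-parameter sweep."""

    param: str
    values: np.ndarray
    a_opt: np.ndarray
    r_opt: np.ndarray
    r_opt_scaled: np.ndarray
    fitness: np.ndarray
    sensitivity: np.ndarray
    landscapes: list = field(default_factory=list)

    def neighbor_differences(
        self, threshold: float = SENSITIVITY_THRESHOLD
    ) -> dict[str, np.ndarray]:
        """Successive differences of the optima restricted to neighboring
        pairs where both landscapes have sensitivity >= threshold."""
        ok = (self.sensitivity[:-1] >= threshold) & (
            self.sensitivity[1:] >= threshold
        )
        return {
            "a_opt": np.diff(self.a_opt)[ok],
            "r_opt_scaled": np.diff(self.r_opt_scaled)[ok],
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param_value": self.values,
                "a_opt": self.a_opt,
                "r_opt": self.r_opt,
                "r_opt_over_E": self.r_opt_scaled,
                "fitness": self.fitness,
                "sensitivity": self.sensitivity,
            }
        )


def default_a_grid(env: Environment, na: int = 21) -> np.ndarray:
    """{0} followed by ``na - 1`` uniform points on [1-T, 1]."""
    if na < 2:
        return np.array([0.0])
    return np.concatenate(([0.0], np.linspace(1 - env.T, 1.0, na - 1)))


def default_r_grid(env: Environment, nr: int = 21) -> np.ndarray:
    return np.linspace(0.0, env.E, nr)


def evaluate_landscape(
    env: Environment,
    a_grid: np.ndarray | None = None,
    r_grid: np.ndarray | None = None,
    **run_kwargs,
) -> FitnessLandscape:
    """Evaluate equilibrium fitness for every strategy on the grid.

    A failed cell is recorded as NaN and excluded from the arg-max; ties at
    the optimum break toward the smallest ``a``, then the smallest ``r``
    (the cheaper strategy).
    """
    a_grid = np.asarray(default_a_grid(env) if a_grid is None else a_grid, float)
    r_grid = np.asarray(default_r_grid(env) if r_grid is None else r_grid, float)
    if a_grid.size == 0 or r_grid.size == 0:
        raise ValueError("strategy grids must be nonempty")
    fit = np.full((a_grid.size, r_grid.size), np.nan)
    for i, a in enumerate(a_grid):
        for j, r in enumerate(r_grid):
            try:
                fit[i, j] = run_to_equilibrium(
                    env, Strategy(a=float(a), r=float(r)), **run_kwargs
                ).fitness
            except Exception:
                fit[i, j] = np.nan
    ls = FitnessLandscape(a_grid=a_grid, r_grid=r_grid, fitness=fit, env=env)
    ls.optimum = _argmax_cheapest(fit)
    if 0.0 in a_grid:
        ls.sensitivity = pcd_sensitivity(ls)
        ls.sensitivity_defined = np.isfinite(ls.sensitivity)
    return ls


def _argmax_cheapest(fit: np.ndarray) -> tuple[int, int]:
    """Arg-max with NaNs excluded; ties break to smallest a then r index."""
    if np.all(np.isnan(fit)):
        return (0, 0)
    best = np.nanmax(fit)
    idx = np.argwhere(fit == best)
    return tuple(int(v) for v in idx[np.lexsort((idx[:, 1], idx[:, 0]))[0]])


def pcd_sensitivity(ls: FitnessLandscape) -> float:
    """1 - fitness(a=0, r_opt) / fitness(a_opt, r_opt).

    Zero when PCD brings no benefit at the optimal immunity level; NaN
    (undefined) when the optimum has zero fitness.
    """
    zero_idx = np.nonzero(ls.a_grid == 0.0)[0]
    if zero_idx.size == 0:
        raise ValueError("a_grid must contain 0 for PCD-sensitivity")
    i_opt, j_opt = ls.optimum
    f_opt = ls.fitness[i_opt, j_opt]
    f_zero = ls.fitness[zero_idx[0], j_opt]
    if not np.isfinite(f_opt) or f_opt == 0:
        return float("nan")
    return float(1.0 - f_zero / f_opt)


def classify_sensitivity(sensitivity: float) -> bool:
    """True (PCD-sensitive) iff sensitivity strictly exceeds 0.1."""
    return bool(sensitivity > SENSITIVITY_THRESHOLD)


def moi_index(env: Environment) -> float:
    """C * psi0: multiplicity of infection of an idealized population at
    carrying capacity."""
    return env.C * env.psi0


_ENV_FIELDS = {f.name for f in fields(Environment)}


def sweep_parameter(
    base_env: Environment,
    param: str,
    values,
    a_grid: np.ndarray | None = None,
    r_grid: np.ndarray | None = None,
    keep_landscapes: bool = False,
    **run_kwargs,
) -> SweepResult:
    """Evaluate one landscape per value of an ecological parameter."""
    if param not in _ENV_FIELDS:
        raise ValueError(f"unknown Environment field: {param!r}")
    values = np.asarray(values, float)
    out = {k: np.empty(values.size) for k in
           ("a_opt", "r_opt", "r_opt_scaled", "fitness", "sensitivity")}
    kept = []
    for k, v in enumerate(values):
        env = replace(base_env, **{param: float(v) if param not in ("p0", "Q")
                                   else int(v)})
        ls = evaluate_landscape(env, a_grid, r_grid, **run_kwargs)
        out["a_opt"][k] = ls.a_opt
        out["r_opt"][k] = ls.r_opt
        out["r_opt_scaled"][k] = ls.r_opt_scaled
        out["fitness"][k] = ls.fitness[ls.optimum]
        out["sensitivity"][k] = ls.sensitivity
        if keep_landscapes:
            kept.append(ls)
    return SweepResult(param=param, values=values, landscapes=kept, **out)
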