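"""Core two-clone germinal center model: parameters, state layout, and the ODE
right-hand side.

The model tracks a single germinal center seeded by two B-cell clones that
mature through ``n`` productive somatic-hypermutation stages while competing
for survival signals from two T follicular helper (Tfh) cell families.  Each
Tfh family is split into an available pool ``G_j`` and an unavailable pool
``H_j`` (cells/ml); availability is lost at rate ``eta`` and regained at rate
``f`` per B-cell.  Clone 1 is *broadly reactive*: it is selected by both Tfh
families, each at per-Tfh-cell rate ``sigma_c``, so its total selection rate
is ``sigma_c * (G1 + G2)``.  Clone 2 is *strain-specific*: it is selected by
family 2 only, at the (larger) per-Tfh-cell rate ``sigma``, giving total rate
``sigma * G2``.

At each selection event a B-cell at stage ``i`` advances to stage ``i + 1``
(forward mutation, probability ``p``) producing ``alpha_i`` offspring, falls
back to ``i - 1`` (backward, probability ``b = 1 - p - q - d``), stays
(neutral, ``q``), or dies (deleterious, ``d``).  B-cells that have reached
stage ``n_c = ceil(2n/3)`` or later additionally differentiate into plasma
cells ``P_j``.

State layout (length ``2(n+1) + 6``)::

    [G1, H1, B1[0], ..., B1[n], P1, G2, H2, B2[0], ..., B2[n], P2]

Units: Tfh pools in cells/ml, B and plasma pools in cells, time in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "MutationKernel",
    "GCParameters",
    "SeedingConfig",
    "StateLayout",
    "Trajectory",
    "proliferation_rate",
    "plasma_threshold_stage",
    "initial_state",
    "derivative",
    "make_rhs",
]


class ParameterError(ValueError):
    """A model parameter violates its biological or mathematical constraints."""


def plasma_threshold_stage(n: int) -> int:
    """First somatic-hypermutation stage that outputs plasma cells.

    Plasma production begins after two thirds of the maturation trajectory,
    ``n_c = ceil(2n/3)``; for non-integral ``2n/3`` the next integer stage is
    used, so the last pre-plasma stage is ``n_c - 1`` (e.g. stage 33 for
    ``n = 50``).
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ParameterError(f"stage count n must be an integer, got {n!r}")
    if n < 2:
        raise ParameterError(f"stage count n must be >= 2, got {n}")
    return -((-2 * int(n)) // 3)  # ceil(2n/3)


@dataclass(frozen=True)
class MutationKernel:
    """Per-selection-event outcome probabilities.

    p : forward (productive) mutation
    q : neutral mutation (stay at the same stage)
    d_del : deleterious mutation (cell death)
    b : backward mutation, the complement ``1 - p - q - d_del``

    Baseline ``p=0.18, q=0.5, d_del=0.3`` gives ``b=0.02``.
    """

    p: float = 0.18
    q: float = 0.5
    d_del: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p", "q", "d_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"kernel.{name} must lie in [0, 1], got {v}")
        if self.b < 0.0:
            raise ParameterError(
                "mutation probabilities exceed 1: "
                f"p + q + d_del = {self.p + self.q + self.d_del}"
            )

    @property
    def b(self) -> float:
        """Backward-mutation probability (simplex complement)."""
        b = 1.0 - self.p - self.q - self.d_del
        # tolerate float cancellation at the simplex boundary
        return 0.0 if -1e-12 < b < 0.0 else b


@dataclass(frozen=True)
class GCParameters:
    """All model rates and the proliferation schedule.

    ``sigma_c`` and ``n_c`` may be left ``None`` to take their conventional
    defaults (``0.5 * sigma`` and ``ceil(2n/3)``); they are resolved to
    concrete values at construction.  Use :meth:`with_n` /
    :meth:`with_sigma_ratio` rather than :func:`dataclasses.replace` when
    changing ``n`` or the selection ratio, so the derived fields are
    re-derived.

    alpha_schedule overrides the per-stage offspring numbers; by default
    ``alpha_0 = alpha_base`` and ``alpha_i = alpha_base * (1 + (i-1)/n)`` for
    ``i >= 1``, i.e. 8 offspring per selection at the earliest stages rising
    to ~16 at the terminal stage.
    """

    n: int = 8
    sigma: float = 1.7e-4  # per-Tfh strain-specific selection rate (ml/cell/day)
    sigma_c: Optional[float] = None  # per-Tfh broadly reactive rate; default 0.5*sigma
    kappa: float = 1.2  # plasma production rate (1/day)
    d_B: float = 0.8  # B-cell death rate (1/day)
    d_G: float = 0.01  # Tfh death rate (1/day)
    eta: float = 1e-5  # Tfh loss-of-availability rate (1/cell/day)
    f: float = 1e-5  # Tfh regain-of-availability rate (1/cell/day)
    kernel: MutationKernel = field(default_factory=MutationKernel)
    alpha_base: float = 8.0  # base offspring number per selection (1/day)
    n_c: Optional[int] = None  # plasma threshold stage; default ceil(2n/3)
    alpha_schedule: Optional[tuple] = None  # explicit (n+1,) override

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or isinstance(self.n, bool):
            raise ParameterError(f"n must be an integer, got {self.n!r}")
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if self.sigma_c is None:
            object.__setattr__(self, "sigma_c", 0.5 * self.sigma)
        if self.n_c is None:
            object.__setattr__(self, "n_c", plasma_threshold_stage(self.n))
        for name in ("sigma", "sigma_c", "kappa", "d_B", "d_G", "eta", "f",
                     "alpha_base"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        if not (1 <= self.n_c <= self.n):
            raise ParameterError(
                f"n_c must lie in [1, n]; got n_c={self.n_c} with n={self.n}"
            )
        if self.alpha_schedule is not None:
            sched = tuple(float(a) for a in self.alpha_schedule)
            if len(sched) != self.n + 1:
                raise ParameterError(
                    f"alpha_schedule needs n+1={self.n + 1} entries, "
                    f"got {len(sched)}"
                )
            if any(a < 0 for a in sched):
                raise ParameterError("alpha_schedule entries must be non-negative")
            object.__setattr__(self, "alpha_schedule", sched)

    @property
    def sigma_ratio(self) -> float:
        """The broadly-reactive to strain-specific selection ratio sigma_c/sigma."""
        return self.sigma_c / self.sigma

    def proliferation_schedule(self) -> np.ndarray:
        """Offspring numbers ``alpha_0..alpha_n`` as an array of length n+1."""
        if self.alpha_schedule is not None:
            return np.asarray(self.alpha_schedule, dtype=float)
        i = np.arange(self.n + 1, dtype=float)
        alpha = self.alpha_base * (1.0 + (i - 1.0) / self.n)
        alpha[0] = self.alpha_base
        return alpha

    def with_sigma_ratio(self, ratio: float) -> "GCParameters":
        """New parameter set with ``sigma_c = ratio * sigma``."""
        if ratio <= 0:
            raise ParameterError(f"sigma_c/sigma ratio must be positive, got {ratio}")
        return replace(self, sigma_c=ratio * self.sigma)

    def with_n(self, n: int) -> "GCParameters":
        """New parameter set with a different stage count and re-derived n_c."""
        return replace(self, n=n, n_c=None, alpha_schedule=None)


@dataclass(frozen=True)
class SeedingConfig:
    """Initial germinal center seeding: founder B-cells and available Tfh."""

    B1_0: float = 50.0  # stage-0 cells of the broadly reactive clone
    B2_0: float = 50.0  # stage-0 cells of the strain-specific clone
    G1_0: float = 5000.0  # available family-1 Tfh (cells/ml)
    G2_0: float = 5000.0  # available family-2 Tfh (cells/ml)

    def __post_init__(self) -> None:
        for name in ("B1_0", "B2_0", "G1_0", "G2_0"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"seeding {name} must be non-negative, got {v}")


class StateLayout:
    """Index map for the flat state vector at a given stage count ``n``."""

    def __init__(self, n: int) -> None:
        m = n + 1
        self.n = n
        self.size = 2 * m + 6
        self.G1 = 0
        self.H1 = 1
        self.B1 = slice(2, 2 + m)
        self.P1 = 2 + m
        self.G2 = 3 + m
        self.H2 = 4 + m
        self.B2 = slice(5 + m, 5 + 2 * m)
        self.P2 = 5 + 2 * m


def proliferation_rate(i: int, params: GCParameters) -> float:
    """Offspring number ``alpha_i`` for selection events at stage ``i``.

    ``alpha_0 = alpha_1 = alpha_base`` and ``alpha_i`` rises linearly to
    ``alpha_base * (2 - 1/n)`` at the terminal stage.
    """
    if not (0 <= i <= params.n):
        raise IndexError(f"stage index {i} outside [0, {params.n}]")
    return float(params.proliferation_schedule()[i])


def initial_state(params: GCParameters, seeding: SeedingConfig) -> np.ndarray:
    """Initial state: founders at stage 0, all Tfh available, no plasma."""
    lay = StateLayout(params.n)
    y0 = np.zeros(lay.size)
    y0[lay.G1] = seeding.G1_0
    y0[lay.G2] = seeding.G2_0
    y0[lay.B1.start] = seeding.B1_0
    y0[lay.B2.start] = seeding.B2_0
    return y0


def _clone_rates(B: np.ndarray, S: float, alpha: np.ndarray, n_c: int,
                 kernel: MutationKernel, d_B: float, kappa: float):
    """Per-stage derivative of one clone's B column plus its plasma gain.

    ``S`` is the clone's total selection rate (sigma_c*(G1+G2) or sigma*G2).
    Forward flux into stage i carries ``p * alpha_i`` offspring; backward flux
    from stage i+1 into stage i carries ``b * alpha_i`` offspring; the
    terminal stage recycles onto itself with ``b * alpha_n``.  Stages at or
    past ``n_c`` lose cells to plasma differentiation at rate ``kappa`` while
    the plasma pool gains ``kappa * alpha_k`` per cell (the proliferative
    burst accompanies differentiation).
    """
    p, q, b = kernel.p, kernel.q, kernel.b
    dB = (q - 1.0) * S * B - d_B * B
    dB[1:] += p * alpha[1:] * S * B[:-1]
    dB[:-1] += b * alpha[:-1] * S * B[1:]
    dB[-1] += b * alpha[-1] * S * B[-1]
    dB[n_c:] -= kappa * B[n_c:]
    dP = kappa * float(np.dot(alpha[n_c:], B[n_c:]))
    return dB, dP


def make_rhs(params: GCParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the ODE right-hand side ``f(t, y)`` with pre-computed constants."""
    lay = StateLayout(params.n)
    alpha = params.proliferation_schedule()
    kernel = params.kernel
    n_c = params.n_c
    d_B, d_G, kappa = params.d_B, params.d_G, params.kappa
    eta, f_rate = params.eta, params.f
    sigma, sigma_c = params.sigma, params.sigma_c

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        G1, H1 = y[lay.G1], y[lay.H1]
        G2, H2 = y[lay.G2], y[lay.H2]
        B1 = y[lay.B1]
        B2 = y[lay.B2]
        sB1 = B1.sum()
        sBt = sB1 + B2.sum()

        dy = np.empty_like(y)
        # Family 1 Tfh see only clone-1 B-cells; family 2 see both clones.
        dy[lay.G1] = -d_G * G1 - eta * G1 * sB1 + f_rate * H1 * sB1
        dy[lay.H1] = -d_G * H1 + eta * G1 * sB1 - f_rate * H1 * sB1
        dy[lay.G2] = -d_G * G2 - eta * G2 * sBt + f_rate * H2 * sBt
        dy[lay.H2] = -d_G * H2 + eta * G2 * sBt - f_rate * H2 * sBt

        S1 = sigma_c * (G1 + G2)
        S2 = sigma * G2
        dy[lay.B1], dy[lay.P1] = _clone_rates(B1, S1, alpha, n_c, kernel, d_B, kappa)
        dy[lay.B2], dy[lay.P2] = _clone_rates(B2, S2, alpha, n_c, kernel, d_B, kappa)
        return dy

    return rhs


def derivative(state: np.ndarray, params: GCParameters) -> np.ndarray:
    """Time-derivative of the full state under the model equations."""
    state = np.asarray(state, dtype=float)
    lay = StateLayout(params.n)
    if state.shape != (lay.size,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({lay.size},) for n={params.n}"
        )
    return make_rhs(params)(0.0, state)


@dataclass
class Trajectory:
    """Time-ordered model states from one integration.

    ``states`` has shape ``(len(times), StateLayout(n).size)`` in the fixed
    layout documented in the module docstring.  ``termination_time`` is the
    germinal center collapse time (NaN if the B-cell population never fell
    below the termination floor within the horizon).
    """

    times: np.ndarray
    states: np.ndarray
    params: GCParameters
    termination_time: float = math.nan
    terminated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, StateLayout(self.params.n).size):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{self.times.size} time points and n={self.params.n}"
            )

    @property
    def layout(self) -> StateLayout:
        return StateLayout(self.params.n)

    @property
    def P1(self) -> np.ndarray:
        return self.states[:, self.layout.P1]

    @property
    def P2(self) -> np.ndarray:
        return self.states[:, self.layout.P2]

    def B(self, clone: int) -> np.ndarray:
        """Stage-by-time matrix of one clone's B-cells, shape (T, n+1)."""
        lay = self.layout
        return self.states[:, lay.B1 if clone == 1 else lay.B2]

    @property
    def total_B(self) -> np.ndarray:
        """Total live B-cells (both clones, all stages) at each time point."""
        return self.B(1).sum(axis=1) + self.B(2).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: columns time, variable, clone, stage, value."""
        lay = self.layout
        pieces = []
        for var, clone, col in (("G", 1, lay.G1), ("H", 1, lay.H1),
                                ("G", 2, lay.G2), ("H", 2, lay.H2),
                                ("P", 1, lay.P1), ("P", 2, lay.P2)):
            pieces.append(pd.DataFrame({
                "time": self.times, "variable": var, "clone": clone,
                "stage": pd.NA, "value": self.states[:, col],
            }))
        for clone in (1, 2):
            Bmat = self.B(clone)
            for stage in range(self.params.n + 1):
                pieces.append(pd.DataFrame({
                    "time": self.times, "variable": "B", "clone": clone,
                    "stage": stage, "value": Bmat[:, stage],
                }))
        out = pd.concat(pieces, ignore_index=True)
        out["stage"] = out["stage"].astype("Int64")
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
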