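"""Regime analyses: parameter sweeps and bisection for regime boundaries.

The qualitative outcome of a germinal center — which clone(s) end up
producing a successful plasma population — depends on the broadly reactive
selection ratio ``sigma_c/sigma``, the clonal composition of the seeding
B-cells, the number of maturation stages ``n``, and the forward-mutation
probability ``p``.  The sweeps here map those regimes; the bisection
routines locate the boundaries (e.g. the critical selection ratio above
which the broadly reactive clone succeeds) to a prescribed width.  All runs
are deterministic, so sweeps re-run bit-identically under fixed solver
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import GCParameters, ParameterError, SeedingConfig
from .simulate import OutcomeSummary, SolverSettings, integrate, summarize

__all__ = [
    "BracketError",
    "SweepResult",
    "run_once",
    "sweep_sigma_ratio",
    "find_ratio_threshold",
    "sweep_seeding",
    "find_seeding_threshold",
    "sweep_forward_mutation",
    "prepl_stage_trace",
]

DEFAULT_RATIO_GRID = np.round(np.arange(0.02, 1.0 + 1e-9, 0.02), 10)
DEFAULT_P_GRID = np.round(np.arange(0.10, 0.20 + 1e-9, 0.005), 10)


class BracketError(ValueError):
    """The bisection bracket does not straddle the regime boundary."""


@dataclass
class SweepResult:
    """One row per swept value, each produced by a full model run."""

    parameter: str
    table: pd.DataFrame
    params: GCParameters

    def to_csv(self, path) -> None:
        """Write the table preceded by '#' header lines recording the full
        parameter set, so the file alone documents the sweep conditions."""
        header = dict(swept=self.parameter, n=self.params.n,
                      n_c=self.params.n_c, sigma=self.params.sigma,
                      sigma_c=self.params.sigma_c, kappa=self.params.kappa,
                      d_B=self.params.d_B, d_G=self.params.d_G,
                      eta=self.params.eta, f=self.params.f,
                      p=self.params.kernel.p, q=self.params.kernel.q,
                      d_del=self.params.kernel.d_del,
                      alpha_base=self.params.alpha_base)
        with open(path, "w") as fh:
            for key, value in header.items():
                fh.write(f"# {key} = {value}\n")
            self.table.to_csv(fh, index=False)


def run_once(params: GCParameters, seeding: SeedingConfig | None = None,
             settings: SolverSettings | None = None) -> OutcomeSummary:
    """Integrate one configuration to termination and summarize it."""
    return summarize(integrate(params, seeding, settings))


def sweep_sigma_ratio(params: GCParameters,
                      ratios: Sequence[float] = DEFAULT_RATIO_GRID,
                      seeding: SeedingConfig | None = None,
                      settings: SolverSettings | None = None) -> SweepResult:
    """Final plasma output as ``sigma_c`` is varied relative to ``sigma``.

    One run per ratio; ``sigma`` and everything else stay at their values in
    ``params``.  Equal seeding by default.
    """
    ratios = np.asarray(list(ratios), dtype=float)
    if np.any(ratios <= 0):
        raise ParameterError("sigma_c/sigma ratios must be positive")
    if np.any(np.diff(ratios) <= 0):
        raise ParameterError("ratio grid must be strictly increasing")
    rows = []
    for r in ratios:
        s = run_once(params.with_sigma_ratio(r), seeding, settings)
        rows.append((r, s.P1_final, s.P2_final, s.clonality,
                     s.termination_time))
    table = pd.DataFrame(rows, columns=["sigma_ratio", "P1_final", "P2_final",
                                        "clonality", "termination_time"])
    return SweepResult(parameter="sigma_ratio", table=table, params=params)


def _bisect_indicator(indicator: Callable[[float], bool],
                      bracket: tuple[float, float], tol: float,
                      what: str) -> float:
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise BracketError(f"bracket must satisfy lo < hi, got {bracket}")
    ind_lo, ind_hi = indicator(lo), indicator(hi)
    if ind_lo == ind_hi:
        raise BracketError(
            f"{what} does not change across the bracket {bracket}: "
            f"indicator is {ind_lo} at both ends"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if indicator(mid) == ind_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_ratio_threshold(params: GCParameters, clone: int,
                         bracket: tuple[float, float], tol: float = 0.005,
                         seeding: SeedingConfig | None = None,
                         settings: SolverSettings | None = None,
                         success_threshold: float = 100.0) -> float:
    """Critical ``sigma_c/sigma`` at which a clone's success flips.

    Bisects the boolean indicator [final plasma of ``clone`` >
    ``success_threshold``] over ``bracket`` down to width ``tol`` and
    returns the midpoint.
    """
    if clone not in (1, 2):
        raise ValueError(f"clone must be 1 or 2, got {clone}")

    def indicator(ratio: float) -> bool:
        s = run_once(params.with_sigma_ratio(ratio), seeding, settings)
        p = s.P1_final if clone == 1 else s.P2_final
        return p > success_threshold

    return _bisect_indicator(indicator, bracket, tol,
                             what=f"clone-{clone} success")


def _seeding_at(fraction: float, total_B: float,
                tfh: SeedingConfig | None) -> SeedingConfig:
    tfh = tfh if tfh is not None else SeedingConfig()
    return SeedingConfig(B1_0=fraction * total_B,
                         B2_0=(1.0 - fraction) * total_B,
                         G1_0=tfh.G1_0, G2_0=tfh.G2_0)


def sweep_seeding(params: GCParameters, fractions: Sequence[float],
                  total_B: float = 100.0,
                  settings: SolverSettings | None = None,
                  tfh: SeedingConfig | None = None) -> SweepResult:
    """Final plasma output as the seeding split ``B1(0)/Bt(0)`` is varied.

    The total founder count is held at ``total_B`` and Tfh seeding stays
    equal (5000 cells/ml per family unless overridden via ``tfh``).
    """
    fractions = np.asarray(list(fractions), dtype=float)
    if total_B <= 0:
        raise ParameterError(f"total_B must be positive, got {total_B}")
    if np.any((fractions <= 0) | (fractions >= 1)):
        raise ParameterError("seeding fractions must lie strictly in (0, 1)")
    if np.any(np.diff(fractions) <= 0):
        raise ParameterError("fraction grid must be strictly increasing")
    rows = []
    for x in fractions:
        s = run_once(params, _seeding_at(x, total_B, tfh), settings)
        rows.append((x, s.P1_final, s.P2_final, s.clonality,
                     s.termination_time))
    table = pd.DataFrame(rows, columns=["seed_fraction", "P1_final",
                                        "P2_final", "clonality",
                                        "termination_time"])
    return SweepResult(parameter="seed_fraction", table=table, params=params)


def find_seeding_threshold(params: GCParameters, criterion: str,
                           bracket: tuple[float, float], tol: float = 0.002,
                           total_B: float = 100.0,
                           settings: SolverSettings | None = None,
                           tfh: SeedingConfig | None = None) -> float:
    """Critical seeding fraction ``B1(0)/Bt(0)`` for a regime change.

    criterion="dominance": the fraction above which the broadly reactive
    plasma output strictly exceeds the strain-specific one
    (``P1_final > P2_final``).
    criterion="clonality": the fraction at which the clonality label
    (none/monoclonal/biclonal) changes from its value at the lower bracket
    end, e.g. the biclonal-to-monoclonal boundary.
    """
    if criterion not in ("dominance", "clonality"):
        raise ValueError(
            f"criterion must be 'dominance' or 'clonality', got {criterion!r}"
        )

    def outcome(x: float) -> OutcomeSummary:
        return run_once(params, _seeding_at(x, total_B, tfh), settings)

    if criterion == "dominance":
        def indicator(x: float) -> bool:
            s = outcome(x)
            return s.P1_final > s.P2_final
    else:
        label_lo = outcome(float(bracket[0])).clonality

        def indicator(x: float) -> bool:
            return outcome(x).clonality == label_lo

    return _bisect_indicator(indicator, bracket, tol, what=criterion)


def sweep_forward_mutation(params: GCParameters,
                           p_grid: Sequence[float] = DEFAULT_P_GRID,
                           seeding: SeedingConfig | None = None,
                           settings: SolverSettings | None = None) -> SweepResult:
    """Final plasma output as the forward-mutation probability ``p`` varies.

    Neutral and deleterious probabilities stay fixed, so the backward
    probability absorbs the change; any grid point that would push it
    negative is rejected.  Records the clone imbalance ``|P1 - P2|`` used to
    locate where forward mutation most differentiates the clones.
    """
    p_grid = np.asarray(list(p_grid), dtype=float)
    if np.any(np.diff(p_grid) <= 0):
        raise ParameterError("p grid must be strictly increasing")
    kernel = params.kernel
    rows = []
    for p in p_grid:
        if 1.0 - p - kernel.q - kernel.d_del < -1e-12:
            raise ParameterError(
                f"p={p} with q={kernel.q}, d_del={kernel.d_del} gives a "
                "negative backward probability"
            )
        run_params = replace(params, kernel=replace(kernel, p=float(p)))
        s = run_once(run_params, seeding, settings)
        rows.append((p, s.P1_final, s.P2_final, abs(s.P1_final - s.P2_final),
                     s.clonality, s.termination_time))
    table = pd.DataFrame(rows, columns=["p", "P1_final", "P2_final",
                                        "abs_diff", "clonality",
                                        "termination_time"])
    return SweepResult(parameter="p", table=table, params=params)


def prepl_stage_trace(params: GCParameters,
                      seeding: SeedingConfig | None = None,
                      settings: SolverSettings | None = None) -> pd.DataFrame:
    """Time series of the last pre-plasma stage ``B_{j, n_c - 1}`` per clone.

    Also records each clone's instantaneous total selection rate
    (``sigma_c * (G1 + G2)`` for the broadly reactive clone, ``sigma * G2``
    for the strain-specific one), the x-axis against which these stage
    populations are conventionally plotted.
    """
    traj = integrate(params, seeding, settings)
    lay = traj.layout
    stage = params.n_c - 1
    G1 = traj.states[:, lay.G1]
    G2 = traj.states[:, lay.G2]
    return pd.DataFrame({
        "time": traj.times,
        "B1_pre": traj.B(1)[:, stage],
        "B2_pre": traj.B(2)[:, stage],
        "selection_broad": params.sigma_c * (G1 + G2),
        "selection_specific": params.sigma * G2,
    })
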