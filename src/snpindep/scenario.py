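"""Five-way outcome classification and the interaction-strength sweep study.

Each simulation replicate yields three p-values — marginal (Algorithm 0),
conditional (Algorithm 1) and interaction (Algorithm 2) — classified into:

* Scenario 1: all three nulls rejected;
* Scenario 2: marginal and conditional rejected, interaction not;
* Scenario 3: marginal and interaction rejected, conditional not;
* Scenario 4: only the marginal null rejected;
* Scenario 5: marginal null not rejected (the other tests are ignored);
* FAILED: a required fit was degenerate.

Rejection is strict (p < alpha); a p-value exactly at alpha does not reject.
`run_study` sweeps the interaction coefficient beta_I over a grid,
tabulating scenario proportions at each point — the power/type-I picture of
when a conditional analysis alone misleads.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regression
from .exceptions import InvalidParameterError
from .simulate import SimulationParams, simulate_dataset

__all__ = ["Scenario", "StudyConfig", "StudyResult", "classify", "run_study", "plot_study"]

DEFAULT_BETA_I_GRID = tuple(np.round(np.arange(0.3, 1.0 + 1e-9, 0.05), 2))


class Scenario(enum.Enum):
    S1 = 1
    S2 = 2
    S3 = 3
    S4 = 4
    S5 = 5
    FAILED = "FAILED"

    def __str__(self) -> str:
        return "FAILED" if self is Scenario.FAILED else f"Scenario {self.value}"


def _is_failed(p) -> bool:
    return p is None or (isinstance(p, float) and math.isnan(p))


def classify(p0, p1, pI, alpha: float) -> Scenario:
    """Map the three p-values (NaN/None = failed fit) to a Scenario.

    Total by construction: every input triple maps to exactly one label.
    Scenario 5 is decided by the marginal test alone, so failures of the
    conditional/interaction fits only matter once the marginal null is
    rejected.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")
    if _is_failed(p0):
        return Scenario.FAILED
    if not p0 < alpha:
        return Scenario.S5
    if _is_failed(p1) or _is_failed(pI):
        return Scenario.FAILED
    r1, rI = p1 < alpha, pI < alpha
    if r1 and rI:
        return Scenario.S1
    if r1:
        return Scenario.S2
    if rI:
        return Scenario.S3
    return Scenario.S4


@dataclass
class StudyConfig:
    """Sweep configuration: base generative parameters plus the beta_I grid."""

    base_params: SimulationParams = field(default_factory=SimulationParams)
    beta_I_grid: tuple = DEFAULT_BETA_I_GRID
    nsim: int = 5000
    alpha: float = 5e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must lie in (0, 1], got {self.alpha}")
        grid = tuple(float(b) for b in self.beta_I_grid)
        if not grid:
            raise InvalidParameterError("beta_I_grid must be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(grid, grid[1:])):
            raise InvalidParameterError("beta_I_grid must be strictly increasing")
        self.beta_I_grid = grid
        if int(self.nsim) != self.nsim or self.nsim < 1:
            raise InvalidParameterError(f"nsim must be a positive integer, got {self.nsim}")
        self.nsim = int(self.nsim)


_COLUMNS = ["prop_scenario1", "prop_scenario2", "prop_scenario3",
            "prop_scenario4", "prop_scenario5", "prop_failed"]
_SCEN_ORDER = [Scenario.S1, Scenario.S2, Scenario.S3, Scenario.S4,
               Scenario.S5, Scenario.FAILED]


@dataclass
class StudyResult:
    """Scenario proportions at every grid point, plus a config echo."""

    table: pd.DataFrame
    config: StudyConfig

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.table.set_index("beta_I")[_COLUMNS]


def run_study(config: StudyConfig) -> StudyResult:
    """Simulate, fit and classify `nsim` replicates at each beta_I.

    Reproducible from ``config.base_params.seed``: one root seed spawns an
    independent stream per (grid point, replicate).
    """
    base = config.base_params
    root = np.random.SeedSequence(base.seed)
    point_seeds = root.spawn(len(config.beta_I_grid))
    rows = []
    for bI, pseed in zip(config.beta_I_grid, point_seeds):
        params = SimulationParams(**{**base.to_dict(), "beta_I": bI})
        counts = {s: 0 for s in _SCEN_ORDER}
        rejects = np.zeros(3)
        for child in pseed.spawn(config.nsim):
            rng = np.random.default_rng(child)
            data = simulate_dataset(params, rng=rng)
            ps = []
            for alg in (regression.algorithm0, regression.algorithm1,
                        regression.algorithm2):
                r = alg(data)
                ps.append(np.nan if r.failed else r.p_target)
            counts[classify(*ps, config.alpha)] += 1
            for j, p in enumerate(ps):
                if not math.isnan(p) and p < config.alpha:
                    rejects[j] += 1
        row = {
            "beta_I": bI,
            "n": params.n,
            "nsim": config.nsim,
            "alpha": config.alpha,
        }
        for s, col in zip(_SCEN_ORDER, _COLUMNS):
            row[col] = counts[s] / config.nsim
        for j in range(3):
            row[f"prop_reject_alg{j}"] = rejects[j] / config.nsim
        rows.append(row)
    return StudyResult(table=pd.DataFrame(rows), config=config)


def plot_study(result: StudyResult, path, title: str | None = None) -> None:
    """One scenario-proportion curve per outcome class versus beta_I."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    if tab.empty:
        raise InvalidParameterError("empty study result")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    labels = ["Scenario 1", "Scenario 2", "Scenario 3", "Scenario 4",
              "Scenario 5", "failed"]
    marker = "o" if len(tab) == 1 else None
    for col, lab in zip(_COLUMNS, labels):
        if lab == "failed" and not tab[col].any():
            continue
        ax.plot(tab["beta_I"], tab[col], label=lab, marker=marker or ".")
    ax.set_xlabel(r"interaction effect $\beta_I$")
    ax.set_ylabel("proportion of simulations")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlim(min(tab["beta_I"]) - 0.02, max(tab["beta_I"]) + 0.02)
    ax.legend(loc="center left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
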