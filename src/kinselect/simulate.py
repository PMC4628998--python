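"""Seeded synthetic data with the statistical structure of kinase profiling.

Two generators mirror the two experimental readouts the analysis modules
consume:

* **Panels** — a mass of near-100 % background residual activities
  (normal, truncated below at 0, *not* truncated above 100, since real
  panels show apparent activation well above 100 %) plus a few planted
  hits at exact stated activities.
* **Kinetic and dose–response data** — the competitive Michaelis–Menten
  surface with multiplicative Gaussian noise, v·(1 + ε), ε ~ N(0, cv²),
  the standard error model for radiometric kinase assays; nonpositive
  draws are rejected and redrawn to keep velocities positive.

Default kinetic parameters describe the CK2-holoenzyme/quinalizarin
system: Ki = 0.058 µM, ATP Km = 13 µM, an ATP grid bracketing the 20 µM
assay concentration, and inhibitor concentrations spanning 0–0.2 µM
(roughly 0–3.5 × Ki).  Every generator is fully deterministic given its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticAssay, mm_velocity, residual_activity_curve
from .panel import KinasePanel, PanelEntry

__all__ = [
    "PanelSimSpec",
    "KineticSimSpec",
    "simulate_panel",
    "simulate_kinetic_assay",
    "simulate_dose_response",
]

DEFAULT_S_GRID = (5.0, 10.0, 20.0, 40.0, 80.0)
DEFAULT_I_GRID = (0.0, 0.05, 0.1, 0.2)


@dataclass(frozen=True)
class PanelSimSpec:
    """Shape parameters of a synthetic selectivity panel.

    ``background_mean``/``background_sd`` describe the off-target residual
    activity spread (100 ± 12 % by default, wide enough to include the
    apparent-activation values above 100 % that real panels show);
    ``hits`` plants named kinases at exact residual activities.
    """

    n_kinases: int = 140
    background_mean: float = 100.0
    background_sd: float = 12.0
    hits: tuple[tuple[str, float], ...] = ()
    seed: int = 0
    inhibitor_name: str = "synthetic"
    inhibitor_conc_uM: float = 1.0

    def __post_init__(self) -> None:
        if self.n_kinases < len(self.hits):
            raise ValueError("n_kinases must be >= number of planted hits")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        names = [name for name, _ in self.hits]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate hit names: {sorted(names)}")


@dataclass(frozen=True)
class KineticSimSpec:
    """True parameters and design of a synthetic competitive-inhibition assay."""

    Vmax: float = 1.0
    Km: float = 13.0  # µM (ATP)
    Ki: float = 0.058  # µM
    S_grid: tuple[float, ...] = DEFAULT_S_GRID
    I_grid: tuple[float, ...] = DEFAULT_I_GRID
    replicates: int = 3
    cv: float = 0.05
    seed: int = 0
    enzyme_form: str = "CK2α2β2"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not (self.Vmax > 0 and self.Km > 0 and self.Ki > 0):
            raise ValueError("Vmax, Km and Ki must be positive")
        if any(s <= 0 for s in self.S_grid):
            raise ValueError("substrate grid must be positive")
        if any(i < 0 for i in self.I_grid) or 0.0 not in self.I_grid:
            raise ValueError("inhibitor grid must be nonnegative and include 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def simulate_panel(spec: PanelSimSpec) -> KinasePanel:
    """Draw a synthetic panel: truncated-normal background plus exact hits.

    Background activities are N(mean, sd) with negative draws rejected
    (truncation below 0 only); planted hits keep their stated activities
    exactly and are flagged as reference targets when named "CK2*".
    """
    rng = np.random.default_rng(spec.seed)
    n_background = spec.n_kinases - len(spec.hits)
    if spec.background_sd == 0:
        activities = np.full(n_background, float(spec.background_mean))
    else:
        activities = np.empty(n_background)
        remaining = np.arange(n_background)
        while remaining.size:
            draws = rng.normal(spec.background_mean, spec.background_sd, remaining.size)
            ok = draws >= 0
            activities[remaining[ok]] = draws[ok]
            remaining = remaining[~ok]
    entries = [
        PanelEntry(
            kinase_name=name,
            activity_percent=float(act),
            is_reference_target=name.startswith("CK2"),
        )
        for name, act in spec.hits
    ]
    width = len(str(max(n_background, 1)))
    entries.extend(
        PanelEntry(kinase_name=f"KIN{i + 1:0{width}d}", activity_percent=float(a))
        for i, a in enumerate(activities)
    )
    return KinasePanel(
        inhibitor_name=spec.inhibitor_name,
        inhibitor_conc_uM=spec.inhibitor_conc_uM,
        entries=tuple(entries),
    )


def _multiplicative_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """values·(1+ε), ε ~ N(0, cv²); nonpositive results redrawn."""
    if cv == 0:
        return values.copy()
    out = values * (1.0 + rng.normal(0.0, cv, values.shape))
    bad = np.flatnonzero(out <= 0)
    while bad.size:
        out[bad] = values[bad] * (1.0 + rng.normal(0.0, cv, bad.size))
        bad = bad[out[bad] <= 0]
    return out


def simulate_kinetic_assay(spec: KineticSimSpec) -> KineticAssay:
    """Velocities on the competitive MM surface with multiplicative noise."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for I in spec.I_grid:
        for S in spec.S_grid:
            true_v = mm_velocity(spec.Vmax, spec.Km, S, I, spec.Ki)
            noisy = _multiplicative_noise(
                rng, np.full(spec.replicates, true_v), spec.cv
            )
            rows.extend(
                {
                    "substrate_uM": S,
                    "inhibitor_uM": I,
                    "replicate": r + 1,
                    "velocity": float(v),
                }
                for r, v in enumerate(noisy)
            )
    return KineticAssay(
        data=pd.DataFrame(rows), enzyme_form=spec.enzyme_form
    )


def simulate_dose_response(
    Km: float,
    S: float,
    Ki: float,
    I_grid: Sequence[float],
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Residual-activity dose–response points with multiplicative noise."""
    rng = np.random.default_rng(seed)
    curve = residual_activity_curve(Km, S, Ki, I_grid)
    curve["activity_percent"] = _multiplicative_noise(
        rng, curve["activity_percent"].to_numpy(), cv
    )
    return curve
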