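"""Selectivity statistics for single-concentration kinase panels.

The inhibition profile of a selective compound is highly *concentrated*:
almost all panel kinases retain ~100 % activity while one or a few are
strongly inhibited.  Concentration of a nonnegative distribution is what
the Lorenz curve and the Gini coefficient measure, so they serve as
panel-level selectivity scores: Gini 0 means every kinase is inhibited
equally (perfectly unselective), and the maximum (n−1)/n means all
inhibition falls on a single kinase.

All statistics operate on percent inhibition, the complement of the
residual activity the panel reports (inhibition = 100 − activity, floored
at 0 so that apparent activation does not count as negative selectivity
signal).

The discrete sample Gini used throughout is the rank formula

    G = (2 · Σᵢ i·x₍ᵢ₎) / (n · Σ x) − (n + 1) / n

with x₍ᵢ₎ the values sorted ascending and i the 1-based rank.  It is
algebraically identical to the mean pairwise difference form
Σᵢⱼ|xᵢ−xⱼ| / (2n²·x̄) and to twice the trapezoidal area between the
diagonal and the Lorenz polygon; the test-suite asserts all three agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import KinasePanel, PanelValidationError

__all__ = [
    "InhibitionVector",
    "LorenzCurve",
    "SelectivityReport",
    "SelectivityProfile",
    "GiniUndefinedError",
    "to_inhibition",
    "gini_coefficient",
    "lorenz_curve",
    "hit_rate",
    "census",
    "rank_by_potency",
    "compare_inhibitors",
    "plot_lorenz",
]

DEFAULT_HIT_THRESHOLD = 50.0
DEFAULT_CENSUS_CUTOFFS = (50.0, 80.0)


class GiniUndefinedError(ValueError):
    """The Gini coefficient is undefined (no measurable inhibition)."""


@dataclass(frozen=True)
class InhibitionVector:
    """Per-kinase percent inhibition, with bookkeeping of clipped entries."""

    values: np.ndarray  # each in [0, 100]
    labels: tuple[str, ...]
    clipped_count: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.labels):
            raise ValueError("values and labels must be aligned 1-D")
        if np.any(values < 0) or np.any(values > 100):
            raise ValueError("inhibition values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LorenzCurve:
    """Lorenz polygon of an inhibition distribution.

    ``points`` holds n+1 (cumulative kinase fraction, cumulative inhibition
    fraction) pairs from (0, 0) to (1, 1), computed over values sorted
    ascending; the curve is convex and lies on or below the diagonal.
    """

    points: np.ndarray  # shape (n+1, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def gini(self) -> float:
        """Twice the trapezoidal area between the diagonal and the curve."""
        return float(2.0 * (0.5 - np.trapezoid(self.y, self.x)))


@dataclass(frozen=True)
class SelectivityReport:
    """Panel-level selectivity summary for one inhibitor."""

    inhibitor_name: str
    inhibitor_conc_uM: float
    n_kinases: int
    gini: float
    hit_rate: float
    hit_threshold: float
    censuses: Mapping[float, int]
    census_members: Mapping[float, tuple[str, ...]]
    clipped_count: int
    ranking: tuple[tuple[str, float], ...]

    @property
    def gini_reported(self) -> float:
        """Gini rounded half-away-from-zero to 3 decimals (reporting style)."""
        return _round3(self.gini)

    @property
    def hit_rate_reported(self) -> float:
        return _round3(self.hit_rate)

    def to_dict(self, top_k: int = 10) -> dict:
        return {
            "inhibitor": self.inhibitor_name,
            "concentration_uM": self.inhibitor_conc_uM,
            "n_kinases": self.n_kinases,
            "gini": float(f"{self.gini:.6g}"),
            "hit_rate": float(f"{self.hit_rate:.6g}"),
            "hit_threshold": self.hit_threshold,
            "censuses": {str(c): int(n) for c, n in self.censuses.items()},
            "clipped_count": self.clipped_count,
            "ranking": [
                {"kinase": k, "activity_percent": a} for k, a in self.ranking[:top_k]
            ],
            "reported": {
                "gini": self.gini_reported,
                "hit_rate": self.hit_rate_reported,
            },
        }


def _round3(x: float) -> float:
    """Round half away from zero to 3 decimals (reporting convention)."""
    return float(np.floor(abs(x) * 1000 + 0.5) / 1000 * np.sign(x)) if x else 0.0


def _require_collapsed(panel: KinasePanel) -> None:
    if not panel.is_collapsed:
        raise PanelValidationError(
            "panel has duplicate group_keys; collapse_panel() it before scoring"
        )


def to_inhibition(panel: KinasePanel, clip_negative: bool = True) -> InhibitionVector:
    """Percent inhibition 100 − activity per kinase, floored at 0 by default.

    Requires a collapsed panel.  ``clipped_count`` records how many entries
    had activity above 100 % (apparent activation) and were clipped.
    """
    _require_collapsed(panel)
    activity = np.array([e.activity_percent for e in panel.entries], dtype=float)
    raw = 100.0 - activity
    clipped = int(np.sum(raw < 0))
    if clip_negative:
        values = np.maximum(raw, 0.0)
    else:
        if clipped:
            raise ValueError(
                f"{clipped} entries have activity > 100 %; enable clip_negative "
                "or remove them"
            )
        values = raw
    return InhibitionVector(
        values=values,
        labels=tuple(e.kinase_name for e in panel.entries),
        clipped_count=clipped if clip_negative else 0,
    )


def _as_values(inh: InhibitionVector | Sequence[float]) -> np.ndarray:
    if isinstance(inh, InhibitionVector):
        return inh.values
    return np.asarray(inh, dtype=float)


def gini_coefficient(inh: InhibitionVector | Sequence[float]) -> float:
    """Discrete sample Gini of an inhibition vector (rank formula).

    Requires n >= 2 and at least one positive value; an all-zero vector —
    a compound with no measurable inhibition anywhere — has no defined
    concentration and raises :class:`GiniUndefinedError`.
    """
    x = _as_values(inh)
    if x.size < 2:
        raise ValueError("Gini requires at least 2 values")
    if np.any(x < 0):
        raise ValueError("inhibition values must be nonnegative")
    total = x.sum()
    if total == 0:
        raise GiniUndefinedError("all inhibition values are zero; Gini undefined")
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * np.sum(ranks * xs) / (n * total) - (n + 1) / n)


def lorenz_curve(inh: InhibitionVector | Sequence[float]) -> LorenzCurve:
    """Lorenz polygon: point k is (k/n, Σ_{i<=k} x₍ᵢ₎ / Σx), k = 0..n."""
    x = _as_values(inh)
    if x.size < 1:
        raise ValueError("empty inhibition vector")
    total = x.sum()
    if total <= 0:
        raise GiniUndefinedError("total inhibition is zero; Lorenz curve undefined")
    xs = np.sort(x)
    n = xs.size
    cum = np.concatenate([[0.0], np.cumsum(xs) / total])
    frac = np.arange(n + 1) / n
    return LorenzCurve(points=np.column_stack([frac, cum]))


def hit_rate(
    panel: KinasePanel, threshold: float = DEFAULT_HIT_THRESHOLD
) -> float:
    """Fraction of panel kinases inhibited strictly more than *threshold* %."""
    if not (0 < threshold < 100):
        raise ValueError("hit threshold must lie strictly between 0 and 100")
    inh = to_inhibition(panel)
    return float(np.sum(inh.values > threshold) / len(inh))


def census(
    panel: KinasePanel,
    activity_cutoff: float,
    exclude_reference: bool = False,
) -> tuple[int, tuple[str, ...]]:
    """Count (and list) kinases with residual activity strictly below the cutoff.

    With ``exclude_reference`` the profiled target's entries are omitted,
    matching statements of the form "none of the *other* kinases…".
    """
    _require_collapsed(panel)
    members = sorted(
        e.kinase_name
        for e in panel.entries
        if e.activity_percent < activity_cutoff
        and not (exclude_reference and e.is_reference_target)
    )
    return len(members), tuple(members)


def rank_by_potency(
    panel: KinasePanel, exclude_reference: bool = False
) -> tuple[tuple[str, float], ...]:
    """Kinases sorted by ascending residual activity, ties alphabetical."""
    _require_collapsed(panel)
    entries = [
        e for e in panel.entries if not (exclude_reference and e.is_reference_target)
    ]
    return tuple(
        (e.kinase_name, e.activity_percent)
        for e in sorted(entries, key=lambda e: (e.activity_percent, e.kinase_name))
    )


class SelectivityProfile(BaseEstimator):
    """Selectivity scorer for a single-concentration kinase panel.

    Fitting a :class:`~kinselect.panel.KinasePanel` computes the Lorenz
    curve, Gini coefficient, hit rate, threshold censuses and potency
    ranking of the percent-inhibition distribution, exposed as fitted
    attributes.

    Parameters
    ----------
    hit_threshold : float, default 50
        A kinase is a *hit* when inhibited strictly more than this percent.
    census_cutoffs : sequence of float, default (50, 80)
        Residual-activity cutoffs for the strict "< cutoff" censuses.
    clip_negative : bool, default True
        Floor percent inhibition at 0 (activation is not selectivity signal).
    exclude_reference_in_census : bool, default True
        Omit the profiled target from censuses (off-target counting).

    Attributes
    ----------
    gini_ : float
    hit_rate_ : float
    lorenz_ : LorenzCurve
    inhibition_ : InhibitionVector
    censuses_ : dict cutoff -> count
    census_members_ : dict cutoff -> sorted kinase tuple
    ranking_ : tuple of (kinase, activity), ascending activity
    n_kinases_ : int
    report_ : SelectivityReport

    Examples
    --------
    >>> from kinselect import load_quinalizarin_panel, SelectivityProfile
    >>> profile = SelectivityProfile().fit(load_quinalizarin_panel(collapsed=True))
    >>> round(profile.gini_, 3), round(profile.hit_rate_, 3)
    (0.747, 0.007)
    """

    def __init__(
        self,
        hit_threshold: float = DEFAULT_HIT_THRESHOLD,
        census_cutoffs: Sequence[float] = DEFAULT_CENSUS_CUTOFFS,
        clip_negative: bool = True,
        exclude_reference_in_census: bool = True,
    ):
        self.hit_threshold = hit_threshold
        self.census_cutoffs = census_cutoffs
        self.clip_negative = clip_negative
        self.exclude_reference_in_census = exclude_reference_in_census

    def fit(self, panel: KinasePanel, y=None) -> "SelectivityProfile":
        _require_collapsed(panel)
        inh = to_inhibition(panel, clip_negative=self.clip_negative)
        self.inhibition_ = inh
        self.gini_ = gini_coefficient(inh)
        self.lorenz_ = lorenz_curve(inh)
        self.hit_rate_ = hit_rate(panel, self.hit_threshold)
        self.censuses_ = {}
        self.census_members_ = {}
        for cutoff in self.census_cutoffs:
            count, members = census(
                panel, cutoff, exclude_reference=self.exclude_reference_in_census
            )
            self.censuses_[float(cutoff)] = count
            self.census_members_[float(cutoff)] = members
        self.ranking_ = rank_by_potency(panel)
        self.n_kinases_ = len(panel)
        self.report_ = SelectivityReport(
            inhibitor_name=panel.inhibitor_name,
            inhibitor_conc_uM=panel.inhibitor_conc_uM,
            n_kinases=self.n_kinases_,
            gini=self.gini_,
            hit_rate=self.hit_rate_,
            hit_threshold=self.hit_threshold,
            censuses=dict(self.censuses_),
            census_members=dict(self.census_members_),
            clipped_count=inh.clipped_count,
            ranking=self.ranking_,
        )
        return self

    def score(self, panel: KinasePanel, y=None) -> float:
        """Gini coefficient of *panel* (higher = more selective)."""
        return gini_coefficient(to_inhibition(panel, self.clip_negative))


def compare_inhibitors(
    panels: Sequence[KinasePanel], **profile_params
) -> tuple[pd.DataFrame, tuple[LorenzCurve, ...]]:
    """Score several inhibitors side by side on their own panels.

    No cross-panel kinase alignment is attempted: panels of different
    composition are each scored on their own membership, so Gini values
    are panel-relative.  Returns a summary table (one row per inhibitor,
    input order preserved) and the matching Lorenz curves for overlay
    plotting.
    """
    if not panels:
        raise ValueError("compare_inhibitors needs at least one panel")
    rows, curves = [], []
    for panel in panels:
        prof = SelectivityProfile(**profile_params).fit(panel)
        r = prof.report_
        rows.append(
            {
                "inhibitor": r.inhibitor_name,
                "concentration_uM": r.inhibitor_conc_uM,
                "n_kinases": r.n_kinases,
                "gini": r.gini,
                "hit_rate": r.hit_rate,
                "clipped_count": r.clipped_count,
            }
        )
        curves.append(prof.lorenz_)
    return pd.DataFrame(rows), tuple(curves)


def plot_lorenz(
    curves: Sequence[LorenzCurve],
    labels: Sequence[str] | None = None,
    ax=None,
):
    """Overlay Lorenz curves with the equality diagonal (presentation only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="equality")
    for i, curve in enumerate(curves):
        label = labels[i] if labels else None
        ax.plot(curve.x, curve.y, lw=1.5, label=label)
    ax.set_xlabel("cumulative fraction of kinases")
    ax.set_ylabel("cumulative fraction of inhibition")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if labels:
        ax.legend(frameon=False)
    return ax
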