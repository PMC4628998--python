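"""Competitive-inhibition kinetics: Lineweaver–Burk fits, Ki replot, IC50.

Model
-----
Initial velocities follow Michaelis–Menten kinetics with an ATP-competitive
inhibitor:

    v = Vmax · [S] / (Km · (1 + [I]/Ki) + [S])

Competition raises the *apparent* Km by the factor (1 + [I]/Ki) and leaves
Vmax unchanged.  The classical graphical inference chain implemented here:

1. At each inhibitor concentration, an ordinary least-squares line of
   1/v on 1/[S] (the Lineweaver–Burk double-reciprocal plot) gives
   slope = Km,app/Vmax and intercept = 1/Vmax.
2. Under the competitive model the primary slope is affine in [I]:
   slope([I]) = (Km/Vmax)·(1 + [I]/Ki).  Regressing the per-concentration
   slopes on [I] (the secondary replot) therefore yields
   Ki = replot intercept / replot slope.
3. At fixed substrate concentration the residual activity is
   a([I]) = 100·(Km+S) / (Km·(1+[I]/Ki) + S), a one-site logistic in [I]
   with unit Hill slope and midpoint IC50 = Ki·(1 + S/Km) — the
   Cheng–Prusoff relation for competitive inhibition.

Units: all concentrations in µM; velocities are unit-agnostic (only
ratios enter Km, Ki and IC50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "KineticAssay",
    "MMFit",
    "KiFit",
    "IC50Fit",
    "KineticsError",
    "DesignError",
    "NonHyperbolicDataError",
    "NoInhibitionError",
    "MechanismViolationError",
    "UnidentifiableError",
    "mm_velocity",
    "LineweaverBurkRegression",
    "CompetitiveKiRegression",
    "IC50Curve",
    "fit_lineweaver_burk",
    "fit_ki_replot",
    "fit_ic50",
    "cheng_prusoff",
    "ic50_from_ki",
    "residual_activity_curve",
    "read_kinetics_csv",
    "read_dose_response_csv",
]

KINETICS_COLUMNS = ("substrate_uM", "inhibitor_uM", "replicate", "velocity")
DOSE_COLUMNS = ("inhibitor_uM", "activity_percent")


class KineticsError(ValueError):
    """Base class for kinetic-inference failures."""


class DesignError(KineticsError):
    """The assay design cannot support the requested fit."""


class NonHyperbolicDataError(KineticsError):
    """Double-reciprocal line has nonpositive slope or intercept."""


class NoInhibitionError(KineticsError):
    """Replot slope is not positive: the inhibitor has no measurable effect."""


class MechanismViolationError(KineticsError):
    """Fitted parameters contradict the competitive mechanism (Ki <= 0)."""


class UnidentifiableError(KineticsError):
    """Dose–response data carry no transition; IC50 cannot be identified."""


def mm_velocity(
    Vmax: float, Km: float, S, I=0.0, Ki: float = math.inf
):
    """Competitive Michaelis–Menten velocity Vmax·S / (Km·(1 + I/Ki) + S).

    ``S`` and ``I`` may be scalars or arrays (broadcast); ``Ki=inf`` (or
    ``I=0``) reduces to the uninhibited hyperbola.
    """
    if not (Vmax > 0 and Km > 0 and Ki > 0):
        raise ValueError("Vmax, Km and Ki must be positive")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate concentration must be positive")
    if np.any(I < 0):
        raise ValueError("inhibitor concentration must be nonnegative")
    v = Vmax * S / (Km * (1.0 + I / Ki) + S)
    return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class KineticAssay:
    """Initial-velocity measurements on a ([S] × [I] × replicate) design.

    ``data`` is a long-format table with columns ``substrate_uM``,
    ``inhibitor_uM``, ``replicate`` and ``velocity``.  Substrate
    concentrations must be positive, velocities positive, and the
    inhibitor series must include the uninhibited [I] = 0 control (the
    anchor of the secondary replot).
    """

    data: pd.DataFrame
    enzyme_form: str = ""
    inhibitor_name: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"kinetics table missing columns {missing}")
        if df.empty:
            raise DesignError("kinetics table is empty")
        if (df["substrate_uM"] <= 0).any():
            raise DesignError("all substrate concentrations must be > 0")
        if (df["inhibitor_uM"] < 0).any():
            raise DesignError("inhibitor concentrations must be >= 0")
        if (df["velocity"] <= 0).any():
            raise DesignError("all velocities must be > 0")
        if 0.0 not in set(df["inhibitor_uM"]):
            raise DesignError("inhibitor series must include the [I] = 0 control")

    @property
    def substrate_grid(self) -> np.ndarray:
        return np.sort(self.data["substrate_uM"].unique())

    @property
    def inhibitor_grid(self) -> np.ndarray:
        return np.sort(self.data["inhibitor_uM"].unique())

    def mean_velocities(self, I: float) -> pd.DataFrame:
        """Replicate-averaged velocities at one inhibitor concentration."""
        sub = self.data[self.data["inhibitor_uM"] == I]
        if sub.empty:
            raise DesignError(f"no measurements at [I] = {I} µM")
        return (
            sub.groupby("substrate_uM", as_index=False)["velocity"]
            .mean()
            .sort_values("substrate_uM", ignore_index=True)
        )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters fitted at one inhibitor concentration."""

    Km: float  # apparent Km at this [I], µM
    Vmax: float
    inhibitor_uM: float
    slope: float  # double-reciprocal slope = Km/Vmax
    intercept: float  # 1/Vmax
    method: str = "lineweaver-burk"
    residual_ss: float = 0.0
    n_points: int = 0


@dataclass(frozen=True)
class KiFit:
    """Competitive inhibition constant from the Km/Vmax-vs-[I] replot."""

    Ki: float  # µM
    replot_slope: float
    replot_intercept: float
    per_conc_fits: tuple[MMFit, ...]
    mechanism_assumed: str = "competitive"
    replot_stderr: float = float("nan")


@dataclass(frozen=True)
class IC50Fit:
    """Logistic dose–response fit at fixed substrate concentration."""

    IC50: float  # µM
    hill_slope: float
    top: float  # percent activity asymptote at I -> 0
    bottom: float
    residual_ss: float = 0.0
    n_points: int = 0


class LineweaverBurkRegression(BaseEstimator, RegressorMixin):
    """Michaelis–Menten fit by double-reciprocal OLS (or direct NLS).

    The default, classical graphical method regresses 1/v on 1/[S]
    (replicates averaged per substrate level first), giving
    Km = slope/intercept and Vmax = 1/intercept.  ``method="direct"``
    fits the hyperbola v = Vmax·S/(Km+S) by nonlinear least squares
    behind the same interface; both agree exactly on noiseless data and
    diverge under noise (1/v amplifies low-velocity errors).

    Attributes (after ``fit(S, v)``)
    --------------------------------
    Km_, Vmax_ : float
    slope_, intercept_ : float — double-reciprocal line parameters
    residual_ss_ : float — residual sum of squares on the fitted scale
    """

    def __init__(self, method: str = "lineweaver-burk"):
        self.method = method

    def fit(self, X, y) -> "LineweaverBurkRegression":
        S = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if S.shape != v.shape:
            raise ValueError("S and v must have the same length")
        if np.unique(S).size < 3:
            raise DesignError("need >= 3 distinct substrate concentrations")
        if np.any(S <= 0) or np.any(v <= 0):
            raise DesignError("substrate concentrations and velocities must be > 0")

        if self.method == "lineweaver-burk":
            line = stats.linregress(1.0 / S, 1.0 / v)
            slope, intercept = float(line.slope), float(line.intercept)
            if intercept <= 0 or slope <= 0:
                raise NonHyperbolicDataError(
                    f"double-reciprocal fit gave slope={slope:.4g}, "
                    f"intercept={intercept:.4g}; data are not hyperbolic"
                )
            self.Vmax_ = 1.0 / intercept
            self.Km_ = slope / intercept
            self.slope_, self.intercept_ = slope, intercept
            resid = 1.0 / v - (intercept + slope / S)
            self.residual_ss_ = float(resid @ resid)
        elif self.method == "direct":
            # start from the reciprocal-plot estimate when it is sane
            try:
                p0 = LineweaverBurkRegression().fit(S, v)
                start = (p0.Vmax_, p0.Km_)
            except KineticsError:
                start = (float(v.max()), float(np.median(S)))
            popt, _ = optimize.curve_fit(
                lambda s, vmax, km: vmax * s / (km + s),
                S, v, p0=start, maxfev=10000,
            )
            Vmax, Km = map(float, popt)
            if Vmax <= 0 or Km <= 0:
                raise NonHyperbolicDataError(
                    f"direct fit gave Vmax={Vmax:.4g}, Km={Km:.4g}"
                )
            self.Vmax_, self.Km_ = Vmax, Km
            self.slope_, self.intercept_ = Km / Vmax, 1.0 / Vmax
            resid = v - Vmax * S / (Km + S)
            self.residual_ss_ = float(resid @ resid)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.n_points_ = int(S.size)
        return self

    def predict(self, X) -> np.ndarray:
        S = np.asarray(X, dtype=float).ravel()
        return self.Vmax_ * S / (self.Km_ + S)


def fit_lineweaver_burk(
    assay: KineticAssay, I: float, method: str = "lineweaver-burk"
) -> MMFit:
    """Fit apparent Km and Vmax at one inhibitor concentration of *assay*.

    Replicates are averaged per substrate level before the reciprocal
    transform (averaging on the v scale avoids the extra 1/v variance
    distortion).
    """
    means = assay.mean_velocities(I)
    est = LineweaverBurkRegression(method=method).fit(
        means["substrate_uM"].to_numpy(), means["velocity"].to_numpy()
    )
    return MMFit(
        Km=est.Km_,
        Vmax=est.Vmax_,
        inhibitor_uM=float(I),
        slope=est.slope_,
        intercept=est.intercept_,
        method=method,
        residual_ss=est.residual_ss_,
        n_points=est.n_points_,
    )


class CompetitiveKiRegression(BaseEstimator):
    """Ki of a competitive inhibitor via the secondary Km/Vmax replot.

    ``fit`` takes a :class:`KineticAssay` spanning several inhibitor
    concentrations (including the [I] = 0 control).  Each concentration
    gets a primary Lineweaver–Burk fit; the primary slopes Km,app/Vmax
    are then regressed on [I], and Ki is the intercept/slope ratio of
    that replot line (slope([I]) = (Km/Vmax)(1 + [I]/Ki) under the
    competitive model).

    Attributes
    ----------
    Ki_ : float — inhibition constant, µM
    replot_slope_, replot_intercept_ : float
    per_conc_fits_ : tuple of MMFit, ascending [I]
    Km_, Vmax_ : float — uninhibited parameters (from the [I] = 0 fit)
    result_ : KiFit
    """

    def __init__(self, method: str = "lineweaver-burk", rel_slope_tol: float = 1e-10):
        self.method = method
        self.rel_slope_tol = rel_slope_tol

    def fit(self, assay: KineticAssay, y=None) -> "CompetitiveKiRegression":
        I_grid = assay.inhibitor_grid
        if I_grid.size < 2:
            raise DesignError(
                "Ki replot needs >= 2 inhibitor concentrations including 0"
            )
        fits = tuple(
            fit_lineweaver_burk(assay, I, method=self.method) for I in I_grid
        )
        slopes = np.array([f.slope for f in fits])
        line = stats.linregress(I_grid, slopes)
        replot_slope, replot_intercept = float(line.slope), float(line.intercept)
        # a flat replot (relative to the primary slope scale) means no effect
        if replot_slope <= self.rel_slope_tol * abs(replot_intercept):
            raise NoInhibitionError(
                "Km/Vmax does not increase with [I]: no inhibition detected"
            )
        Ki = replot_intercept / replot_slope
        if Ki <= 0:
            raise MechanismViolationError(
                f"replot implies Ki = {Ki:.4g} µM <= 0; data contradict "
                "competitive inhibition"
            )
        self.Ki_ = float(Ki)
        self.replot_slope_ = replot_slope
        self.replot_intercept_ = replot_intercept
        self.per_conc_fits_ = fits
        self.Km_ = fits[0].Km
        self.Vmax_ = fits[0].Vmax
        self.result_ = KiFit(
            Ki=self.Ki_,
            replot_slope=replot_slope,
            replot_intercept=replot_intercept,
            per_conc_fits=fits,
            replot_stderr=float(line.stderr) if line.stderr is not None else float("nan"),
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted primary slope Km,app/Vmax at inhibitor concentrations *X*."""
        I = np.asarray(X, dtype=float).ravel()
        return self.replot_intercept_ + self.replot_slope_ * I


def fit_ki_replot(assay: KineticAssay, method: str = "lineweaver-burk") -> KiFit:
    """Functional wrapper over :class:`CompetitiveKiRegression`."""
    return CompetitiveKiRegression(method=method).fit(assay).result_


class IC50Curve(BaseEstimator, RegressorMixin):
    """Logistic dose–response fit a(I) = bottom + (top−bottom)/(1+(I/IC50)^h).

    Defaults pin top = 100 %, bottom = 0 % and Hill slope h = 1, which is
    exactly the fixed-substrate competitive Michaelis–Menten residual
    activity curve; any of the three can be freed for empirical fits.

    Attributes (after ``fit(I, activity)``)
    ---------------------------------------
    ic50_ : float — µM
    top_, bottom_, hill_slope_ : float
    result_ : IC50Fit
    """

    def __init__(
        self,
        top: float | None = 100.0,
        bottom: float | None = 0.0,
        hill_slope: float | None = 1.0,
    ):
        self.top = top
        self.bottom = bottom
        self.hill_slope = hill_slope

    @staticmethod
    def _model(I, ic50, top, bottom, h):
        with np.errstate(divide="ignore"):
            ratio = np.where(I > 0, (I / ic50) ** h, 0.0)
        return bottom + (top - bottom) / (1.0 + ratio)

    def fit(self, X, y) -> "IC50Curve":
        I = np.asarray(X, dtype=float).ravel()
        a = np.asarray(y, dtype=float).ravel()
        if I.shape != a.shape:
            raise ValueError("I and activity must have the same length")
        if np.unique(I).size < 4:
            raise DesignError("need >= 4 inhibitor concentrations for an IC50 fit")
        if np.any(I < 0):
            raise DesignError("inhibitor concentrations must be >= 0")
        top = self.top
        bottom = self.bottom
        h = self.hill_slope
        span = a.max() - a.min()
        if span < 1e-9 * max(1.0, abs(a.max())):
            raise UnidentifiableError(
                "activities show no transition across the dose range; "
                "IC50 is unidentifiable"
            )

        # midpoint crossing as the IC50 starting value
        t0 = 100.0 if top is None else top
        b0 = 0.0 if bottom is None else bottom
        mid = (t0 + b0) / 2.0
        below = I[a < mid]
        ic50_0 = float(below.min()) if below.size else float(np.median(I[I > 0]))

        free_names = ["ic50"]
        p0 = [ic50_0]
        bounds_lo, bounds_hi = [0.0], [np.inf]
        for name, fixed, start, lo, hi in (
            ("top", top, float(a.max()), -np.inf, np.inf),
            ("bottom", bottom, float(a.min()), -np.inf, np.inf),
            ("h", h, 1.0, 0.0, np.inf),
        ):
            if fixed is None:
                free_names.append(name)
                p0.append(start)
                bounds_lo.append(lo)
                bounds_hi.append(hi)

        def model(Ix, *params):
            vals = dict(zip(free_names, params))
            return self._model(
                Ix,
                vals["ic50"],
                vals.get("top", top),
                vals.get("bottom", bottom),
                vals.get("h", h),
            )

        try:
            popt, _ = optimize.curve_fit(
                model, I, a, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=20000
            )
        except RuntimeError as err:
            raise UnidentifiableError(f"IC50 fit failed to converge: {err}") from err
        vals = dict(zip(free_names, popt))
        self.ic50_ = float(vals["ic50"])
        self.top_ = float(vals.get("top", top))
        self.bottom_ = float(vals.get("bottom", bottom))
        self.hill_slope_ = float(vals.get("h", h))
        if not (self.ic50_ > 0) or not np.isfinite(self.ic50_):
            raise UnidentifiableError(f"fitted IC50 = {self.ic50_!r} is not positive")
        if self.bottom_ >= self.top_:
            raise UnidentifiableError("fitted bottom asymptote is not below top")
        resid = a - self.predict(I)
        self.residual_ss_ = float(resid @ resid)
        self.n_points_ = int(I.size)
        self.result_ = IC50Fit(
            IC50=self.ic50_,
            hill_slope=self.hill_slope_,
            top=self.top_,
            bottom=self.bottom_,
            residual_ss=self.residual_ss_,
            n_points=self.n_points_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        I = np.asarray(X, dtype=float).ravel()
        return self._model(I, self.ic50_, self.top_, self.bottom_, self.hill_slope_)


def fit_ic50(
    dose: pd.DataFrame,
    top: float | None = 100.0,
    bottom: float | None = 0.0,
    hill_slope: float | None = 1.0,
) -> IC50Fit:
    """Fit an IC50 from a dose–response table (``inhibitor_uM``, ``activity_percent``)."""
    missing = [c for c in DOSE_COLUMNS if c not in dose.columns]
    if missing:
        raise DesignError(f"dose–response table missing columns {missing}")
    est = IC50Curve(top=top, bottom=bottom, hill_slope=hill_slope)
    est.fit(dose["inhibitor_uM"].to_numpy(), dose["activity_percent"].to_numpy())
    return est.result_


def cheng_prusoff(IC50: float, S: float, Km: float) -> float:
    """Ki from IC50 at substrate concentration S: Ki = IC50 / (1 + S/Km)."""
    if not (Km > 0):
        raise ValueError("Km must be positive")
    if not (IC50 > 0):
        raise ValueError("IC50 must be positive")
    if S < 0:
        raise ValueError("S must be nonnegative")
    return IC50 / (1.0 + S / Km)


def ic50_from_ki(Ki: float, S: float, Km: float) -> float:
    """Inverse Cheng–Prusoff: IC50 = Ki · (1 + S/Km)."""
    if not (Km > 0):
        raise ValueError("Km must be positive")
    if not (Ki > 0):
        raise ValueError("Ki must be positive")
    if S < 0:
        raise ValueError("S must be nonnegative")
    return Ki * (1.0 + S / Km)


def residual_activity_curve(
    Km: float, S: float, Ki: float, I_grid: Sequence[float]
) -> pd.DataFrame:
    """Noise-free residual activity a(I) = 100·(Km+S)/(Km·(1+I/Ki)+S).

    a(0) = 100 and a(IC50) = 50 with IC50 = Ki·(1+S/Km); the connection
    between the kinetic parameters and the percent-of-control readout
    of a selectivity panel.
    """
    if not (Km > 0 and S > 0 and Ki > 0):
        raise ValueError("Km, S and Ki must be positive")
    I = np.asarray(I_grid, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be nonnegative")
    activity = 100.0 * (Km + S) / (Km * (1.0 + I / Ki) + S)
    return pd.DataFrame({"inhibitor_uM": I, "activity_percent": activity})


def read_kinetics_csv(
    path: str | Path, enzyme_form: str = "", inhibitor_name: str = ""
) -> KineticAssay:
    """Read a long-format kinetics CSV (substrate_uM,inhibitor_uM,replicate,velocity)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return KineticAssay(
        data=pd.read_csv(path),
        enzyme_form=enzyme_form,
        inhibitor_name=inhibitor_name,
    )


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Read a dose–response CSV (inhibitor_uM,activity_percent)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"dose–response table missing columns {missing}")
    return df
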