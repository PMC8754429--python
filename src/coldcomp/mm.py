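"""Michaelis-Menten fitting of initial-rate series.

Initial velocities v measured at a ladder of substrate concentrations [S]
are fitted to

    v = k_cat * [E] * [S] / (K_M + [S])

by nonlinear least squares with (k_cat, K_M) log-parameterized so both stay
positive.  Per-variant fits over replicate experiments feed the slope
analysis of log10(k_cat) against organismal growth temperature.

Units: substrate and enzyme concentrations in uM, velocities in uM/s, so
k_cat emerges in s^-1 and K_M in uM; the catalytic efficiency k_cat/K_M is
reported in M^-1 s^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "InitialRateSeries",
    "MMFit",
    "ReplicateSummary",
    "michaelis_menten",
    "fit_michaelis_menten",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class InitialRateSeries:
    """Initial velocities of one enzyme variant across substrate levels.

    ``points`` is a sequence of ([S] in uM, v in uM/s); at least four
    distinct substrate concentrations are required for the two-parameter fit
    to be meaningfully overdetermined (bench practice is six to seven).
    """

    variant_label: str
    organism: str
    enzyme_conc_uM: float
    points: tuple[tuple[float, float], ...]
    t_growth_C: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.enzyme_conc_uM > 0:
            raise ValueError("enzyme concentration must be positive")
        if any(s <= 0 or v <= 0 for s, v in self.points):
            raise ValueError("substrate concentrations and velocities must be positive")
        if len({s for s, _ in self.points}) < 4:
            raise ValueError("need >= 4 distinct substrate concentrations")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters for one experiment.

    ``converged=False`` flags fits that failed or are unidentifiable (e.g.
    saturating-only data pushing K_M to the boundary); the parameter values
    are then the best available but should not be trusted.
    """

    k_cat: float          # s^-1
    K_M: float            # uM
    k_cat_over_km: float  # M^-1 s^-1  (= k_cat / (K_M * 1e-6))
    fit_rmse: float
    converged: bool


@dataclass(frozen=True)
class ReplicateSummary:
    mean_k_cat: float
    sd_k_cat: float
    n: int


def michaelis_menten(s, k_cat: float, K_M: float, enzyme_conc: float):
    """Michaelis-Menten velocity at substrate concentration(s) ``s``."""
    s = np.asarray(s, dtype=float)
    return k_cat * enzyme_conc * s / (K_M + s)


def fit_michaelis_menten(series: InitialRateSeries) -> MMFit:
    """Fit (k_cat, K_M) to one initial-rate series.

    Initialization: k_cat from the maximum observed v/[E], K_M from the
    substrate concentration nearest half-maximal velocity.  Parameters are
    log-parameterized.  A fit whose K_M lands far below the smallest assayed
    concentration (factor 1e-3) is flagged unconverged: the data then carry
    no information about K_M (saturation everywhere), and reporting a
    plausible-looking number silently would be worse than flagging it.
    """
    s = np.array([p[0] for p in series.points])
    v = np.array([p[1] for p in series.points])
    e = series.enzyme_conc_uM

    k_cat0 = float(np.max(v) / e)
    half_max = np.max(v) / 2.0
    K_M0 = float(s[np.argmin(np.abs(v - half_max))])

    def model(sub, log_kcat, log_km):
        return np.exp(log_kcat) * e * sub / (np.exp(log_km) + sub)

    p0 = (math.log(k_cat0), math.log(K_M0))
    try:
        with warnings.catch_warnings():
            # unidentifiable series legitimately yield a singular covariance;
            # the K_M boundary check below flags them
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, s, v, p0=p0, maxfev=20_000)
        k_cat, K_M = float(np.exp(popt[0])), float(np.exp(popt[1]))
        converged = True
    except RuntimeError:
        k_cat, K_M = k_cat0, K_M0
        converged = False
    if K_M < np.min(s) * 1e-3:
        converged = False
    resid = v - michaelis_menten(s, k_cat, K_M, e)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return MMFit(
        k_cat=k_cat,
        K_M=K_M,
        k_cat_over_km=k_cat / (K_M * 1e-6),
        fit_rmse=rmse,
        converged=converged,
    )


def aggregate_replicates(fits: Sequence[MMFit]) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1) of k_cat over replicate fits.

    A single replicate reports sd 0 with n=1 flagging that no spread was
    estimable.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    k = np.array([f.k_cat for f in fits])
    sd = float(np.std(k, ddof=1)) if k.size > 1 else 0.0
    return ReplicateSummary(mean_k_cat=float(np.mean(k)), sd_k_cat=sd, n=int(k.size))
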