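"""Concentration profiles and limit-of-detection estimation.

In the linear competitive-hybridization regime the branch distance obeys

    e^rho - 1 = (c_mut / c_wt) * exp(-ddG / RT)

a line through the origin in the relative mutant abundance, whose slope
exp(-ddG/RT) is the physico-chemical impact of the mutation.  Fitting the
profile (from a dilution series, or from a single measured point — the line
is pinned at the origin) yields the slope and hence, for a detectability
threshold rho_t on the branch distance, the concentration detection limit

    c_limit = (e^rho_t - 1) / slope        (as c_mut/c_wt).

Note the two abundance conventions: the profile abscissa is c_mut/c_wt, while
dilution series are usually specified as c_mut/c_total; conversions are
explicit everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .probeset import HybridSNVError
from .thermo import ThermoConfig

#: default branch-distance threshold at which a mutation counts as detectable,
#: the empirical distance still confidently measurable on this platform
DEFAULT_RHO_T = 0.5


def fraction_total_to_ratio(fraction_total: float) -> float:
    """Convert c_mut/c_total to c_mut/c_wt."""
    if not 0 <= fraction_total < 1:
        raise HybridSNVError("fraction of total must be in [0, 1)")
    return fraction_total / (1.0 - fraction_total)


def ratio_to_fraction_total(ratio: float) -> float:
    """Convert c_mut/c_wt to c_mut/c_total."""
    if ratio < 0:
        raise HybridSNVError("concentration ratio must be >= 0")
    return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Through-origin line e^rho - 1 versus c_mut/c_wt.

    ``slope`` estimates exp(-ddG/RT); ``residual_ss`` and ``r_squared`` refer
    to the through-origin fit (r_squared is 1 - SS_res/SS_total about zero).
    """

    ratios: np.ndarray  # c_mut / c_wt
    responses: np.ndarray  # e^rho - 1
    slope: float
    residual_ss: float
    r_squared: float

    @property
    def n_points(self) -> int:
        return len(self.ratios)

    def implied_ddg(self, thermo: ThermoConfig | None = None) -> float:
        """ddG (kcal/mol) implied by the slope: ddG = -RT ln(slope).

        For a mutation branch ddG = -penalty of the wild-type mismatch, so
        the mismatch penalty itself is +RT ln(slope).
        """
        thermo = thermo or ThermoConfig()
        return -thermo.rt * math.log(self.slope)


def fit_profile(
    points: Iterable[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> ConcentrationProfile:
    """Least-squares through-origin fit of e^rho - 1 on c_mut/c_wt.

    ``points`` are ``(c_mut/c_wt, rho)`` pairs.  A single positive-abundance
    point determines the slope exactly ((e^rho - 1)/ratio); points at zero
    abundance carry no information about the slope and only enter the
    residuals.  Optional ``weights`` allow an inverse-variance weighted fit
    for heteroscedastic series.
    """
    pts = list(points)
    if not pts:
        raise HybridSNVError("need at least one profile point")
    ratios = np.array([p[0] for p in pts], dtype=float)
    rhos = np.array([p[1] for p in pts], dtype=float)
    if (ratios < 0).any():
        raise HybridSNVError("concentration ratios must be >= 0")
    if not (ratios > 0).any():
        raise HybridSNVError("all abundances are zero; the slope is undetermined")
    w = np.ones_like(ratios) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != ratios.shape or (w < 0).any():
        raise HybridSNVError("weights must be non-negative, one per point")

    y = np.expm1(rhos)
    slope = float((w * ratios * y).sum() / (w * ratios**2).sum())
    resid = y - slope * ratios
    residual_ss = float((w * resid**2).sum())
    total_ss = float((w * y**2).sum())
    r_squared = 1.0 - residual_ss / total_ss if total_ss > 0 else float("nan")
    return ConcentrationProfile(
        ratios=ratios,
        responses=y,
        slope=slope,
        residual_ss=residual_ss,
        r_squared=r_squared,
    )


def profile_from_series(
    measurements: Iterable[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> ConcentrationProfile:
    """Build a profile from ``(c_mut/c_total, measured rho)`` pairs.

    Only the abscissa needs converting (series are specified as c_mut/c_total,
    the profile abscissa is c_mut/c_wt).  The measured distance needs no
    concentration adjustment: the reference line passes through the mixture's
    own reference-branch points, so the wild-type dilution factor (1 - f) —
    like the optical gain — cancels out of the vertical distance.
    """
    points = [(fraction_total_to_ratio(f), rho) for f, rho in measurements]
    return fit_profile(points, weights=weights)


@dataclass(frozen=True)
class DetectionLimit:
    """Concentration at which the branch distance reaches the threshold rho_t."""

    rho_t: float
    c_limit_ratio: float  # c_mut / c_wt
    c_limit_fraction_total: float  # c_mut / c_total
    slope: float

    @property
    def below_one_percent(self) -> bool:
        return self.c_limit_ratio < 0.01


def detection_limit(
    profile: ConcentrationProfile, rho_t: float = DEFAULT_RHO_T
) -> DetectionLimit:
    """Invert the profile at the threshold: c_limit = (e^rho_t - 1) / slope."""
    if profile.slope <= 0:
        raise HybridSNVError(
            f"profile slope {profile.slope:g} is not positive; no detection limit"
        )
    ratio = float(np.expm1(rho_t)) / profile.slope
    return DetectionLimit(
        rho_t=rho_t,
        c_limit_ratio=ratio,
        c_limit_fraction_total=ratio_to_fraction_total(ratio),
        slope=profile.slope,
    )


def panel_lod(
    measurements: Mapping[str, tuple[float, float]],
    rho_t: float = DEFAULT_RHO_T,
    thermo: ThermoConfig | None = None,
) -> pd.DataFrame:
    """Single-point detection limits for a whole mutation panel.

    ``measurements`` maps a mutation label to ``(c_mut/c_total, rho)`` from
    one experiment at a common fraction; the profile's linearity through the
    origin makes one point per mutation sufficient.  Returns a frame sorted
    from strongest (largest slope) to weakest mutation, flagging the weakest;
    ``frame.attrs["panel_lod_below_1pct"]`` records whether even the weakest
    mutation is detectable below 1% relative abundance.
    """
    if not measurements:
        raise HybridSNVError("empty panel")
    thermo = thermo or ThermoConfig()
    rows = []
    for label, (fraction, rho) in measurements.items():
        profile = profile_from_series([(fraction, rho)])
        limit = detection_limit(profile, rho_t)
        rows.append(
            {
                "mutation": label,
                "fraction_total": fraction,
                "rho": rho,
                "slope": profile.slope,
                "ddg_kcal_per_mol": profile.implied_ddg(thermo),
                "c_limit_ratio": limit.c_limit_ratio,
                "c_limit_fraction_total": limit.c_limit_fraction_total,
                "below_1pct": limit.below_one_percent,
            }
        )
    frame = pd.DataFrame(rows).sort_values("slope", ascending=False, ignore_index=True)
    frame["weakest"] = frame["slope"] == frame["slope"].min()
    frame.attrs["rho_t"] = rho_t
    frame.attrs["panel_lod_below_1pct"] = bool(frame["below_1pct"].all())
    return frame
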