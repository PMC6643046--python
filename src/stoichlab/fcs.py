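"""Fluorescence correlation spectroscopy: autocorrelation model and
oligomer-order estimation by the denaturation ratio.

A single fluorescent species diffusing in 3D through a Gaussian focal
volume has the autocorrelation

    G(tau) = (1/<N>) * (1 + tau/tau_d)^-1 * (1 + kappa^-2 * tau/tau_d)^-1/2

where ``<N>`` is the mean particle number in the focal volume (so the
amplitude G(0) = 1/<N> measures concentration), ``tau_d`` the diffusion
time, and ``kappa = z0/r0`` the structure parameter of the focus.  ``kappa``
is fixed from a calibration with a reference dye of known diffusion
coefficient (rhodamine 6G, 426 um^2/s) because single-condition curves
constrain it poorly.

Denaturing an oligomer of order ``m`` splits each particle into ``m``
fluorescent monomers, multiplying ``<N>`` by ``m``; the ratio
``N_denatured / N_native`` per replicate pair therefore estimates the
oligomer order directly.  Only amplitudes enter the ratio — the denatured
diffusion time is fitted independently since urea changes both viscosity
and particle size.  The model carries no triplet-state term; early lags
contaminated by photophysics can be trimmed before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize

from .errors import ArgumentError, DataError, FitError
from .stats import mean_t_ci


@dataclass
class AcfCurve:
    """An autocorrelation curve on a strictly increasing lag grid (seconds)."""

    lags: np.ndarray
    g: np.ndarray
    condition: str = "native"  # "native" | "denatured"
    label: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape or self.lags.ndim != 1:
            raise ArgumentError("lags and g must be 1-D arrays of equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ArgumentError("lag grid must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ArgumentError("g contains non-finite values")
        if self.condition not in ("native", "denatured"):
            raise ArgumentError(f"unknown condition {self.condition!r}")

    def trimmed(self, min_lag: float) -> "AcfCurve":
        """Copy with lags below ``min_lag`` removed (triplet suppression)."""
        keep = self.lags >= min_lag
        return AcfCurve(self.lags[keep], self.g[keep], self.condition, self.label)


@dataclass(frozen=True)
class FocalVolume:
    r0: float  # um, lateral 1/e^2 radius
    z0: float  # um, axial extent
    kappa: float  # z0 / r0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ArgumentError(f"r0 must be > 0, got {self.r0}")
        if self.kappa < 1:
            raise ArgumentError(f"kappa must be >= 1, got {self.kappa}")


@dataclass(frozen=True)
class AcfFit:
    n_particles: float
    tau_d: float  # s
    kappa_used: float
    residual_ss: float

    def __post_init__(self) -> None:
        if self.n_particles <= 0 or self.tau_d <= 0:
            raise ArgumentError("fitted n_particles and tau_d must be > 0")


@dataclass
class OligomerRatioResult:
    ratios: List[float]
    mean: float
    ci95_half_width: float
    n: int


def acf_model(tau, n: float, tau_d: float, kappa: float):
    """3D-diffusion autocorrelation ``G(tau)``; ``G(0) = 1/n``.

    Strictly decreasing in ``tau``; vanishes as ``tau -> inf``.
    """
    if n <= 0 or tau_d <= 0:
        raise ArgumentError(f"need n > 0 and tau_d > 0, got n={n}, tau_d={tau_d}")
    if kappa < 1:
        raise ArgumentError(f"kappa must be >= 1, got {kappa}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ArgumentError("tau must be >= 0")
    x = tau / tau_d
    g = (1.0 / n) / (1.0 + x) / np.sqrt(1.0 + x / kappa**2)
    return float(g) if g.ndim == 0 else g


def calibrate_focal_volume(tau_d_cal: float, d_cal: float, kappa: float) -> FocalVolume:
    """Focal-volume geometry from a reference dye measurement.

    Given the fitted diffusion time of a dye with known diffusion
    coefficient (``d_cal`` in um^2/s):  ``r0 = sqrt(4 * d_cal * tau_d_cal)``
    and ``z0 = kappa * r0``.
    """
    if tau_d_cal <= 0 or d_cal <= 0:
        raise ArgumentError(
            f"need tau_d_cal > 0 and d_cal > 0, got {tau_d_cal}, {d_cal}"
        )
    r0 = math.sqrt(4.0 * d_cal * tau_d_cal)
    return FocalVolume(r0=r0, z0=kappa * r0, kappa=kappa)


def diffusion_coefficient(tau_d: float, r0: float) -> float:
    """Diffusion coefficient ``D = r0^2 / (4 tau_d)`` in um^2/s."""
    if tau_d <= 0 or r0 <= 0:
        raise ArgumentError(f"need tau_d > 0 and r0 > 0, got {tau_d}, {r0}")
    return r0 * r0 / (4.0 * tau_d)


def fit_acf(
    curve: AcfCurve,
    kappa: float,
    weights: Optional[np.ndarray] = None,
    min_lag: Optional[float] = None,
) -> AcfFit:
    """Nonlinear least squares of the 3D-diffusion model over (N, tau_d).

    ``kappa`` is held fixed at its calibration value.  Initial values are
    ``n0 = 1/G(first lag)`` and ``tau_d0`` = the lag at which G has dropped
    to half its initial value.  Unweighted by default; optional per-point
    weights multiply the residuals.
    """
    if min_lag is not None:
        curve = curve.trimmed(min_lag)
    lags, g = curve.lags, curve.g
    if lags.size < 10:
        raise DataError(f"need >= 10 lag points, got {lags.size}")
    if lags[-1] / lags[0] < 100:
        raise DataError("lag grid must span at least two decades")
    g0 = g[0]
    if g0 <= 0 or np.ptp(g) < 1e-12 * max(abs(g0), 1.0):
        raise FitError("curve shows no decay; tau_d is unidentifiable")
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau_d0 = float(lags[below[0]]) if below.size else float(lags[lags.size // 2])
    w = np.ones_like(g) if weights is None else np.asarray(weights, dtype=float)

    def residuals(p):
        n, tau_d = p
        return w * (acf_model(lags, n, tau_d, kappa) - g)

    sol = optimize.least_squares(
        residuals,
        x0=[n0, tau_d0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not sol.success:
        raise FitError(f"ACF fit failed: {sol.message}")
    n_hat, tau_d_hat = sol.x
    if n_hat <= 1e-10 or tau_d_hat <= 1e-10:
        raise FitError(
            f"ACF fit pinned at parameter bound (n={n_hat:g}, tau_d={tau_d_hat:g})"
        )
    return AcfFit(
        n_particles=float(n_hat),
        tau_d=float(tau_d_hat),
        kappa_used=float(kappa),
        residual_ss=float(2.0 * sol.cost),
    )


def _particle_number(x: Union[AcfFit, float]) -> float:
    return float(x.n_particles) if isinstance(x, AcfFit) else float(x)


def oligomer_ratio(
    native: Sequence[Union[AcfFit, float]],
    denatured: Sequence[Union[AcfFit, float]],
    brightness_correction: float = 1.0,
) -> OligomerRatioResult:
    """Oligomer order from paired native/denatured particle numbers.

    Elements may be :class:`AcfFit` results or bare particle numbers; the
    lists are paired by replicate index.  ``brightness_correction`` divides
    the denatured counts to compensate for condition-dependent fluorophore
    brightness (default 1: no correction).  Mean and CI follow the same
    Student-t convention used for the gel assays.
    """
    if len(native) != len(denatured):
        raise ArgumentError(
            f"paired lists differ in length: {len(native)} vs {len(denatured)}"
        )
    if not native:
        raise ArgumentError("empty replicate lists")
    ratios = []
    for nat, den in zip(native, denatured):
        n_nat = _particle_number(nat)
        n_den = _particle_number(den) / brightness_correction
        if n_nat <= 0 or n_den <= 0:
            raise ArgumentError("particle numbers must be > 0")
        ratios.append(n_den / n_nat)
    mean, half, n = mean_t_ci(ratios)
    return OligomerRatioResult(ratios=ratios, mean=mean, ci95_half_width=half, n=n)
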