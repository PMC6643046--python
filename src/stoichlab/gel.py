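"""Migration-based stoichiometry inference from native gel band tables.

Under the reptation regime the migration distance of a long, linear,
negatively charged chain is linear in the logarithm of its molecular weight.
Two estimators exploit this:

* **Assay I** uses protein-DNA single complexes (lower shifts) of increasing
  flanking-DNA length as internal standards.  All standards carry the same
  unknown single-oligomer protein mass ``S`` on top of their known DNA mass,
  so the standard molecular weights are ``dna_mw + S``.  ``S`` is profiled
  out by least squares, the supershift of each two-site (tandem) fragment is
  mapped through the standard curve, and the mass difference between
  supershift and lower shift divided by the monomer mass gives the number of
  protein units per oligomer.

* **Assay II** uses a ladder of free DNA of known sizes as standards; the
  complex mass is read off the curve at the lower-shift migration and the
  DNA mass of the probe fragment subtracted before dividing by the monomer
  mass.

Migration distances are in arbitrary units (pixels), increasing away from the
well.  Each lane carries two non-interacting reference bands — a slow
``ref_upper`` and a fast ``ref_lower`` — used to normalize per-lane
electrophoresis variation: the normalized lag of a band is simply the
distance of the fast reference minus the distance of the band, which cancels
any per-lane offset.  Larger normalized lag means heavier species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats as sps

from .core import Construct, DnaFragment, complex_mw, dna_mw
from .errors import ArgumentError, DataError, FitError
from .stats import mean_t_ci


class BandType(str, Enum):
    """Identity of a band within a lane.

    Band identity is taken from the input table, never inferred from
    intensities.
    """

    FREE_DNA = "free_dna"
    LOWER_SHIFT = "lower_shift"
    SUPERSHIFT = "supershift"
    REF_UPPER = "ref_upper"  # slow/long reference DNA
    REF_LOWER = "ref_lower"  # fast/short reference DNA


@dataclass(frozen=True)
class GelBand:
    band_type: BandType
    distance: float  # arbitrary gel units, >= 0, increasing away from the well
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_type", BandType(self.band_type))
        if self.distance < 0:
            raise ArgumentError(f"band distance must be >= 0, got {self.distance}")


@dataclass
class GelLane:
    """One lane: a fragment, an optional construct, and its bands."""

    lane_id: str
    fragment: Optional[DnaFragment] = None
    construct: Optional[Construct] = None
    bands: List[GelBand] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ref in (BandType.REF_UPPER, BandType.REF_LOWER):
            if sum(1 for b in self.bands if b.band_type is ref) > 1:
                raise DataError(f"lane {self.lane_id!r}: duplicate {ref.value} band")
        upper = self.band(BandType.REF_UPPER)
        lower = self.band(BandType.REF_LOWER)
        if upper is not None and lower is not None and lower.distance < upper.distance:
            raise DataError(
                f"lane {self.lane_id!r}: ref_lower (fast, short DNA) must migrate "
                "at least as far as ref_upper"
            )

    def band(self, band_type: BandType) -> Optional[GelBand]:
        for b in self.bands:
            if b.band_type is BandType(band_type):
                return b
        return None

    def has_band(self, band_type: BandType) -> bool:
        return self.band(band_type) is not None


@dataclass
class GelTable:
    """An ordered collection of lanes from one gel."""

    lanes: List[GelLane]
    assay_mode: str = "assay1"  # "assay1" | "assay2"
    gel_id: str = "gel1"

    def __post_init__(self) -> None:
        if self.assay_mode not in ("assay1", "assay2"):
            raise ArgumentError(f"unknown assay_mode {self.assay_mode!r}")


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear migration-to-MW calibration.

    Fit of ``log10(MW / anchor_mw)`` on ``d - anchor_distance`` where ``d``
    is the normalized migration lag.  ``slope`` is positive under this
    convention (larger lag means heavier).  The standard range is kept so
    that extrapolated estimates can be flagged.
    """

    slope: float
    intercept: float
    r_squared: float
    anchor_mw: float
    anchor_distance: float
    d_min: float
    d_max: float

    def in_range(self, normalized_distance: float) -> bool:
        return self.d_min <= normalized_distance <= self.d_max


@dataclass
class StoichiometryResult:
    construct: Construct
    per_measurement_units: List[float]
    mean_units: float
    ci95_half_width: float
    n: int
    warnings: List[str] = field(default_factory=list)


class HypothesisFit(dict):
    """Per-hypothesis observed-vs-expected regression statistics.

    Maps hypothesized unit count to a dict with ``slope``, ``intercept``,
    ``r_squared`` and ``score`` (squared deviation of the regression line
    from the identity line).  ``best`` is the hypothesis with minimal score.
    """

    best: int


def normalize_migration(lane: GelLane, band_type: Union[BandType, str]) -> float:
    """Normalized migration lag of a band relative to the fast reference.

    Computes ``(d_ref_lower - d_ref_upper) - (d_band - d_ref_upper)``, which
    is algebraically ``d_ref_lower - d_band``: how far the band lags behind
    the fast reference DNA.  Heavier species lag more.  Per-lane offsets
    cancel because both references run in the same lane.
    """
    band_type = BandType(band_type)
    upper = lane.band(BandType.REF_UPPER)
    lower = lane.band(BandType.REF_LOWER)
    if upper is None or lower is None:
        missing = "ref_upper" if upper is None else "ref_lower"
        raise DataError(f"lane {lane.lane_id!r}: missing {missing} reference band")
    band = lane.band(band_type)
    if band is None:
        raise DataError(f"lane {lane.lane_id!r}: missing {band_type.value} band")
    return (lower.distance - upper.distance) - (band.distance - upper.distance)


def fit_standard_curve(
    standards: Sequence[Tuple[float, float]],
    anchor_index: int = 0,
) -> StandardCurve:
    """Ordinary least squares of log10(MW ratio) on migration-lag difference.

    Parameters
    ----------
    standards
        ``(normalized_distance, mw_kd)`` pairs; at least two with distinct
        distances and positive MWs.
    anchor_index
        Which standard anchors the curve (responses and abscissae are taken
        relative to it).  The intercept is fitted, not forced through the
        anchor, and is therefore ~0 for well-behaved data.
    """
    if len(standards) < 2:
        raise FitError(f"need >= 2 standards, got {len(standards)}")
    d = np.asarray([s[0] for s in standards], dtype=float)
    mw = np.asarray([s[1] for s in standards], dtype=float)
    if np.any(mw <= 0):
        raise FitError("all standard MWs must be > 0")
    if np.ptp(d) == 0:
        raise FitError("standards have duplicated migration distances")
    if not 0 <= anchor_index < len(standards):
        raise ArgumentError(f"anchor_index {anchor_index} out of range")
    x = d - d[anchor_index]
    y = np.log10(mw / mw[anchor_index])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        anchor_mw=float(mw[anchor_index]),
        anchor_distance=float(d[anchor_index]),
        d_min=float(d.min()),
        d_max=float(d.max()),
    )


def estimate_mw(curve: StandardCurve, normalized_distance: float) -> float:
    """Molecular weight (kD) at a normalized migration lag.

    ``anchor_mw * 10**(intercept + slope * (d - anchor_distance))``; strictly
    increasing in ``d``.  Extrapolation beyond the standard range is
    permitted; callers may consult :meth:`StandardCurve.in_range`.
    """
    return curve.anchor_mw * 10.0 ** (
        curve.intercept + curve.slope * (normalized_distance - curve.anchor_distance)
    )


def summarize_units(per_measurement_units: Sequence[float]):
    """Mean and two-sided 95% Student-t CI half-width of unit counts.

    Returns ``(mean, ci95_half_width, n)``; the half-width is NaN for a
    single measurement.
    """
    return mean_t_ci(per_measurement_units)


# ---------------------------------------------------------------------------
# assay I


def _joint_offset_fit(d: np.ndarray, dna: np.ndarray) -> Tuple[float, float, float]:
    """Fit d = a + b*log10(dna + S) profiling out the common protein mass S.

    The single-complex protein mass S is identical across assay-I standards
    (every lower shift carries exactly one oligomer), so it enters each
    standard's total MW additively.  For fixed S, (a, b) are the inner OLS
    solution; S is located by a coarse geometric scan followed by bounded
    minimization and a final full least-squares polish.  Returns (a, b, S).
    """

    def inner_sse(s: float) -> float:
        x = np.log10(dna + s)
        b, a = np.polyfit(x, d, 1)
        r = d - (a + b * x)
        return float(r @ r)

    grid = np.geomspace(1e-3, 1e5, 160)
    sses = np.array([inner_sse(s) for s in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        inner_sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    s0 = float(res.x)
    x0 = np.log10(dna + s0)
    b0, a0 = np.polyfit(x0, d, 1)

    def residuals(p: np.ndarray) -> np.ndarray:
        a, b, s = p
        return a + b * np.log10(dna + max(s, 1e-9)) - d

    sol = optimize.least_squares(
        residuals, x0=[a0, b0, s0], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    a, b, s = sol.x
    return float(a), float(b), float(max(s, 1e-9))


def assay1_stoichiometry(gel: GelTable, construct: Construct) -> StoichiometryResult:
    """Protein units per oligomer from supershift-minus-lowershift masses.

    Every lane with a lower shift (single- and two-site fragments alike)
    contributes a standard; each two-site lane that also shows a supershift
    contributes one unit-count measurement::

        units_i = (MW(supershift_i) - MW(lower_shift_i)) / monomer_mw

    Requires at least three lower-shift standards (the joint fit estimates
    slope, intercept and the shared single-complex protein mass).
    """
    if gel.assay_mode != "assay1":
        raise ArgumentError(f"expected an assay1 gel, got {gel.assay_mode!r}")
    standards: List[Tuple[float, float]] = []
    measure_lanes: List[GelLane] = []
    for lane in gel.lanes:
        if lane.fragment is None or not lane.has_band(BandType.LOWER_SHIFT):
            continue
        standards.append(
            (normalize_migration(lane, BandType.LOWER_SHIFT), lane.fragment.mw)
        )
        if lane.has_band(BandType.SUPERSHIFT):
            measure_lanes.append(lane)
    if len(standards) < 3:
        raise DataError(
            f"assay I needs >= 3 lower-shift standard lanes, found {len(standards)}"
        )
    if not measure_lanes:
        raise DataError("assay I needs >= 1 tandem lane with a supershift band")

    d = np.asarray([s[0] for s in standards])
    dna = np.asarray([s[1] for s in standards])
    _, _, s_hat = _joint_offset_fit(d, dna)
    curve = fit_standard_curve(list(zip(d, dna + s_hat)), anchor_index=0)

    units: List[float] = []
    warns: List[str] = []
    for lane in measure_lanes:
        d_low = normalize_migration(lane, BandType.LOWER_SHIFT)
        d_sup = normalize_migration(lane, BandType.SUPERSHIFT)
        if not curve.in_range(d_sup):
            warns.append(
                f"lane {lane.lane_id!r}: supershift outside standard range "
                "(extrapolated)"
            )
        d_mw = estimate_mw(curve, d_sup) - estimate_mw(curve, d_low)
        units.append(d_mw / construct.monomer_mw)
    mean, half, n = summarize_units(units)
    if n == 1:
        warns.append("single measurement: CI undefined")
    return StoichiometryResult(construct, units, mean, half, n, warns)


# ---------------------------------------------------------------------------
# assay II


def assay2_stoichiometry(
    gels: Union[GelTable, Sequence[GelTable]],
    construct: Construct,
    probe_fragment: DnaFragment,
) -> StoichiometryResult:
    """Protein units per oligomer from a free-DNA ladder standard curve.

    For each replicate gel the ladder of free DNA bands (known sizes)
    calibrates the curve and every lower shift of the requested construct
    yields one measurement::

        units = (MW(lower_shift) - dna_mw(probe)) / monomer_mw
    """
    if isinstance(gels, GelTable):
        gels = [gels]
    units: List[float] = []
    warns: List[str] = []
    for gel in gels:
        if gel.assay_mode != "assay2":
            raise ArgumentError(f"expected an assay2 gel, got {gel.assay_mode!r}")
        standards = []
        for lane in gel.lanes:
            if lane.fragment is not None and lane.has_band(BandType.FREE_DNA):
                if lane.construct is None:
                    standards.append(
                        (normalize_migration(lane, BandType.FREE_DNA), lane.fragment.mw)
                    )
        if len(standards) < 3:
            raise DataError(
                f"gel {gel.gel_id!r}: free-DNA ladder needs >= 3 sizes, "
                f"found {len(standards)}"
            )
        curve = fit_standard_curve(standards, anchor_index=0)
        found = False
        for lane in gel.lanes:
            if lane.construct is None or lane.construct.name != construct.name:
                continue
            if not lane.has_band(BandType.LOWER_SHIFT):
                continue
            found = True
            d_low = normalize_migration(lane, BandType.LOWER_SHIFT)
            if not curve.in_range(d_low):
                warns.append(
                    f"gel {gel.gel_id!r} lane {lane.lane_id!r}: lower shift "
                    "outside ladder range (extrapolated)"
                )
            mw_complex = estimate_mw(curve, d_low)
            units.append(
                (mw_complex - dna_mw(probe_fragment.length)) / construct.monomer_mw
            )
        if not found:
            raise DataError(
                f"gel {gel.gel_id!r}: no lower-shift lane for construct "
                f"{construct.name!r}"
            )
    mean, half, n = summarize_units(units)
    if n == 1:
        warns.append("single measurement: CI undefined")
    return StoichiometryResult(construct, units, mean, half, n, warns)


# ---------------------------------------------------------------------------
# hypothesis fit and ANOVA


def stoichiometry_hypothesis_fit(
    gels: Union[GelTable, Sequence[GelTable]],
    construct: Construct,
    hypotheses: Iterable[int] = (2, 3, 4),
) -> HypothesisFit:
    """Observed vs expected migration under competing unit-count hypotheses.

    For each hypothesized oligomer size ``n`` the expected normalized
    migration of every complex band is computed from the gel's own standard
    curve (assay II: free-DNA ladder; assay I: lower shifts whose total MW is
    now known because the hypothesis fixes the protein mass) and regressed
    against the observed migration.  The best hypothesis is the one whose
    regression line is closest to the identity line (slope 1, intercept 0,
    by squared deviation).

    Replicate gels may be pooled; the regression needs at least two complex
    bands with distinct expected molecular weights (e.g. shifts on probes
    of different lengths, or lower plus supershifts of tandem fragments).
    """
    hypotheses = sorted(set(int(h) for h in hypotheses))
    if not hypotheses:
        raise ArgumentError("hypotheses must be non-empty")
    gel_list = [gels] if isinstance(gels, GelTable) else list(gels)
    if not gel_list:
        raise ArgumentError("no gels given")
    result = HypothesisFit()
    for n in hypotheses:
        observed: List[float] = []
        exp_d_list: List[float] = []
        for gel in gel_list:
            obs_g, exp_g = _hypothesis_points(gel, construct, n)
            observed.extend(obs_g)
            exp_d_list.extend(exp_g)
        if not observed:
            raise DataError("no complex bands found for hypothesis fit")
        exp_d = np.asarray(exp_d_list)
        obs = np.asarray(observed)
        if np.ptp(exp_d) == 0:
            raise DataError(
                "hypothesis fit needs >= 2 complex bands with distinct "
                "expected MWs (vary fragment length or band type)"
            )
        slope, intercept = np.polyfit(exp_d, obs, 1)
        resid = obs - (intercept + slope * exp_d)
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
        score = (slope - 1.0) ** 2 + intercept**2
        result[n] = {
            "slope": float(slope),
            "intercept": float(intercept),
            "r_squared": r2,
            "score": float(score),
        }
    result.best = min(result, key=lambda h: result[h]["score"])
    return result


def _hypothesis_points(
    gel: GelTable, construct: Construct, n: int
) -> Tuple[List[float], List[float]]:
    """Observed normalized lags and expected lags under hypothesis ``n``."""
    observed: List[float] = []
    expected_mw: List[float] = []
    if gel.assay_mode == "assay2":
        standards = [
            (normalize_migration(lane, BandType.FREE_DNA), lane.fragment.mw)
            for lane in gel.lanes
            if lane.fragment is not None
            and lane.construct is None
            and lane.has_band(BandType.FREE_DNA)
        ]
        if len(standards) < 2:
            raise DataError("hypothesis fit needs a free-DNA ladder")
        curve = fit_standard_curve(standards, anchor_index=0)
        for lane in gel.lanes:
            if lane.construct is None or lane.fragment is None:
                continue
            if lane.construct.name != construct.name:
                continue
            if lane.has_band(BandType.LOWER_SHIFT):
                observed.append(normalize_migration(lane, BandType.LOWER_SHIFT))
                expected_mw.append(complex_mw(lane.fragment, construct, n, 1))
    else:
        standards = []
        for lane in gel.lanes:
            if lane.fragment is None or not lane.has_band(BandType.LOWER_SHIFT):
                continue
            standards.append(
                (
                    normalize_migration(lane, BandType.LOWER_SHIFT),
                    complex_mw(lane.fragment, construct, n, 1),
                )
            )
        if len(standards) < 2:
            raise DataError("hypothesis fit needs >= 2 lower-shift lanes")
        curve = fit_standard_curve(standards, anchor_index=0)
        for lane in gel.lanes:
            if lane.fragment is None:
                continue
            if lane.has_band(BandType.LOWER_SHIFT):
                observed.append(normalize_migration(lane, BandType.LOWER_SHIFT))
                expected_mw.append(complex_mw(lane.fragment, construct, n, 1))
            if lane.has_band(BandType.SUPERSHIFT):
                observed.append(normalize_migration(lane, BandType.SUPERSHIFT))
                expected_mw.append(complex_mw(lane.fragment, construct, n, 2))
    # invert the curve: expected lag at the hypothesized MW
    exp_d = [
        curve.anchor_distance
        + (math.log10(mw / curve.anchor_mw) - curve.intercept) / curve.slope
        for mw in expected_mw
    ]
    return observed, exp_d


def anova_units(results: Sequence[StoichiometryResult]) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA on unit counts grouped by construct.

    Returns ``(F, p)``.  Every group must contribute at least two
    measurements and there must be at least two groups.
    """
    if len(results) < 2:
        raise ArgumentError("ANOVA needs >= 2 construct groups")
    groups = []
    for r in results:
        if len(r.per_measurement_units) < 2:
            raise ArgumentError(
                f"construct {r.construct.name!r} has n < 2 measurements"
            )
        groups.append(np.asarray(r.per_measurement_units, dtype=float))
    means = np.array([g.mean() for g in groups])
    if np.allclose(means, means[0], rtol=0, atol=1e-12):
        return 0.0, 1.0  # no between-group variance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return float(f), float(p)
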