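"""Seeded forward simulators for every assay the package analyses.

Each generator is a pure function of its config, including the integer
seed (``numpy.random.default_rng(seed)``), so identical configs give
byte-identical outputs.  Draw order is fixed and documented per generator,
so cross-language ports can match moments even if not bit streams.

The gel forward model inverts the analysis assumption: migration distance
is linear in log10(MW) with a per-lane offset and per-band Gaussian noise,

    distance = intercept - slope * log10(MW) + offset_lane + eps_band,

clipped at zero.  Reference bands are placed from their own molecular
weights with the same lane offset, so reference-based normalization cancels
the offset exactly.  Default geometry spans the 75-1460 bp fragment range
over roughly 150 gel units (~100 bp resolvable steps); default band noise
is 1% of the standard span, lane offsets 5 gel units — calibration choices,
all config-exposed.

The titration simulator draws the depletion-aware equilibrium fractions
(per-site occupancy for tandem fragments) with multiplicative lognormal
noise renormalized to sum to one; the FCS simulator multiplies the native
particle number by the oligomer order for the denatured curve; the peak
list simulator perturbs the theoretical digest with Gaussian mass error and
appends uniform contaminant peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .binding import TitrationPoint, fraction_bound, site_occupancy, tandem_fractions
from .core import Construct, DnaFragment, complex_mw, dna_mw
from .errors import ArgumentError, ConfigError
from .fcs import AcfCurve, acf_model
from .gel import BandType, GelBand, GelLane, GelTable
from .pmf import tryptic_digest

# Paper-style default designs ------------------------------------------------

#: Assay I single-site standard fragment lengths (bp).
ASSAY1_SINGLE_BP: Tuple[int, ...] = (75, 740, 856, 1053, 1147, 1460)
#: Assay I two-site (tandem) fragment lengths (bp).
ASSAY1_TANDEM_BP: Tuple[int, ...] = (114, 232, 352, 468)
#: Assay II free-DNA ladder lengths (bp).
ASSAY2_LADDER_BP: Tuple[int, ...] = (75, 114, 273, 543, 740)
#: Reference DNA lengths (bp): slow/long and fast/short.
ASSAY1_REFS_BP: Tuple[int, int] = (4368, 220)


@dataclass
class GelSimConfig:
    """Design and noise model for a simulated band-shift gel."""

    assay_mode: str
    construct: Construct
    true_units: int = 3
    standard_fragments: Tuple[DnaFragment, ...] = ()
    tandem_fragments: Tuple[DnaFragment, ...] = ()  # assay1 only
    probe_fragment: Optional[DnaFragment] = None  # assay2 only
    ref_upper_mw: float = dna_mw(ASSAY1_REFS_BP[0])
    ref_lower_mw: float = dna_mw(ASSAY1_REFS_BP[1])
    migration_intercept: float = 430.0  # gel units
    migration_slope: float = 120.0  # gel units per decade of MW
    lane_offset_sd: float = 5.0  # gel units
    band_noise_sd: Optional[float] = None  # gel units; None -> 1% of span
    seed: int = 0
    gel_id: str = "sim"

    def __post_init__(self) -> None:
        if self.assay_mode not in ("assay1", "assay2"):
            raise ConfigError(f"unknown assay_mode {self.assay_mode!r}")
        if self.true_units < 0:
            raise ConfigError("true_units must be >= 0")
        if self.migration_slope <= 0:
            raise ConfigError("migration_slope must be > 0")
        if self.lane_offset_sd < 0 or (
            self.band_noise_sd is not None and self.band_noise_sd < 0
        ):
            raise ConfigError("noise standard deviations must be >= 0")
        if self.assay_mode == "assay2":
            if self.tandem_fragments:
                raise ConfigError("assay2 designs carry no tandem lanes")
            if self.probe_fragment is None:
                raise ConfigError("assay2 design needs a probe_fragment")
            if len(self.standard_fragments) < 3:
                raise ConfigError("assay2 ladder needs >= 3 sizes")
        else:
            if not self.tandem_fragments:
                raise ConfigError("assay1 design needs >= 1 tandem fragment")


def default_assay1_config(
    construct: Construct,
    true_units: int = 3,
    seed: int = 0,
    **overrides,
) -> GelSimConfig:
    """Assay I design: six single-site standards, four tandem fragments."""
    singles = tuple(
        DnaFragment(name=f"single-{bp}", length=bp, n_sites=1)
        for bp in ASSAY1_SINGLE_BP
    )
    tandems = tuple(
        DnaFragment(name=f"tandem-{bp}", length=bp, n_sites=2)
        for bp in ASSAY1_TANDEM_BP
    )
    return GelSimConfig(
        assay_mode="assay1",
        construct=construct,
        true_units=true_units,
        standard_fragments=singles,
        tandem_fragments=tandems,
        seed=seed,
        **overrides,
    )


def default_assay2_config(
    construct: Construct,
    true_units: int = 3,
    seed: int = 0,
    **overrides,
) -> GelSimConfig:
    """Assay II design: five-step free-DNA ladder, one 75-bp probe lane."""
    ladder = tuple(
        DnaFragment(name=f"ladder-{bp}", length=bp, n_sites=0)
        for bp in ASSAY2_LADDER_BP
    )
    probe = DnaFragment(name="probe-75", length=75, n_sites=1)
    return GelSimConfig(
        assay_mode="assay2",
        construct=construct,
        true_units=true_units,
        standard_fragments=ladder,
        probe_fragment=probe,
        ref_lower_mw=dna_mw(75),
        seed=seed,
        **overrides,
    )


def _standard_span(config: GelSimConfig) -> float:
    """Span of noise-free normalized standard distances, gel units."""
    if config.assay_mode == "assay1":
        mws = [
            complex_mw(f, config.construct, config.true_units, 1)
            for f in (*config.standard_fragments, *config.tandem_fragments)
        ]
    else:
        mws = [f.mw for f in config.standard_fragments]
    logs = np.log10(mws)
    return float(config.migration_slope * (logs.max() - logs.min()))


def simulate_gel(config: GelSimConfig) -> GelTable:
    """Simulate one gel from a design; deterministic given the config.

    Draw order: lanes in design order; within a lane one normal for the
    lane offset, then one normal per band in the order (ref_upper,
    ref_lower, species bands).
    """
    rng = np.random.default_rng(config.seed)
    band_sd = (
        0.01 * _standard_span(config)
        if config.band_noise_sd is None
        else config.band_noise_sd
    )

    def distance(mw: float, offset: float) -> float:
        d = (
            config.migration_intercept
            - config.migration_slope * np.log10(mw)
            + offset
            + (rng.normal(0.0, band_sd) if band_sd > 0 else 0.0)
        )
        return max(d, 0.0)

    def make_lane(
        lane_id: str,
        fragment: Optional[DnaFragment],
        construct: Optional[Construct],
        species: Sequence[Tuple[BandType, float]],
    ) -> GelLane:
        offset = rng.normal(0.0, config.lane_offset_sd) if config.lane_offset_sd else 0.0
        bands = [
            GelBand(BandType.REF_UPPER, distance(config.ref_upper_mw, offset)),
            GelBand(BandType.REF_LOWER, distance(config.ref_lower_mw, offset)),
        ]
        bands.extend(GelBand(bt, distance(mw, offset)) for bt, mw in species)
        return GelLane(lane_id=lane_id, fragment=fragment, construct=construct, bands=bands)

    lanes: List[GelLane] = []
    c = config.construct
    n = config.true_units
    if config.assay_mode == "assay1":
        for i, frag in enumerate(config.standard_fragments, start=1):
            lanes.append(
                make_lane(
                    f"std{i}", frag, c,
                    [(BandType.LOWER_SHIFT, complex_mw(frag, c, n, 1))],
                )
            )
        for i, frag in enumerate(config.tandem_fragments, start=1):
            lanes.append(
                make_lane(
                    f"tandem{i}", frag, c,
                    [
                        (BandType.LOWER_SHIFT, complex_mw(frag, c, n, 1)),
                        (BandType.SUPERSHIFT, complex_mw(frag, c, n, 2)),
                    ],
                )
            )
    else:
        for i, frag in enumerate(config.standard_fragments, start=1):
            lanes.append(
                make_lane(f"ladder{i}", frag, None, [(BandType.FREE_DNA, frag.mw)])
            )
        probe = config.probe_fragment
        lanes.append(
            make_lane(
                "probe", probe, c,
                [(BandType.LOWER_SHIFT, complex_mw(probe, c, n, 1))],
            )
        )
    return GelTable(lanes=lanes, assay_mode=config.assay_mode, gel_id=config.gel_id)


# Titrations -----------------------------------------------------------------


@dataclass
class TitrationSimConfig:
    """Equilibrium titration of protein over a constant DNA amount."""

    kd: float = 48.0  # nM
    dna_conc: float = 5.0  # nM (molecules)
    protein_concs: Tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(2.3, 1500.0, 12)
    )
    mode: str = "single"  # "single" | "tandem"
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.dna_conc <= 0:
            raise ConfigError("kd and dna_conc must be > 0")
        if not self.protein_concs:
            raise ConfigError("protein_concs must be non-empty")
        if any(p <= 0 for p in self.protein_concs):
            raise ConfigError("protein concentrations must be > 0")
        if self.mode not in ("single", "tandem"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


def simulate_titration(config: TitrationSimConfig) -> List[TitrationPoint]:
    """Simulate a titration series; deterministic given the config.

    Draw order: one lognormal factor per fraction (unbound, lower, super)
    per point, in protein-concentration order.  Noisy fractions are
    renormalized to sum to one.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    points: List[TitrationPoint] = []
    for p0 in config.protein_concs:
        if config.mode == "single":
            fb = fraction_bound(p0, config.dna_conc, config.kd)
            fracs = np.array([1.0 - fb, fb, 0.0])
        else:
            theta = site_occupancy(p0, config.dna_conc, config.kd)
            fracs = np.array(tandem_fractions(theta))
        if config.noise_cv > 0:
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=3)
            fracs = fracs * factors
            fracs = fracs / fracs.sum()
        points.append(
            TitrationPoint(
                protein_conc=float(p0),
                dna_conc=float(config.dna_conc),
                fraction_unbound=float(fracs[0]),
                fraction_lower=float(fracs[1]),
                fraction_super=float(fracs[2]),
            )
        )
    return points


# FCS ------------------------------------------------------------------------


@dataclass
class AcfSimConfig:
    """Paired native/denatured autocorrelation curves of one replicate."""

    n_native: float = 0.3
    tau_d_native: float = 1e-3  # s
    tau_d_denatured: float = 4e-4  # s (urea changes viscosity and size)
    oligomer_order: int = 3
    kappa: float = 5.0
    lag_grid: Tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(1e-6, 1.0, 120)
    )
    noise_rel_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_native <= 0 or self.tau_d_native <= 0 or self.tau_d_denatured <= 0:
            raise ConfigError("particle number and diffusion times must be > 0")
        if self.oligomer_order < 1:
            raise ConfigError("oligomer_order must be >= 1")
        if self.kappa < 1:
            raise ConfigError("kappa must be >= 1")
        lags = np.asarray(self.lag_grid)
        if lags.size < 2 or np.any(np.diff(lags) <= 0):
            raise ConfigError("lag_grid must be strictly increasing")
        if self.noise_rel_sd < 0:
            raise ConfigError("noise_rel_sd must be >= 0")


def simulate_acf(config: AcfSimConfig) -> Tuple[AcfCurve, AcfCurve]:
    """Simulate a native/denatured curve pair; deterministic given config.

    The denatured particle number is ``oligomer_order * n_native`` (each
    oligomer dissociates into its monomers).  Additive Gaussian noise with
    per-point sd ``noise_rel_sd * G(tau)``; draw order: native curve noise
    first, then denatured.
    """
    rng = np.random.default_rng(config.seed)
    lags = np.asarray(config.lag_grid, dtype=float)

    def make(n: float, tau_d: float, condition: str) -> AcfCurve:
        g = acf_model(lags, n, tau_d, config.kappa)
        if config.noise_rel_sd > 0:
            g = g + rng.normal(0.0, config.noise_rel_sd * g)
        return AcfCurve(lags=lags, g=g, condition=condition, label=f"sim-{condition}")

    native = make(config.n_native, config.tau_d_native, "native")
    denatured = make(
        config.oligomer_order * config.n_native,
        config.tau_d_denatured,
        "denatured",
    )
    return native, denatured


# PMF ------------------------------------------------------------------------


def simulate_peaklist(
    protein_seq: str,
    mass_error_sd: float = 0.05,
    n_contaminants: int = 4,
    mz_range: Tuple[float, float] = (800.0, 3500.0),
    seed: int = 0,
    max_missed_cleavages: int = 0,
) -> np.ndarray:
    """Simulate an observed MALDI peak list from a protein sequence.

    Theoretical tryptic [M+H]+ masses inside ``mz_range`` are perturbed by
    N(0, mass_error_sd^2) (one draw per peptide in digest order), then
    ``n_contaminants`` uniform peaks in ``mz_range`` are appended; the
    result is sorted.  Deterministic given the seed.
    """
    if mass_error_sd < 0:
        raise ArgumentError("mass_error_sd must be >= 0")
    if n_contaminants < 0:
        raise ArgumentError("n_contaminants must be >= 0")
    lo, hi = mz_range
    if not lo < hi:
        raise ArgumentError(f"invalid mz_range {mz_range}")
    rng = np.random.default_rng(seed)
    peptides = tryptic_digest(protein_seq, max_missed_cleavages)
    mzs = [p.mz_mh for p in peptides if lo <= p.mz_mh <= hi]
    peaks = np.asarray(mzs, dtype=float)
    if mass_error_sd > 0 and peaks.size:
        peaks = peaks + rng.normal(0.0, mass_error_sd, size=peaks.size)
    if n_contaminants:
        peaks = np.concatenate([peaks, rng.uniform(lo, hi, size=n_contaminants)])
    return np.sort(peaks)
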