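"""Equilibrium models for sequence-specific protein-DNA binding.

The single-site model is the exact two-component equilibrium ("receptor-
ligand binding in solution"): with total protein ``p0``, total DNA ``d0``
and dissociation constant ``kd`` the fraction of DNA bound solves a
quadratic that accounts for ligand depletion,

    FB = ((p0 + d0 + kd) - sqrt((p0 + d0 + kd)^2 - 4 p0 d0)) / (2 d0),

which reduces to the hyperbola ``p0 / (p0 + kd)`` in the dilute-DNA limit.
Two-site (tandem) fragments are modelled as two independent, identical
sites, giving binomial occupancy fractions for the unbound, single-complex
(lower shift) and double-complex (supershift) populations.

Band-pattern enumeration covers the two competing topologies for a
multimeric binder offered a mixture of differently sized target fragments:
either each oligomer engages exactly one DNA molecule (two shifts, four
bands for two fragments) or it bridges two (three shifts, five bands), plus
the restriction-digest rearrangement that splits a doubly occupied tandem
fragment into two independently shifted products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize

from .core import Construct, DnaFragment, complex_mw, dna_mw
from .errors import ArgumentError, DataError, FitError


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a protein-over-DNA titration (concentrations in nM)."""

    protein_conc: float
    dna_conc: float
    fraction_unbound: float
    fraction_lower: Optional[float] = None
    fraction_super: Optional[float] = None

    def __post_init__(self) -> None:
        if self.protein_conc < 0 or self.dna_conc <= 0:
            raise ArgumentError(
                "protein_conc must be >= 0 and dna_conc > 0 "
                f"(got {self.protein_conc}, {self.dna_conc})"
            )


@dataclass(frozen=True)
class KdFit:
    kd: float  # nM
    se: float  # nM
    residual_ss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ArgumentError(f"kd must be > 0, got {self.kd}")


@dataclass
class BandPattern:
    """Distinct electrophoretic species and their molecular weights."""

    species: List[Tuple[str, float]]  # (description, mw_kd)

    @property
    def n_bands(self) -> int:
        return len({round(mw, 6) for _, mw in self.species})


def fraction_bound(p0, d0: float, kd: float):
    """Fraction of DNA bound at equilibrium with ligand depletion.

    Uses the algebraically stable root ``2 p0 / (b + sqrt(b^2 - 4 p0 d0))``
    with ``b = p0 + d0 + kd`` (no catastrophic cancellation for
    concentrations spanning many decades).  ``d0 == 0`` falls back to the
    hyperbolic limit.  Accepts scalar or array ``p0``.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0):
        raise ArgumentError("protein concentration must be >= 0")
    if d0 < 0 or kd <= 0:
        raise ArgumentError(f"need d0 >= 0 and kd > 0, got d0={d0}, kd={kd}")
    if d0 == 0:
        fb = p0 / (p0 + kd)
    else:
        b = p0 + d0 + kd
        disc = np.maximum(b * b - 4.0 * p0 * d0, 0.0)
        fb = 2.0 * p0 / (b + np.sqrt(disc))
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def tandem_fractions(theta: float) -> Tuple[float, float, float]:
    """Population fractions of a two-site fragment at per-site occupancy θ.

    Two independent identical sites give ``((1-θ)^2, 2θ(1-θ), θ^2)`` for
    (unbound, lower shift, supershift); the lower-shift fraction peaks at
    0.5 when half the sites are filled.
    """
    if not 0.0 <= theta <= 1.0:
        raise ArgumentError(f"theta must be in [0, 1], got {theta}")
    return ((1 - theta) ** 2, 2 * theta * (1 - theta), theta**2)


def site_occupancy(p0, d0_molecules: float, kd: float):
    """Per-site occupancy θ of a two-site fragment under depletion.

    Treats the sites as a ligand pool of concentration ``2 * d0_molecules``
    competing for the same protein: ``θ = fraction_bound(p0, 2 d0, kd)``.
    """
    return fraction_bound(p0, 2.0 * d0_molecules, kd)


def fit_kd(
    points: Sequence[TitrationPoint],
    mode: str = "single",
    active_fraction: float = 1.0,
) -> KdFit:
    """Least-squares dissociation constant from a titration series.

    ``mode="single"`` fits ``1 - fraction_unbound``;  ``mode="tandem_sum"``
    fits ``fraction_lower + fraction_super`` (the summed shifts of a
    two-site fragment) with the same depletion-aware single-species model,
    i.e. an *effective* K_D, mirroring how tandem titrations are commonly
    summarized.  ``active_fraction`` rescales nominal (lysate) protein
    concentrations.
    """
    if mode not in ("single", "tandem_sum"):
        raise ArgumentError(f"unknown mode {mode!r}")
    if not points:
        raise DataError("empty titration series")
    if len(points) < 3:
        raise DataError(f"need >= 3 titration points, got {len(points)}")
    p0 = np.array([pt.protein_conc for pt in points], dtype=float) * active_fraction
    d0 = np.array([pt.dna_conc for pt in points], dtype=float)
    if mode == "single":
        y = 1.0 - np.array([pt.fraction_unbound for pt in points], dtype=float)
    else:
        if any(pt.fraction_lower is None or pt.fraction_super is None for pt in points):
            raise DataError("tandem_sum mode requires lower/super fractions")
        y = np.array(
            [pt.fraction_lower + pt.fraction_super for pt in points], dtype=float
        )
    if np.all(y < 1e-6) or np.all(y > 1 - 1e-6):
        raise FitError("titration response is flat (all ~0 or all ~1)")

    def _model(p, kd):
        b = p + d0 + kd
        disc = np.maximum(b * b - 4.0 * p * d0, 0.0)
        return 2.0 * p / (b + np.sqrt(disc))

    # initial guess: protein concentration at half response
    order = np.argsort(p0)
    kd0 = float(np.interp(0.5, np.clip(y[order], 0, 1), p0[order]))
    if not np.isfinite(kd0) or kd0 <= 0:
        kd0 = float(np.median(p0[p0 > 0])) if np.any(p0 > 0) else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _model, p0, y, p0=[kd0], bounds=(1e-12, np.inf), maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message path
        raise FitError(f"K_D fit did not converge: {exc}") from exc
    kd_hat = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    resid = y - _model(p0, kd_hat)
    return KdFit(kd=kd_hat, se=se, residual_ss=float(resid @ resid), n_points=len(points))


def predict_band_pattern(
    model: str,
    fragments: Sequence[DnaFragment],
    construct: Construct,
    n_units: int,
) -> BandPattern:
    """Enumerate distinct bands for a mixture of target fragments.

    ``model="one_dna_per_complex"``: each oligomer binds exactly one DNA
    molecule — the pattern is every free fragment plus one shifted complex
    per fragment (2 x #fragments bands).  ``model="multi_dna_per_complex"``:
    the oligomer bridges two DNA molecules — free fragments plus every
    unordered fragment pair (for two fragments: 2 + 3 = 5 bands).
    Fragments without binding sites are excluded with a warning.
    """
    if model not in ("one_dna_per_complex", "multi_dna_per_complex"):
        raise ArgumentError(f"unknown model {model!r}")
    usable: List[DnaFragment] = []
    for f in fragments:
        if f.n_sites < 1:
            warnings.warn(
                f"fragment {f.name!r} has no binding site; excluded", stacklevel=2
            )
            continue
        usable.append(f)
    names = {f.name for f in usable}
    if not 1 <= len(names) <= 2:
        raise ArgumentError(
            f"need 1-2 distinct fragments with binding sites, got {len(names)}"
        )
    species: List[Tuple[str, float]] = [
        (f"free {f.name}", dna_mw(f.length)) for f in usable
    ]
    protein = n_units * construct.monomer_mw
    if model == "one_dna_per_complex":
        for f in usable:
            species.append(
                (f"{construct.name} + {f.name}", complex_mw(f, construct, n_units, 1))
            )
    else:
        for i, f1 in enumerate(usable):
            for f2 in usable[i:]:
                mw = dna_mw(f1.length) + dna_mw(f2.length) + protein
                species.append((f"{construct.name} + {f1.name} + {f2.name}", mw))
    return BandPattern(species=species)


def digest_rearrangement(
    fragment: DnaFragment,
    bound_state: str,
    *,
    construct: Construct,
    n_units: int,
) -> BandPattern:
    """Band pattern after cutting a tandem fragment at its internal site.

    A free fragment yields its two free products; a supershift (two
    independent oligomers, one per site) yields one single complex on each
    product, migrating as the corresponding one-site shifts; a lower shift
    (one oligomer on either site) yields a mixture of each free product and
    each singly shifted product.
    """
    if not fragment.has_internal_cut_site:
        raise ArgumentError(f"fragment {fragment.name!r} has no internal cut site")
    if bound_state not in ("free", "lower", "super"):
        raise ArgumentError(f"unknown bound_state {bound_state!r}")
    products = [
        DnaFragment(name=f"{fragment.name}-cut{i + 1}", length=bp, n_sites=1)
        for i, bp in enumerate(fragment.cut_products)
    ]
    species: List[Tuple[str, float]] = []
    if bound_state == "free":
        species = [(f"free {p.name}", dna_mw(p.length)) for p in products]
    elif bound_state == "super":
        species = [
            (f"{construct.name} + {p.name}", complex_mw(p, construct, n_units, 1))
            for p in products
        ]
    else:  # lower: the single oligomer sits on one of the two sites
        for p in products:
            species.append((f"free {p.name}", dna_mw(p.length)))
            species.append(
                (f"{construct.name} + {p.name}", complex_mw(p, construct, n_units, 1))
            )
    return BandPattern(species=species)
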