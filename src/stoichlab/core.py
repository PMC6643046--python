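"""Shared domain entities and molecular-weight arithmetic.

A *construct* is a recombinant protein variant (zinc-finger array with
optional tags) characterized by its monomer molecular weight in kilodaltons.
A *fragment* is a double-stranded DNA molecule carrying zero, one, or two
specific binding sites.  A *complex* is one or two protein oligomers bound to
a fragment.  All downstream assays reduce to arithmetic on the molecular
weights of these species, so the conversions live here.

Molecular weights are in kilodaltons (kD) throughout; DNA lengths in base
pairs (bp).  dsDNA mass uses the standard sodium-salt average of 0.650 kD/bp;
the ~0.6 kD biotin label is negligible at gel resolution and is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .errors import ArgumentError

#: Average mass of one double-stranded base pair (sodium salt), kD.
DNA_KD_PER_BP: float = 0.650

_EXPRESSION_SYSTEMS = {"bacterial_SN", "bacterial_WC", "IVE", "semipure"}


@dataclass(frozen=True)
class Construct:
    """A protein construct with a known monomer molecular weight.

    Monomer MWs are inputs (taken from the construct table of the study
    design), never computed from sequence.  ``pi`` (theoretical isoelectric
    point) is carried as metadata only.
    """

    name: str
    monomer_mw: float  # kD
    tags: Tuple[str, ...] = ()
    expression_system: Optional[str] = None
    pi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.monomer_mw <= 0:
            raise ArgumentError(f"monomer_mw must be > 0, got {self.monomer_mw}")
        if (
            self.expression_system is not None
            and self.expression_system not in _EXPRESSION_SYSTEMS
        ):
            raise ArgumentError(
                f"unknown expression_system {self.expression_system!r}; "
                f"expected one of {sorted(_EXPRESSION_SYSTEMS)}"
            )
        object.__setattr__(self, "tags", tuple(self.tags))


@dataclass(frozen=True)
class DnaFragment:
    """A dsDNA fragment with 0-2 specific protein-binding sites.

    ``cut_products`` are the two product lengths of an internal restriction
    site; they must sum to the fragment length (the site design absorbs the
    recognition-sequence overlap, e.g. 75 + 157 = 232).
    """

    name: str
    length: int  # bp
    n_sites: int = 1
    has_internal_cut_site: bool = False
    cut_products: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ArgumentError(f"fragment length must be > 0, got {self.length}")
        if self.n_sites not in (0, 1, 2):
            raise ArgumentError(f"n_sites must be 0, 1 or 2, got {self.n_sites}")
        if self.has_internal_cut_site:
            if self.cut_products is None or len(self.cut_products) != 2:
                raise ArgumentError(
                    f"fragment {self.name!r}: has_internal_cut_site requires "
                    "a pair of cut_products"
                )
            if sum(self.cut_products) != self.length:
                raise ArgumentError(
                    f"fragment {self.name!r}: cut_products "
                    f"{self.cut_products} must sum to length {self.length}"
                )
            object.__setattr__(self, "cut_products", tuple(self.cut_products))

    @property
    def mw(self) -> float:
        """Molecular weight of the bare fragment, kD."""
        return dna_mw(self.length)


@dataclass(frozen=True)
class Complex:
    """One or two protein oligomers bound to a DNA fragment.

    ``n_units`` is the monomer count per bound oligomer; ``n_complexes`` is
    the number of oligomers on the fragment (1 for a lower shift, 2 for a
    supershift, 0 for free DNA).
    """

    fragment: DnaFragment
    construct: Construct
    n_units: int
    n_complexes: int = 1

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ArgumentError(f"n_units must be >= 0, got {self.n_units}")
        if self.n_complexes not in (0, 1, 2):
            raise ArgumentError(
                f"n_complexes must be 0, 1 or 2, got {self.n_complexes}"
            )

    @property
    def mw(self) -> float:
        return complex_mw(self.fragment, self.construct, self.n_units, self.n_complexes)


def dna_mw(length: float, kd_per_bp: float = DNA_KD_PER_BP) -> float:
    """Molecular weight of a dsDNA fragment of ``length`` base pairs, in kD.

    Parameters
    ----------
    length
        Fragment length in bp; must be positive.
    kd_per_bp
        Mass per base pair, kD.  Default 0.650 (sodium-salt dsDNA average).
    """
    if length <= 0:
        raise ArgumentError(f"DNA length must be > 0 bp, got {length}")
    if kd_per_bp <= 0:
        raise ArgumentError(f"kd_per_bp must be > 0, got {kd_per_bp}")
    return length * kd_per_bp


def complex_mw(
    fragment: DnaFragment,
    construct: Construct,
    n_units: int,
    n_complexes: int = 1,
) -> float:
    """Molecular weight of a protein-DNA complex, in kD.

    The complex mass is the DNA mass plus ``n_complexes`` bound oligomers of
    ``n_units`` monomers each::

        MW = dna_mw(fragment.length) + n_complexes * n_units * monomer_mw

    With ``n_units == 0`` or ``n_complexes == 0`` this reduces to the free
    DNA mass.
    """
    if n_units < 0:
        raise ArgumentError(f"n_units must be >= 0, got {n_units}")
    if n_complexes < 0:
        raise ArgumentError(f"n_complexes must be >= 0, got {n_complexes}")
    return dna_mw(fragment.length) + n_complexes * n_units * construct.monomer_mw
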