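"""In-silico tryptic digestion and peptide-mass-fingerprint matching.

Verifies protein identity the way an in-gel digest / MALDI-TOF workflow
does: cleave the sequence with trypsin (after K or R, never before P),
compute singly protonated monoisotopic peptide masses with fixed
carbamidomethylation of cysteine (+57.02146 Da from iodoacetamide
alkylation), match an observed peak list within a mass tolerance, and
report sequence coverage as the union of matched peptide spans.  a/b/y
fragment-ion ladders support MS/MS confirmation of individual peptides.

Masses are monoisotopic throughout (standard IUPAC residue masses to five
decimals); only singly charged [M+H]+ ions are considered (MALDI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ArgumentError, DataError

#: Monoisotopic residue masses, Da.
MONOISOTOPIC: Dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276
CO = 27.994915
#: Carbamidomethyl (iodoacetamide) fixed modification on cysteine, Da.
CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based inclusive position in the parent protein
    end: int
    missed_cleavages: int
    mz_mh: float  # [M+H]+ monoisotopic, Da


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "a" | "b" | "y"
    index: int
    mz: float


@dataclass
class PmfMatchResult:
    matched: List[Tuple[float, Peptide, float]]  # (observed, peptide, delta Da)
    unmatched_observed: List[float]
    coverage_percent: float
    tolerance: float


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ArgumentError("empty protein/peptide sequence")
    bad = [i + 1 for i, aa in enumerate(seq) if aa not in MONOISOTOPIC]
    if bad:
        raise ArgumentError(
            f"invalid residues at positions {bad} in sequence {sequence[:30]!r}..."
        )
    return seq


def peptide_mz(sequence: str, carbamidomethyl: bool = True) -> float:
    """Monoisotopic [M+H]+ of a peptide, Da.

    Sum of residue masses plus water plus one proton, with +57.02146 Da per
    cysteine when carbamidomethylation is enabled (the default).
    """
    seq = _validate_sequence(sequence)
    mass = sum(MONOISOTOPIC[aa] for aa in seq) + WATER + PROTON
    if carbamidomethyl:
        mass += CARBAMIDOMETHYL * seq.count("C")
    return mass


def tryptic_digest(
    protein_seq: str,
    max_missed_cleavages: int = 0,
    carbamidomethyl: bool = True,
) -> List[Peptide]:
    """Tryptic peptides of a protein with 0..max missed cleavages.

    Cleaves C-terminal to K or R except when the next residue is P (the
    classical Keil rule).  Zero-missed-cleavage peptides partition the
    input; higher missed-cleavage peptides are concatenations of adjacent
    fully cleaved pieces.
    """
    seq = _validate_sequence(protein_seq)
    if max_missed_cleavages < 0:
        raise ArgumentError("max_missed_cleavages must be >= 0")
    cut_after = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(seq)]
    pieces = [
        (boundaries[j], boundaries[j + 1]) for j in range(len(boundaries) - 1)
    ]
    peptides: List[Peptide] = []
    for j, (start, _) in enumerate(pieces):
        for mc in range(max_missed_cleavages + 1):
            if j + mc >= len(pieces):
                break
            end = pieces[j + mc][1]
            sub = seq[start:end]
            peptides.append(
                Peptide(
                    sequence=sub,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                    mz_mh=peptide_mz(sub, carbamidomethyl),
                )
            )
    return peptides


def pmf_match(
    observed_peaks: Sequence[float],
    peptides: Sequence[Peptide],
    tolerance: float = 0.25,
    protein_length: Optional[int] = None,
) -> PmfMatchResult:
    """Assign observed m/z peaks to theoretical peptides within a tolerance.

    Each peak takes the nearest theoretical mass within ``tolerance`` Da
    (ties broken by smaller |delta|, then by lower missed-cleavage count);
    deltas are reported signed (observed minus theoretical).  Coverage is
    the union of the matched peptides' position spans as a percentage of
    the protein length (inferred from the digest when not given) and is
    invariant to peak-list order.

    The default tolerance of 0.25 Da accommodates MALDI calibration offsets
    of up to ~0.1 Da between measured and theoretical monoisotopic masses.
    """
    if tolerance <= 0:
        raise ArgumentError(f"tolerance must be > 0, got {tolerance}")
    if not peptides:
        raise DataError("empty theoretical peptide list")
    length = protein_length if protein_length is not None else max(p.end for p in peptides)
    matched: List[Tuple[float, Peptide, float]] = []
    unmatched: List[float] = []
    for mz in observed_peaks:
        candidates = [
            (abs(mz - p.mz_mh), p.missed_cleavages, p) for p in peptides
        ]
        delta_abs, _, best = min(candidates, key=lambda c: (c[0], c[1]))
        if delta_abs <= tolerance:
            matched.append((float(mz), best, float(mz - best.mz_mh)))
        else:
            unmatched.append(float(mz))
    intervals = sorted((p.start, p.end) for _, p, _ in matched)
    covered = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for s, e in intervals:
        if cur_start is None or s > cur_end + 1:
            if cur_start is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        covered += cur_end - cur_start + 1
    coverage = 100.0 * covered / length
    return PmfMatchResult(
        matched=matched,
        unmatched_observed=unmatched,
        coverage_percent=min(coverage, 100.0),
        tolerance=tolerance,
    )


def fragment_ions(peptide_seq: str, carbamidomethyl: bool = True) -> List[FragmentIon]:
    """Singly charged a/b/y fragment-ion ladders of a peptide.

    For i = 1..L-1:  b_i = sum of the first i residues + proton;
    a_i = b_i - CO;  y_i = sum of the last i residues + water + proton.
    The complementarity b_i + y_(L-i) = [M+H]+ + proton holds exactly.
    """
    seq = _validate_sequence(peptide_seq)
    if len(seq) < 2:
        raise ArgumentError("peptide must have length >= 2 for fragment ions")

    def res_mass(aa: str) -> float:
        m = MONOISOTOPIC[aa]
        if carbamidomethyl and aa == "C":
            m += CARBAMIDOMETHYL
        return m

    ions: List[FragmentIon] = []
    prefix = 0.0
    for i in range(1, len(seq)):
        prefix += res_mass(seq[i - 1])
        b = prefix + PROTON
        ions.append(FragmentIon("b", i, b))
        ions.append(FragmentIon("a", i, b - CO))
    suffix = 0.0
    for i in range(1, len(seq)):
        suffix += res_mass(seq[len(seq) - i])
        ions.append(FragmentIon("y", i, suffix + WATER + PROTON))
    return ions
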