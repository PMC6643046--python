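"""Readers and writers for the package's plain-text formats.

* Band tables: TSV, one row per band, columns
  ``gel_id, lane_id, fragment_name, construct_name, band_type, distance,
  intensity``.
* Titrations: TSV with ``protein_conc_nM, dna_conc_nM, frac_unbound,
  frac_lower, frac_super`` (last two optional).
* Autocorrelation curves: CSV with ``lag_s, g, condition, replicate``.
* Proteins: FASTA (via Biopython).
* Observed peaks: two-column whitespace/TSV text ``mz [intensity]``.
* Run configuration and reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import TitrationPoint
from .core import Construct, DnaFragment
from .errors import DataError
from .fcs import AcfCurve
from .gel import BandType, GelBand, GelLane, GelTable

BAND_COLUMNS = [
    "gel_id",
    "lane_id",
    "fragment_name",
    "construct_name",
    "band_type",
    "distance",
    "intensity",
]


def write_band_table(
    tables: Union[GelTable, Sequence[GelTable]], path: Union[str, Path]
) -> None:
    """Serialize one or more gels to the band-table TSV format."""
    if isinstance(tables, GelTable):
        tables = [tables]
    rows = []
    for table in tables:
        for lane in table.lanes:
            for band in lane.bands:
                rows.append(
                    {
                        "gel_id": table.gel_id,
                        "lane_id": lane.lane_id,
                        "fragment_name": lane.fragment.name if lane.fragment else "",
                        "construct_name": lane.construct.name if lane.construct else "",
                        "band_type": band.band_type.value,
                        "distance": band.distance,
                        "intensity": "" if band.intensity is None else band.intensity,
                    }
                )
    pd.DataFrame(rows, columns=BAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_band_table(
    path: Union[str, Path],
    fragments: Mapping[str, DnaFragment],
    constructs: Mapping[str, Construct],
    assay_mode: str = "assay1",
) -> List[GelTable]:
    """Parse a band-table TSV into validated :class:`GelTable` objects.

    ``fragments`` and ``constructs`` resolve the name columns to domain
    objects.  Schema violations raise :class:`DataError` naming the
    offending row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"band table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"band table {path} is empty") from exc
    missing = [c for c in BAND_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"band table {path} missing columns: {missing}")
    if df.empty:
        raise DataError(f"band table {path} has no data rows")

    valid_types = {bt.value for bt in BandType}
    # group rows per (gel, lane) preserving file order
    lanes_by_gel: Dict[str, Dict[str, dict]] = {}
    gel_order: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.band_type not in valid_types:
            raise DataError(
                f"band table {path} row {i}: unknown band_type {row.band_type!r} "
                f"(expected one of {sorted(valid_types)})"
            )
        try:
            distance = float(row.distance)
        except ValueError:
            raise DataError(
                f"band table {path} row {i}: non-numeric distance {row.distance!r}"
            ) from None
        intensity = None
        if str(row.intensity).strip() != "":
            try:
                intensity = float(row.intensity)
            except ValueError:
                raise DataError(
                    f"band table {path} row {i}: non-numeric intensity "
                    f"{row.intensity!r}"
                ) from None
        fragment = None
        if row.fragment_name:
            if row.fragment_name not in fragments:
                raise DataError(
                    f"band table {path} row {i}: unknown fragment "
                    f"{row.fragment_name!r}"
                )
            fragment = fragments[row.fragment_name]
        construct = None
        if row.construct_name:
            if row.construct_name not in constructs:
                raise DataError(
                    f"band table {path} row {i}: unknown construct "
                    f"{row.construct_name!r}"
                )
            construct = constructs[row.construct_name]
        gel = lanes_by_gel.setdefault(row.gel_id, {})
        if row.gel_id not in gel_order:
            gel_order.append(row.gel_id)
        lane = gel.setdefault(
            row.lane_id,
            {"fragment": fragment, "construct": construct, "bands": [], "row": i},
        )
        if fragment is not None and lane["fragment"] is None:
            lane["fragment"] = fragment
        if (
            lane["fragment"] is not None
            and fragment is not None
            and lane["fragment"].name != fragment.name
        ):
            raise DataError(
                f"band table {path} row {i}: lane {row.lane_id!r} mixes fragments"
            )
        if band_is_ref := row.band_type in ("ref_upper", "ref_lower"):
            if any(b.band_type.value == row.band_type for b in lane["bands"]):
                raise DataError(
                    f"band table {path} row {i}: duplicate {row.band_type} in lane "
                    f"{row.lane_id!r}"
                )
        lane["bands"].append(GelBand(BandType(row.band_type), distance, intensity))

    tables = []
    for gel_id in gel_order:
        lanes = [
            GelLane(
                lane_id=lane_id,
                fragment=spec["fragment"],
                construct=spec["construct"],
                bands=spec["bands"],
            )
            for lane_id, spec in lanes_by_gel[gel_id].items()
        ]
        tables.append(GelTable(lanes=lanes, assay_mode=assay_mode, gel_id=gel_id))
    return tables


# Titrations -----------------------------------------------------------------


def write_titration(points: Sequence[TitrationPoint], path: Union[str, Path]) -> None:
    rows = [
        {
            "protein_conc_nM": p.protein_conc,
            "dna_conc_nM": p.dna_conc,
            "frac_unbound": p.fraction_unbound,
            "frac_lower": "" if p.fraction_lower is None else p.fraction_lower,
            "frac_super": "" if p.fraction_super is None else p.fraction_super,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_titration(path: Union[str, Path]) -> List[TitrationPoint]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"titration table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"protein_conc_nM", "dna_conc_nM", "frac_unbound"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"titration table {path} missing columns: {sorted(missing)}")

    def opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    return [
        TitrationPoint(
            protein_conc=float(row["protein_conc_nM"]),
            dna_conc=float(row["dna_conc_nM"]),
            fraction_unbound=float(row["frac_unbound"]),
            fraction_lower=opt(row, "frac_lower"),
            fraction_super=opt(row, "frac_super"),
        )
        for _, row in df.iterrows()
    ]


# FCS ------------------------------------------------------------------------


def write_acf_curves(
    curves: Sequence[Tuple[AcfCurve, str]], path: Union[str, Path]
) -> None:
    """Write ``(curve, replicate_id)`` pairs to the ACF CSV format."""
    frames = []
    for curve, replicate in curves:
        frames.append(
            pd.DataFrame(
                {
                    "lag_s": curve.lags,
                    "g": curve.g,
                    "condition": curve.condition,
                    "replicate": replicate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_acf_curves(path: Union[str, Path]) -> Dict[Tuple[str, str], AcfCurve]:
    """Read the ACF CSV; returns ``{(replicate, condition): AcfCurve}``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"ACF file not found: {path}")
    df = pd.read_csv(path, dtype={"replicate": str})
    missing = {"lag_s", "g", "condition", "replicate"} - set(df.columns)
    if missing:
        raise DataError(f"ACF file {path} missing columns: {sorted(missing)}")
    curves: Dict[Tuple[str, str], AcfCurve] = {}
    for (rep, cond), grp in df.groupby(["replicate", "condition"], sort=False):
        grp = grp.sort_values("lag_s")
        curves[(str(rep), str(cond))] = AcfCurve(
            lags=grp["lag_s"].to_numpy(),
            g=grp["g"].to_numpy(),
            condition=str(cond),
            label=f"{rep}/{cond}",
        )
    return curves


# Proteins and peaks ---------------------------------------------------------


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read a protein FASTA file into ``{record_id: sequence}``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise DataError(f"FASTA file {path} contains no records")
    return records


def read_peaklist(path: Union[str, Path]) -> np.ndarray:
    """Read a two-column ``mz [intensity]`` peak list; returns sorted m/z."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak list not found: {path}")
    mzs = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            mzs.append(float(fields[0]))
        except ValueError:
            raise DataError(f"peak list {path} line {i}: non-numeric m/z") from None
    if not mzs:
        raise DataError(f"peak list {path} contains no peaks")
    return np.sort(np.asarray(mzs))


def write_peaklist(mzs: Sequence[float], path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{mz:.5f}\n" for mz in mzs))


# Config ---------------------------------------------------------------------


def parse_constructs(entries: Sequence[dict]) -> Dict[str, Construct]:
    out: Dict[str, Construct] = {}
    for e in entries:
        c = Construct(
            name=e["name"],
            monomer_mw=float(e["monomer_mw_kd"]),
            tags=tuple(e.get("tags", ())),
            expression_system=e.get("expression_system"),
            pi=e.get("pi"),
        )
        if c.name in out:
            raise DataError(f"duplicate construct name {c.name!r}")
        out[c.name] = c
    return out


def parse_fragments(entries: Sequence[dict]) -> Dict[str, DnaFragment]:
    out: Dict[str, DnaFragment] = {}
    for e in entries:
        f = DnaFragment(
            name=e["name"],
            length=int(e["length_bp"]),
            n_sites=int(e.get("n_sites", 1)),
            has_internal_cut_site=bool(e.get("has_internal_cut_site", False)),
            cut_products=tuple(e["cut_products"]) if e.get("cut_products") else None,
        )
        if f.name in out:
            raise DataError(f"duplicate fragment name {f.name!r}")
        out[f.name] = f
    return out


def read_config(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    return json.loads(path.read_text())
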