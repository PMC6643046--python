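"""End-to-end pipeline: configuration, stage orchestration, JSON reports.

A run configuration is a JSON document declaring the study entities
(constructs, fragments) and up to four analysis blocks — ``gel``,
``titration``, ``fcs``, ``pmf`` — each of which either points at input
files or at a ``simulate`` block consumed by :mod:`stoichlab.simulate`.
Stages run in that order; the report collects their numeric results plus
provenance (config hash, seed, package version) and accumulated warnings.
Reports are deterministic given the config including the seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Union

from . import __version__
from .binding import fit_kd
from .errors import ConfigError, DataError, StoichlabError
from .fcs import fit_acf, oligomer_ratio
from .gel import assay1_stoichiometry, assay2_stoichiometry
from .io import (
    parse_constructs,
    parse_fragments,
    read_acf_curves,
    read_band_table,
    read_fasta,
    read_peaklist,
    read_titration,
)
from .pmf import pmf_match, tryptic_digest
from .simulate import (
    AcfSimConfig,
    GelSimConfig,
    TitrationSimConfig,
    default_assay1_config,
    default_assay2_config,
    simulate_acf,
    simulate_gel,
    simulate_peaklist,
    simulate_titration,
)


class StageError(StoichlabError):
    """A pipeline stage failed; the message names the stage and its input."""


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _nan_to_none(x: float) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def run_pipeline(
    config: dict,
    base_dir: Union[str, Path] = ".",
    seed: Optional[int] = None,
) -> dict:
    """Execute the stages requested by ``config`` and return the report.

    ``base_dir`` resolves relative input paths; ``seed`` overrides the
    config's seed for every simulated input.
    """
    base = Path(base_dir)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    constructs = parse_constructs(config.get("constructs", []))
    fragments = parse_fragments(config.get("fragments", []))
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "stoichlab_version": __version__,
        },
        "warnings": [],
    }

    if "gel" in config:
        report["gel"] = _gel_stage(config["gel"], constructs, fragments, base, seed, report)
    if "titration" in config:
        report["titration"] = _titration_stage(config["titration"], base, seed)
    if "fcs" in config:
        report["fcs"] = _fcs_stage(config["fcs"], base, seed)
    if "pmf" in config:
        report["pmf"] = _pmf_stage(config["pmf"], base, seed)
    return report


def _gel_stage(block, constructs, fragments, base, seed, report) -> dict:
    try:
        mode = block.get("mode", "assay1")
        construct = constructs[block["construct"]]
        if "simulate" in block:
            sim = dict(block["simulate"])
            sim.setdefault("seed", seed)
            true_units = int(sim.pop("true_units", 3))
            factory = default_assay1_config if mode == "assay1" else default_assay2_config
            cfg = factory(construct, true_units=true_units, **sim)
            gels = [simulate_gel(cfg)]
            probe = cfg.probe_fragment
        else:
            gels = read_band_table(
                base / block["band_table"], fragments, constructs, assay_mode=mode
            )
            probe = fragments[block["probe_fragment"]] if "probe_fragment" in block else None
        if mode == "assay1":
            results = [assay1_stoichiometry(g, construct) for g in gels]
            units = [u for r in results for u in r.per_measurement_units]
            from .gel import summarize_units

            mean, half, n = summarize_units(units)
            warns = [w for r in results for w in r.warnings]
        else:
            if probe is None:
                raise ConfigError("assay2 gel stage needs a probe_fragment")
            r = assay2_stoichiometry(gels, construct, probe)
            units, mean, half, n, warns = (
                r.per_measurement_units,
                r.mean_units,
                r.ci95_half_width,
                r.n,
                r.warnings,
            )
        report["warnings"].extend(f"gel: {w}" for w in warns)
        return {
            "assay_mode": mode,
            "construct": construct.name,
            "per_measurement_units": units,
            "mean_units": mean,
            "ci95_half_width": _nan_to_none(half),
            "n": n,
            "units": "protein monomers per oligomer",
        }
    except KeyError as exc:
        raise StageError(f"gel stage: missing config key {exc}") from exc
    except StoichlabError as exc:
        raise StageError(f"gel stage: {exc}") from exc


def _titration_stage(block, base, seed) -> dict:
    try:
        mode = block.get("fit_mode", "single")
        if "simulate" in block:
            sim = dict(block["simulate"])
            sim.setdefault("seed", seed)
            points = simulate_titration(TitrationSimConfig(**sim))
        else:
            points = read_titration(base / block["path"])
        fit = fit_kd(points, mode=mode, active_fraction=block.get("active_fraction", 1.0))
        return {
            "mode": mode,
            "kd_nM": fit.kd,
            "se_nM": _nan_to_none(fit.se),
            "residual_ss": fit.residual_ss,
            "n": fit.n_points,
            "units": "nM",
        }
    except KeyError as exc:
        raise StageError(f"titration stage: missing config key {exc}") from exc
    except StoichlabError as exc:
        raise StageError(f"titration stage: {exc}") from exc


def _fcs_stage(block, base, seed) -> dict:
    try:
        kappa = float(block.get("kappa", 5.0))
        native, denatured = [], []
        if "simulate" in block:
            sim = dict(block["simulate"])
            n_rep = int(sim.pop("n_replicates", 5))
            for rep in range(n_rep):
                cfg = AcfSimConfig(**{**sim, "seed": seed + rep, "kappa": kappa})
                nat, den = simulate_acf(cfg)
                native.append(fit_acf(nat, kappa))
                denatured.append(fit_acf(den, kappa))
        else:
            curves = read_acf_curves(base / block["path"])
            reps = sorted({rep for rep, _ in curves})
            for rep in reps:
                if (rep, "native") not in curves or (rep, "denatured") not in curves:
                    raise DataError(f"replicate {rep!r} lacks a native/denatured pair")
                native.append(fit_acf(curves[(rep, "native")], kappa))
                denatured.append(fit_acf(curves[(rep, "denatured")], kappa))
        result = oligomer_ratio(
            native, denatured, brightness_correction=block.get("brightness_correction", 1.0)
        )
        return {
            "ratios": result.ratios,
            "mean": result.mean,
            "ci95_half_width": _nan_to_none(result.ci95_half_width),
            "n": result.n,
            "n_native": [f.n_particles for f in native],
            "n_denatured": [f.n_particles for f in denatured],
            "units": "monomers per oligomer (dimensionless ratio)",
        }
    except KeyError as exc:
        raise StageError(f"fcs stage: missing config key {exc}") from exc
    except StoichlabError as exc:
        raise StageError(f"fcs stage: {exc}") from exc


def _pmf_stage(block, base, seed) -> dict:
    try:
        records = read_fasta(base / block["fasta"])
        name, seq = next(iter(records.items()))
        peptides = tryptic_digest(seq, int(block.get("max_missed_cleavages", 1)))
        if "peaks" in block:
            peaks = read_peaklist(base / block["peaks"])
        elif "simulate" in block:
            sim = dict(block["simulate"])
            sim.setdefault("seed", seed)
            peaks = simulate_peaklist(seq, **sim)
        else:
            raise ConfigError("pmf stage needs 'peaks' or 'simulate'")
        result = pmf_match(
            peaks, peptides, tolerance=float(block.get("tolerance", 0.25)),
            protein_length=len(seq),
        )
        return {
            "protein": name,
            "n_observed": int(len(peaks)),
            "n_matched": len(result.matched),
            "n_unmatched": len(result.unmatched_observed),
            "coverage_percent": result.coverage_percent,
            "tolerance_da": result.tolerance,
            "units": "Da (tolerance), percent (coverage)",
        }
    except KeyError as exc:
        raise StageError(f"pmf stage: missing config key {exc}") from exc
    except StoichlabError as exc:
        raise StageError(f"pmf stage: {exc}") from exc


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
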