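"""Deterministic JSON/TSV serialization of analysis results.

All floats are fixed at 4 decimals (Å, Å², bits) and JSON keys are
emitted in sorted order, so identical inputs and configuration produce
byte-identical reports — a property the test suite asserts.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .active_site import ActiveSiteGeometry
from .flexibility import FlexibilityProfile, RegionAnnotation
from .regions import DomainProfile
from .superpose import SuperpositionResult


def _round(x: float | None) -> float | None:
    return None if x is None else round(float(x), 4)


def superposition_dict(result: SuperpositionResult) -> dict[str, Any]:
    return {
        "rotation": [[_round(v) for v in row] for row in np.asarray(result.rotation)],
        "translation": [_round(v) for v in np.asarray(result.translation)],
        "rmsd_angstrom": _round(result.rmsd),
        "n_pairs": result.n_pairs,
        "degenerate": result.degenerate,
        "cycles": [{"cycle": c, "n_pairs": n, "rmsd_angstrom": _round(r),
                    "n_rejected": k} for c, n, r, k in result.cycles],
    }


def region_dict(region: RegionAnnotation) -> dict[str, Any]:
    return {
        "chain": region.chain_id,
        "start": region.start,
        "end": region.end,
        "label": region.label,
        "evidence": sorted(region.evidence),
        "mean_H_bits": _round(region.mean_h),
        "mean_z": _round(region.mean_z),
    }


def active_site_dict(geometry: ActiveSiteGeometry) -> dict[str, Any]:
    def rid(r):
        return None if r is None else f"{r[0]}{r[1]}"
    return {
        "chain": geometry.chain_id,
        "catalytic_his": rid(geometry.catalytic_his),
        "catalytic_asp": rid(geometry.catalytic_asp),
        "dyad_distance_angstrom": _round(geometry.dyad_distance),
        "dyad_found": geometry.dyad_found,
        "conserved_arg": rid(geometry.conserved_arg),
        "arg_his_ca_distance_angstrom": _round(geometry.arg_his_ca_distance),
        "ligand_reach_angstrom": _round(geometry.ligand_reach),
        "notes": geometry.notes,
    }


def profile_dict(profile: DomainProfile) -> dict[str, Any]:
    out: dict[str, Any] = {
        "structure": profile.structure_id,
        "chain": profile.chain_id,
        "params": {
            "h_percentile": _round(profile.params.h_percentile),
            "z_threshold": _round(profile.params.z_threshold),
            "min_length": profile.params.min_length,
            "merge_gap": profile.params.merge_gap,
        },
        "regions": [region_dict(r) for r in profile.regions],
    }
    if profile.active_site is not None:
        out["active_site"] = active_site_dict(profile.active_site)
    if profile.flexibility is not None:
        out["flexibility"] = {
            "mean_B_angstrom2": _round(profile.flexibility.mean_b),
            "sd_B_angstrom2": _round(profile.flexibility.sd_b),
            "unmodeled_segments": [list(g) for g in profile.flexibility.gaps],
        }
    if profile.entropy is not None:
        out["entropy"] = {
            "n_columns_retained": len(profile.entropy.column_indices),
            "min_occupancy": _round(profile.entropy.min_occupancy),
            "mean_H_bits": _round(float(np.mean(profile.entropy.entropy))),
        }
    return out


def to_json(obj: dict[str, Any]) -> str:
    return json.dumps(obj, indent=2, sort_keys=True) + "\n"


def flexibility_tsv(profile: FlexibilityProfile) -> str:
    """TSV per-residue table: chain, resnum, resname, meanB (Å²), z, modeled."""
    lines = ["chain\tresnum\tresname\tmeanB_angstrom2\tz\tmodeled"]
    for rec in profile.residues:
        mean_b = "" if rec.mean_b is None else f"{rec.mean_b:.4f}"
        z = "" if rec.z is None else f"{rec.z:.4f}"
        lines.append(f"{profile.chain_id}\t{rec.number}{rec.icode}\t{rec.name}"
                     f"\t{mean_b}\t{z}\t{int(rec.modeled)}")
    return "\n".join(lines) + "\n"


def entropy_tsv(profile, mapping=None) -> str:
    """TSV per-column table: msa_column, occupancy, H (bits), ref_resnum."""
    res_for_col = mapping.residue_for_column() if mapping is not None else {}
    lines = ["msa_column\toccupancy\tH_bits\tref_resnum"]
    for col, occ, h in zip(profile.column_indices, profile.occupancy, profile.entropy):
        rid = res_for_col.get(col)
        ref = f"{rid[0]}{rid[1]}" if rid is not None else "NA"
        lines.append(f"{col}\t{occ:.4f}\t{h:.4f}\t{ref}")
    return "\n".join(lines) + "\n"


def regions_tsv(regions: list[RegionAnnotation]) -> str:
    lines = ["chain\tstart\tend\tlabel\tevidence\tmean_H_bits\tmean_z"]
    for r in regions:
        mean_h = "" if r.mean_h is None else f"{r.mean_h:.4f}"
        mean_z = "" if r.mean_z is None else f"{r.mean_z:.4f}"
        lines.append(f"{r.chain_id}\t{r.start}\t{r.end}\t{r.label}"
                     f"\t{','.join(sorted(r.evidence))}\t{mean_h}\t{mean_z}")
    return "\n".join(lines) + "\n"
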