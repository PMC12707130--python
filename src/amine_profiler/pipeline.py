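"""Survey orchestration: per-structure classification and descriptors,
aggregation into the summary tables, acceptor-pair rankings and
pseudotorsion region reports.

The survey iterates over structures (local files or in-memory fixtures),
strips hydrogens, protonates the A/C/G amines of the requested chains,
classifies every amine as non/single/dual, computes burial and torsion
descriptors, and accumulates one row per amine. Per-entry failures are
recorded in a manifest and skipped, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import hbonds
from .config import SurveyConfig
from .structure import IFE, Structure, load_structure, protonate_amines, strip_hydrogens

__all__ = [
    "SurveySummary",
    "SurveyResult",
    "survey_structure",
    "run_survey",
    "rank_acceptor_pairs",
    "region_report",
    "location_adjacency_count",
]

RECORD_COLUMNS = [
    "entry", "chain", "resnum", "icode", "base", "klass", "scenario",
    "pair_1", "pair_2", "same_residue", "d1", "alpha1", "d2", "alpha2",
    "sasa", "rho1", "rho2", "chi", "syn", "minor", "eta", "theta",
]


@dataclass
class SurveySummary:
    """Aggregate counts in the shape of the survey's headline tables."""

    per_base: pd.DataFrame  # index: base; columns: non, single, dual
    percentages: pd.DataFrame  # same shape, % of all amines (sums to 100)
    n_amines: int
    n_excluded: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_base_counts": self.per_base.to_dict(),
            "per_base_percent": self.percentages.round(4).to_dict(),
            "n_amines": int(self.n_amines),
            "n_excluded": int(self.n_excluded),
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class SurveyResult:
    records: pd.DataFrame
    exclusions: pd.DataFrame
    summary: SurveySummary
    classifications: list = field(default_factory=list)
    cache_hits: int = 0


def survey_structure(structure: Structure, chains=None,
                     config: SurveyConfig | None = None,
                     compute_descriptors: bool = True):
    """One structure's amine records; returns (rows, exclusion rows, classifications)."""
    config = config or SurveyConfig()
    st = strip_hydrogens(structure)
    sites, excluded = protonate_amines(
        st, target_chains=chains,
        bond_length=config.nh_bond_length, hnh_angle=config.hnh_angle)
    classifications = hbonds.classify_structure(
        st, sites, config.criteria(),
        exclude_parent_residue=config.exclude_parent_residue)

    sasa_map = {}
    eta_theta_map = {}
    if compute_descriptors and sites:
        sasa_map = desc.sasa_of_amine_nitrogens(
            st, sites, probe=config.probe_radius, n_points=config.sasa_points)
        for chain in {s.residue_key[0] for s in sites}:
            eta_theta_map.update(desc.chain_eta_theta(st, chain))

    rows = []
    for cl in classifications:
        site = cl.amine
        key = site.residue_key
        row = {
            "entry": st.entry_id, "chain": key[0], "resnum": key[1],
            "icode": key[2], "base": site.base_type, "klass": cl.klass,
            "scenario": cl.scenario,
            "pair_1": str(cl.acceptor_pair[0]) if cl.acceptor_pair else None,
            "pair_2": str(cl.acceptor_pair[1]) if cl.acceptor_pair else None,
            "same_residue": cl.same_residue,
            "d1": cl.pair_geometry[0][0] if cl.pair_geometry else None,
            "alpha1": cl.pair_geometry[0][1] if cl.pair_geometry else None,
            "d2": cl.pair_geometry[1][0] if cl.pair_geometry else None,
            "alpha2": cl.pair_geometry[1][1] if cl.pair_geometry else None,
        }
        if compute_descriptors:
            residue = st.residues[key]
            chi_v = desc.chi(residue)
            rho1, rho2 = desc.shell_density(
                st, site.n_position, config.roi1_radius, config.roi2_radius)
            eta, theta = eta_theta_map.get(key, (None, None))
            row.update({
                "sasa": sasa_map.get(key), "rho1": rho1, "rho2": rho2,
                "chi": chi_v, "syn": desc.is_syn(chi_v),
                "minor": desc.is_minor(chi_v), "eta": eta, "theta": theta,
            })
        else:
            row.update({k: None for k in ("sasa", "rho1", "rho2", "chi",
                                          "syn", "minor", "eta", "theta")})
        rows.append(row)
    exclusion_rows = [
        {"entry": st.entry_id, "chain": e.residue_key[0],
         "resnum": e.residue_key[1], "icode": e.residue_key[2],
         "resname": e.residue_name, "reason": e.reason}
        for e in excluded
    ]
    return rows, exclusion_rows, classifications


def _summarize(records: pd.DataFrame, n_excluded: int,
               config: SurveyConfig) -> SurveySummary:
    bases = ["A", "C", "G"]
    classes = ["non", "single", "dual"]
    counts = pd.DataFrame(0, index=bases, columns=classes, dtype=int)
    if len(records):
        tab = records.groupby(["base", "klass"]).size()
        for (b, k), v in tab.items():
            counts.loc[b, k] = v
    total = int(counts.to_numpy().sum())
    pct = counts / total * 100.0 if total else counts.astype(float)
    return SurveySummary(
        per_base=counts, percentages=pct, n_amines=total,
        n_excluded=n_excluded,
        metadata={"config_hash": config.config_hash(),
                  "criteria": {
                      "prescreen_radius": config.prescreen_radius,
                      "max_h_acceptor_distance": config.max_h_acceptor_distance,
                      "min_nha_angle": config.min_nha_angle},
                  },
    )


def run_survey(inputs, config: SurveyConfig | None = None,
               compute_descriptors: bool = True,
               cache_dir=None, strict: bool = False) -> SurveyResult:
    """Survey a collection of structures.

    ``inputs``: iterable of (structure-or-path, chains-or-None) pairs, or an
    iterable of structures/paths (all chains). With ``cache_dir`` set,
    per-entry records are reloaded from CSV instead of recomputed when the
    configuration hash matches. ``strict`` turns per-entry failures into
    errors instead of manifest entries.
    """
    config = config or SurveyConfig()
    cache_dir = Path(cache_dir) if cache_dir else None
    if cache_dir:
        cache_dir.mkdir(parents=True, exist_ok=True)
    all_rows: list[dict] = []
    excl_rows: list[dict] = []
    classifications = []
    cache_hits = 0
    for item in inputs:
        if isinstance(item, tuple):
            source, chains = item
        else:
            source, chains = item, None
        try:
            if isinstance(source, (str, Path)):
                structure = load_structure(source, config.model_policy,
                                           config.altloc_policy)
            else:
                structure = source
            tag = f"{structure.entry_id}_{config.config_hash()}"
            cache_file = cache_dir / f"{tag}.csv" if cache_dir else None
            if cache_file and cache_file.exists():
                cached = pd.read_csv(cache_file, keep_default_na=True)
                cached["icode"] = cached["icode"].fillna("").astype(str)
                for col in ("scenario",):
                    cached[col] = cached[col].astype("Int64")
                rows = cached.replace({np.nan: None}).to_dict("records")
                for row in rows:
                    row["scenario"] = (None if pd.isna(row["scenario"])
                                       else int(row["scenario"]))
                all_rows.extend(rows)
                cache_hits += 1
                continue
            rows, excl, cls = survey_structure(structure, chains, config,
                                               compute_descriptors)
            all_rows.extend(rows)
            excl_rows.extend(excl)
            classifications.extend(cls)
            if cache_file:
                pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(
                    cache_file, index=False)
        except Exception as exc:
            if strict:
                raise
            excl_rows.append({"entry": str(source), "chain": "", "resnum": None,
                              "icode": "", "resname": "", "reason": f"entry failed: {exc}"})
    records = pd.DataFrame(all_rows, columns=RECORD_COLUMNS)
    exclusions = pd.DataFrame(
        excl_rows, columns=["entry", "chain", "resnum", "icode", "resname", "reason"])
    summary = _summarize(records, len(exclusions), config)
    return SurveyResult(records=records, exclusions=exclusions,
                        summary=summary, classifications=classifications,
                        cache_hits=cache_hits)


def rank_acceptor_pairs(records: pd.DataFrame, base: str | None = None,
                        top_k: int = 10) -> pd.DataFrame:
    """Ranked acceptor-pair table for dual-donating amines.

    Returns columns pair, count, same_residue_fraction, sorted by
    descending count (ties by pair label for determinism).
    """
    dual = records[records["klass"] == "dual"]
    if base is not None:
        dual = dual[dual["base"] == base]
    if not len(dual):
        return pd.DataFrame(columns=["pair", "count", "same_residue_fraction"])
    pairs = dual.assign(pair=dual["pair_1"] + "/" + dual["pair_2"])
    grouped = pairs.groupby("pair").agg(
        count=("pair", "size"),
        same_residue_fraction=("same_residue", "mean"),
    ).reset_index()
    grouped = grouped.sort_values(["count", "pair"],
                                  ascending=[False, True], ignore_index=True)
    return grouped.head(top_k)


def _in_box(records: pd.DataFrame, box: desc.RegionBox) -> pd.Series:
    eta = pd.to_numeric(records["eta"], errors="coerce")
    theta = pd.to_numeric(records["theta"], errors="coerce")
    return (eta.between(*box.eta_range) & theta.between(*box.theta_range)
            ).fillna(False)


def region_report(records: pd.DataFrame, box: desc.RegionBox,
                  top_k: int = 4) -> pd.DataFrame:
    """Acceptor-pair counts for dual donors inside one pseudotorsion box."""
    members = records[_in_box(records, box)]
    return rank_acceptor_pairs(members, top_k=top_k)


def location_adjacency_count(records: pd.DataFrame,
                             box1: desc.RegionBox = desc.LOCATION_1,
                             box2: desc.RegionBox = desc.LOCATION_2) -> int:
    """Dual-donor residues in box1 directly 5'-linked to a box2 residue.

    Counts (entry, chain) residue pairs where the box-1 residue immediately
    precedes the box-2 residue in sequence numbering.
    """
    dual = records[records["klass"] == "dual"]
    in1 = dual[_in_box(dual, box1)]
    in2 = dual[_in_box(dual, box2)]
    keys2 = {(r.entry, r.chain, r.resnum) for r in in2.itertuples()}
    return sum((r.entry, r.chain, r.resnum + 1) in keys2 for r in in1.itertuples())


def resolve_ife_paths(ifes: list[IFE], local_dir) -> list[tuple[Path, tuple[str, ...]]]:
    """Map IFEs to local structure files (ENTRY.cif or ENTRY.pdb)."""
    local_dir = Path(local_dir)
    out = []
    for ife in ifes:
        for ext in (".cif", ".pdb"):
            p = local_dir / f"{ife.entry_id.upper()}{ext}"
            if p.exists():
                out.append((p, ife.chains))
                break
        else:
            raise FileNotFoundError(f"no local file for {ife.entry_id}")
    return out
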