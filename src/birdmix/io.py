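"""CSV dialects and dataset round-tripping.

Four UTF-8 CSVs with header rows describe a dataset:

* ``sites.csv``   — site_id, block_id, origin {forest,grass}, treated {0,1},
  site_area_ha, patch_area_ha, weed_contrast_eligible {0,1}
* ``visits.csv``  — site_id, visit, date_days, minutes_since_sunrise
* ``counts.csv``  — site_id, visit, species_id, count (sparse: absent rows
  are zero counts)
* ``species.csv`` — species_id, common_name, urban_class (case-insensitive)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountData, SurveyDesign, normalize_roster
from .simulate import TruthBundle

__all__ = ["read_dataset", "write_dataset", "write_truth", "read_csv_strict"]


def read_csv_strict(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_dataset(sites_csv, visits_csv, counts_csv, species_csv
                 ) -> tuple[SurveyDesign, CountData, pd.DataFrame]:
    """Load and cross-validate a dataset from the four CSV files.

    The sparse counts file is densified: any (species, site, visit) triple
    not listed is a zero count.  Unknown site or species ids, duplicate
    triples and negative counts are rejected with the offending rows named.
    """
    sites = read_csv_strict(sites_csv, ["site_id", "block_id", "origin",
                                        "treated", "patch_area_ha"])
    visits = read_csv_strict(visits_csv, ["site_id", "visit", "date_days",
                                          "minutes_since_sunrise"])
    design = SurveyDesign(sites, visits)

    roster = normalize_roster(
        read_csv_strict(species_csv, ["species_id", "urban_class"]))

    counts = read_csv_strict(counts_csv, ["site_id", "visit", "species_id",
                                          "count"])
    counts = counts.copy()
    counts["site_id"] = counts["site_id"].astype(str)
    counts["species_id"] = counts["species_id"].astype(str)

    site_ids = design.site_ids
    species_ids = roster["species_id"].tolist()
    unknown_sites = set(counts["site_id"]) - set(site_ids)
    if unknown_sites:
        rows = counts.index[counts["site_id"].isin(unknown_sites)].tolist()
        raise ValueError(
            f"counts rows {rows} reference unknown site(s) {sorted(unknown_sites)}")
    unknown_sp = set(counts["species_id"]) - set(species_ids)
    if unknown_sp:
        rows = counts.index[counts["species_id"].isin(unknown_sp)].tolist()
        raise ValueError(
            f"counts rows {rows} reference unknown species {sorted(unknown_sp)}")
    dup = counts.duplicated(["species_id", "site_id", "visit"])
    if dup.any():
        raise ValueError(
            f"duplicate (species, site, visit) rows at index {counts.index[dup].tolist()}")
    if (counts["count"] < 0).any():
        rows = counts.index[counts["count"] < 0].tolist()
        raise ValueError(f"negative counts at rows {rows}")
    valid_visits = set(range(1, design.n_visits + 1))
    bad_visit = ~counts["visit"].isin(valid_visits)
    if bad_visit.any():
        raise ValueError(
            f"counts rows {counts.index[bad_visit].tolist()} have visit "
            f"numbers outside 1..{design.n_visits}")

    si = {s: i for i, s in enumerate(species_ids)}
    ji = {s: j for j, s in enumerate(site_ids)}
    y = np.zeros((len(species_ids), design.n_sites, design.n_visits), dtype=int)
    y[counts["species_id"].map(si).to_numpy(),
      counts["site_id"].map(ji).to_numpy(),
      counts["visit"].to_numpy(int) - 1] = counts["count"].to_numpy(int)

    return design, CountData(y=y, species_ids=species_ids, design=design), roster


def write_dataset(design: SurveyDesign, counts: CountData,
                  roster: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write the four-CSV dialect; counts are written sparsely (nonzero only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.csv",
        "visits": out / "visits.csv",
        "counts": out / "counts.csv",
        "species": out / "species.csv",
    }
    design.sites.to_csv(paths["sites"], index=False)
    design.visits.to_csv(paths["visits"], index=False)

    i_idx, j_idx, k_idx = np.nonzero(counts.y)
    sparse = pd.DataFrame({
        "site_id": np.asarray(design.site_ids)[j_idx],
        "visit": k_idx + 1,
        "species_id": np.asarray(counts.species_ids)[i_idx],
        "count": counts.y[i_idx, j_idx, k_idx],
    })
    sparse.to_csv(paths["counts"], index=False)

    roster = roster.copy()
    if "common_name" not in roster:
        roster["common_name"] = roster["species_id"]
    roster[["species_id", "common_name", "urban_class"]].to_csv(
        paths["species"], index=False)
    return paths


def write_truth(bundle: TruthBundle, out_dir) -> Path:
    """Write the generating truth of a simulated dataset as a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {
        "species_params": [
            {"species_id": p.species_id, "urban_class": p.urban_class,
             "psi": p.psi,
             **{c: getattr(p, c) for c in
                ("u1", "u2", "o1", "o2", "a1", "a2", "a3", "a4",
                 "v1", "b1", "b2", "b3", "b4")}}
            for p in bundle.species_params
        ],
        "latent_N": np.asarray(bundle.N).tolist(),
        "latent_w": np.asarray(bundle.w).tolist(),
    }
    if bundle.hyperparams is not None:
        truth["hyperparams"] = {
            cls: {"mu": h.mu, "sigma": h.sigma}
            for cls, h in bundle.hyperparams.items()
        }
    path = out / "truth.json"
    path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path
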