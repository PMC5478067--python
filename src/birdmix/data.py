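"""Core data containers for community N-mixture analyses.

The model works on three tables — sites, visits, counts — plus a species
roster mapping each species to an urban-response class.  :class:`SurveyDesign`
owns the covariates and their standardization; :class:`CountData` owns the
dense count tensor (species x site x visit) and, for simulated data, the
latent truth (abundance ``N`` and inclusion ``w``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical order of urban-response classes.
URBAN_CLASSES = ("sensitive", "adaptable", "exploitative")

#: Canonical order of the species-level coefficients.
#: u1/u2: treated/untreated intercepts; o1/o2: forest/grass origin effects;
#: a1: (log, standardized) patch-area effect; a2: area x treatment;
#: a3: treatment benefit at forest-origin sites (weed control);
#: a4: treatment benefit at grass-origin sites (revegetation);
#: v1: detection intercept; b1/b2: linear/quadratic date-of-season effects;
#: b3/b4: linear/quadratic time-since-sunrise effects.
COEF_NAMES = (
    "u1", "u2", "o1", "o2", "a1", "a2", "a3", "a4",
    "v1", "b1", "b2", "b3", "b4",
)
ABUNDANCE_COEFS = COEF_NAMES[:8]
DETECTION_COEFS = COEF_NAMES[8:]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SiteCovariates:
    """Covariates of one survey site, already standardized.

    ``area`` is the z-score of log patch area; ``trt`` is 1 for treated sites
    (revegetated or weed-controlled), ``ori`` is 1 for forest-origin sites.
    """

    site_id: str
    block_id: str
    trt: int
    ori: int
    area: float

    def __post_init__(self):
        if self.trt not in (0, 1):
            raise ValueError(f"TRT must be 0 or 1, got {self.trt}")
        if self.ori not in (0, 1):
            raise ValueError(f"ORI must be 0 or 1, got {self.ori}")
        _require_finite("area", self.area)


@dataclass(frozen=True)
class VisitCovariates:
    """Covariates of one visit to one site (standardized DATE and TSR)."""

    site_id: str
    visit_index: int
    date: float
    tsr: float

    def __post_init__(self):
        _require_finite("DATE", self.date)
        _require_finite("TSR", self.tsr)


@dataclass
class SpeciesParams:
    """Species-level coefficients of the hierarchical model.

    ``psi`` is the inclusion probability of the zero-inflation layer; the 13
    named coefficients follow :data:`COEF_NAMES`.
    """

    species_id: str
    urban_class: str
    psi: float = 0.5
    u1: float = 0.0
    u2: float = 0.0
    o1: float = 0.0
    o2: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    a4: float = 0.0
    v1: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0

    def __post_init__(self):
        if self.urban_class not in URBAN_CLASSES:
            raise ValueError(f"unknown urban class {self.urban_class!r}")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must lie in [0, 1], got {self.psi}")
        for name in COEF_NAMES:
            _require_finite(name, getattr(self, name))

    def coefficients(self) -> np.ndarray:
        """All 13 coefficients in :data:`COEF_NAMES` order."""
        return np.array([getattr(self, c) for c in COEF_NAMES], dtype=float)


@dataclass
class ClassHyperparams:
    """Per-class hyperparameters: Normal mean and sd for every coefficient.

    Species coefficients of class ``c`` are drawn
    ``coef_i ~ Normal(mu[coef], sigma[coef])``.
    """

    urban_class: str
    mu: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.urban_class not in URBAN_CLASSES:
            raise ValueError(f"unknown urban class {self.urban_class!r}")
        self.mu = {c: float(self.mu.get(c, 0.0)) for c in COEF_NAMES}
        self.sigma = {c: float(self.sigma.get(c, 1.0)) for c in COEF_NAMES}
        for c in COEF_NAMES:
            if not np.isfinite(self.mu[c]):
                raise ValueError(f"mu[{c}] must be finite")
            if not (self.sigma[c] > 0 and np.isfinite(self.sigma[c])):
                raise ValueError(f"sigma[{c}] must be positive and finite")

    def mu_vector(self) -> np.ndarray:
        return np.array([self.mu[c] for c in COEF_NAMES])

    def sigma_vector(self) -> np.ndarray:
        return np.array([self.sigma[c] for c in COEF_NAMES])


def normalize_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Validate a species roster (species_id, urban_class) table.

    Class labels are matched case-insensitively against
    :data:`URBAN_CLASSES`.
    """
    if roster.empty:
        raise ValueError("species roster is empty")
    roster = roster.copy()
    roster["species_id"] = roster["species_id"].astype(str)
    labels = roster["urban_class"].astype(str).str.strip().str.lower()
    bad = sorted(set(labels) - set(URBAN_CLASSES))
    if bad:
        raise ValueError(
            f"unknown urban class label(s) {bad}; expected one of {URBAN_CLASSES}"
        )
    roster["urban_class"] = labels
    if roster["species_id"].duplicated().any():
        dups = roster.loc[roster["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species ids in roster: {dups}")
    return roster


class SurveyDesign:
    """Blocked survey design: site and visit covariate tables.

    Parameters
    ----------
    sites : DataFrame with columns site_id, block_id, origin ("forest"/"grass"),
        treated (0/1), site_area_ha, patch_area_ha, weed_contrast_eligible (0/1).
    visits : DataFrame with columns site_id, visit, date_days,
        minutes_since_sunrise.  Every site must have the same number of visits.

    On construction the covariates entering the linear predictors are
    standardized: patch area is log-transformed then z-scored; DATE and TSR
    are z-scored over all visits.  The constants used are kept in
    ``standardization`` so a fitted model can be applied reproducibly.
    """

    def __init__(self, sites: pd.DataFrame, visits: pd.DataFrame,
                 standardization: dict | None = None):
        sites = sites.copy()
        sites["site_id"] = sites["site_id"].astype(str)
        sites["block_id"] = sites["block_id"].astype(str)
        origin = sites["origin"].astype(str).str.strip().str.lower()
        bad = sorted(set(origin) - {"forest", "grass"})
        if bad:
            raise ValueError(f"unknown origin label(s) {bad}")
        sites["origin"] = origin
        sites["treated"] = sites["treated"].astype(int)
        if not sites["treated"].isin([0, 1]).all():
            raise ValueError("treated must be 0 or 1")
        if "weed_contrast_eligible" not in sites:
            sites["weed_contrast_eligible"] = 1
        sites["weed_contrast_eligible"] = sites["weed_contrast_eligible"].astype(int)
        if sites["site_id"].duplicated().any():
            raise ValueError("duplicate site ids")
        if (sites["patch_area_ha"] <= 0).any():
            raise ValueError("patch areas must be positive")

        visits = visits.copy()
        visits["site_id"] = visits["site_id"].astype(str)
        visits["visit"] = visits["visit"].astype(int)
        unknown = set(visits["site_id"]) - set(sites["site_id"])
        if unknown:
            rows = visits.index[visits["site_id"].isin(unknown)].tolist()
            raise ValueError(
                f"visit rows {rows} reference unknown site id(s) {sorted(unknown)}"
            )
        if visits.duplicated(["site_id", "visit"]).any():
            raise ValueError("duplicate (site, visit) rows")
        per_site = visits.groupby("site_id").size()
        if per_site.nunique() != 1 or set(per_site.index) != set(sites["site_id"]):
            raise ValueError("every site must have the same set of visits")

        self.sites = sites.reset_index(drop=True)
        visits = visits.sort_values(["site_id", "visit"]).reset_index(drop=True)
        self.visits = visits
        self.n_sites = len(sites)
        self.n_visits = int(per_site.iloc[0])

        if standardization is None:
            log_area = np.log(self.sites["patch_area_ha"].to_numpy(float))
            standardization = {
                "log_patch_area_mean": float(log_area.mean()),
                "log_patch_area_sd": float(log_area.std() or 1.0),
                "date_mean": float(visits["date_days"].mean()),
                "date_sd": float(visits["date_days"].std(ddof=0) or 1.0),
                "tsr_mean": float(visits["minutes_since_sunrise"].mean()),
                "tsr_sd": float(visits["minutes_since_sunrise"].std(ddof=0) or 1.0),
            }
        self.standardization = standardization

    # -- derived arrays -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return self.sites["site_id"].tolist()

    @property
    def trt(self) -> np.ndarray:
        return self.sites["treated"].to_numpy(int)

    @property
    def ori(self) -> np.ndarray:
        return (self.sites["origin"] == "forest").to_numpy(int)

    @property
    def area_z(self) -> np.ndarray:
        s = self.standardization
        log_area = np.log(self.sites["patch_area_ha"].to_numpy(float))
        return (log_area - s["log_patch_area_mean"]) / s["log_patch_area_sd"]

    def visit_covariates(self) -> tuple[np.ndarray, np.ndarray]:
        """Standardized (DATE, TSR) arrays, each shaped (n_sites, n_visits)."""
        s = self.standardization
        order = pd.Categorical(
            self.visits["site_id"], categories=self.site_ids, ordered=True
        )
        v = self.visits.iloc[np.lexsort((self.visits["visit"], order.codes))]
        date = (v["date_days"].to_numpy(float) - s["date_mean"]) / s["date_sd"]
        tsr = (v["minutes_since_sunrise"].to_numpy(float) - s["tsr_mean"]) / s["tsr_sd"]
        shape = (self.n_sites, self.n_visits)
        return date.reshape(shape), tsr.reshape(shape)

    def abundance_design_matrix(self) -> np.ndarray:
        """(n_sites, 8) matrix multiplying (u1,u2,o1,o2,a1,a2,a3,a4)."""
        trt, ori, area = self.trt, self.ori, self.area_z
        return np.column_stack([
            trt, 1 - trt, ori, 1 - ori,
            area, area * trt, trt * ori, trt * (1 - ori),
        ]).astype(float)

    def detection_design_matrix(self) -> np.ndarray:
        """(n_sites, n_visits, 5) matrix multiplying (v1,b1,b2,b3,b4)."""
        date, tsr = self.visit_covariates()
        ones = np.ones_like(date)
        return np.stack([ones, date, date ** 2, tsr, tsr ** 2], axis=-1)

    def site_covariates(self, site_id: str) -> SiteCovariates:
        j = self.site_ids.index(str(site_id))
        row = self.sites.iloc[j]
        return SiteCovariates(
            site_id=row["site_id"], block_id=row["block_id"],
            trt=int(row["treated"]), ori=int(row["origin"] == "forest"),
            area=float(self.area_z[j]),
        )


@dataclass
class CountData:
    """Dense repeated-count tensor with optional latent truth.

    ``y[i, j, k]`` is the count of species ``i`` at site ``j`` on visit ``k``.
    When the data are simulated, ``N`` (latent abundance) and ``w`` (inclusion
    indicator) hold the generating truth.
    """

    y: np.ndarray
    species_ids: list[str]
    design: SurveyDesign
    N: np.ndarray | None = None
    w: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.ndim != 3:
            raise ValueError("y must be (species, site, visit)")
        if (self.y < 0).any():
            raise ValueError("counts must be non-negative")
        if self.y.shape[1] != self.design.n_sites or \
                self.y.shape[2] != self.design.n_visits:
            raise ValueError("count tensor does not match the design")
        if len(self.species_ids) != self.y.shape[0]:
            raise ValueError("species_ids length does not match y")
        if self.N is not None:
            if (self.y.max(axis=2) > self.N).any():
                raise ValueError("observed count exceeds latent abundance")
            if self.w is not None and (self.N[np.asarray(self.w) == 0] != 0).any():
                raise ValueError("latent N must be 0 where w = 0")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]
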