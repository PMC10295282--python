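"""Data containers and CSV I/O for two-species repeated-count surveys.

The study design is a classic N-mixture layout: ``n_sites`` plots each
visited ``n_surveys`` times within a closed season, with per-visit counts of
two species.  Species ``A`` is the directional "donor" (its latent abundance
and detection enter the other species' model as covariates) and species
``B`` the "receiver".  Which observed species plays which role is explicit
configuration, never inferred from the data.

Covariates come in two blocks: site-level (habitat descriptors such as soil
moisture, insolation hours, topographic position) and survey-level
(conditions of each visit such as day of year, temperature, antecedent
rain).  All covariates are z-scored before entering the linear predictors,
and a pairwise Pearson screen guards against collinear pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountData",
    "CovariateSet",
    "ValidationError",
    "load_counts",
    "write_counts",
    "load_site_covariates",
    "load_survey_covariates",
    "write_site_covariates",
    "write_survey_covariates",
    "standardize",
    "destandardize",
    "collinearity_screen",
]


class ValidationError(ValueError):
    """Raised when an input table violates the design contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountData:
    """Repeated counts for the two species on a common site × survey grid.

    ``counts_A``/``counts_B`` are integer matrices of shape
    ``(n_sites, n_surveys)``; row ``i``, column ``j`` is the number of
    individuals counted at site ``i`` on survey ``j``.  Counts are
    non-negative and the two matrices share one design; missing values are
    rejected (no NA support).
    """

    counts_A: np.ndarray
    counts_B: np.ndarray
    site_ids: tuple = ()
    survey_ids: tuple = ()

    def __post_init__(self):
        a = np.asarray(self.counts_A)
        b = np.asarray(self.counts_B)
        if a.ndim != 2 or b.ndim != 2:
            raise ValidationError("count matrices must be 2-D (sites × surveys)")
        if a.shape != b.shape:
            raise ValidationError(
                f"species count matrices differ in shape: {a.shape} vs {b.shape}"
            )
        for name, m in (("A", a), ("B", b)):
            if np.any(pd.isna(m)):
                raise ValidationError(f"species {name} counts contain missing values")
            if not np.all(np.equal(np.mod(m, 1), 0)):
                raise ValidationError(f"species {name} counts must be integers")
            if np.any(m < 0):
                raise ValidationError(f"species {name} counts must be non-negative")
        object.__setattr__(self, "counts_A", a.astype(np.int64))
        object.__setattr__(self, "counts_B", b.astype(np.int64))
        if not self.site_ids:
            object.__setattr__(self, "site_ids", tuple(range(1, a.shape[0] + 1)))
        if not self.survey_ids:
            object.__setattr__(self, "survey_ids", tuple(range(1, a.shape[1] + 1)))
        if len(self.site_ids) != a.shape[0] or len(self.survey_ids) != a.shape[1]:
            raise ValidationError("site/survey label lengths do not match counts")

    @property
    def n_sites(self) -> int:
        return self.counts_A.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.counts_A.shape[1]


@dataclass(frozen=True)
class CovariateSet:
    """Site- and survey-level covariates, raw or z-scored.

    ``site_covs`` has shape ``(n_sites, k_site)``; ``survey_covs`` has shape
    ``(n_sites, n_surveys, k_survey)`` so that survey conditions may vary by
    site, by occasion, or both.  After :func:`standardize`, ``means``/``sds``
    hold the constants needed to map back to the raw scale.
    """

    site_covs: np.ndarray
    survey_covs: np.ndarray
    site_names: tuple
    survey_names: tuple
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    standardized: bool = False

    def __post_init__(self):
        s = np.asarray(self.site_covs, dtype=float)
        v = np.asarray(self.survey_covs, dtype=float)
        if s.ndim != 2:
            raise ValidationError("site_covs must be 2-D (sites × covariates)")
        if v.ndim != 3:
            raise ValidationError(
                "survey_covs must be 3-D (sites × surveys × covariates)"
            )
        if s.shape[0] != v.shape[0]:
            raise ValidationError("site_covs and survey_covs disagree on n_sites")
        if np.any(~np.isfinite(s)) or np.any(~np.isfinite(v)):
            raise ValidationError("covariates contain missing/non-finite values")
        if len(self.site_names) != s.shape[1]:
            raise ValidationError("site covariate name count mismatch")
        if len(self.survey_names) != v.shape[2]:
            raise ValidationError("survey covariate name count mismatch")
        object.__setattr__(self, "site_covs", s)
        object.__setattr__(self, "survey_covs", v)
        object.__setattr__(self, "site_names", tuple(self.site_names))
        object.__setattr__(self, "survey_names", tuple(self.survey_names))

    @property
    def n_sites(self) -> int:
        return self.site_covs.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.survey_covs.shape[1]


# ---------------------------------------------------------------------------
# count I/O
# ---------------------------------------------------------------------------


def load_counts(path, format: str = "long", species_a: str | None = None,
                species_b: str | None = None) -> CountData:
    """Read a two-species count table from CSV.

    Long format has columns ``site,survey,species,count`` with one row per
    site × survey × species cell.  Wide format has one row per site and
    columns ``<species>_s1..<species>_sJ``.  ``species_a`` names the species
    mapped to the donor role A (defaults to the first species in file order,
    but an explicit mapping is strongly recommended).
    """
    df = pd.read_csv(path, comment="#")
    if format == "long":
        return _counts_from_long(df, species_a, species_b)
    if format == "wide":
        return _counts_from_wide(df, species_a, species_b)
    raise ValueError(f"unknown counts format {format!r}")


def _counts_from_long(df: pd.DataFrame, species_a, species_b) -> CountData:
    required = {"site", "survey", "species", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"long counts CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["count"].isna().any():
        raise ValidationError("counts contain missing values")
    species = list(dict.fromkeys(df["species"]))
    if len(species) != 2:
        raise ValidationError(f"expected exactly 2 species, found {species}")
    if species_a is None:
        species_a = species[0]
    if species_b is None:
        species_b = next(s for s in species if s != species_a)
    if {species_a, species_b} != set(species):
        raise ValidationError(
            f"species mapping ({species_a!r}, {species_b!r}) does not match file {species}"
        )
    sites = list(dict.fromkeys(df["site"]))
    surveys = list(dict.fromkeys(df["survey"]))
    mats = {}
    for sp in (species_a, species_b):
        sub = df[df["species"] == sp]
        piv = sub.pivot_table(index="site", columns="survey", values="count",
                              aggfunc="sum", dropna=False)
        piv = piv.reindex(index=sites, columns=surveys)
        if piv.isna().any().any():
            raise ValidationError(
                f"ragged design: species {sp!r} missing some site × survey cells"
            )
        mats[sp] = piv.to_numpy()
    return CountData(mats[species_a], mats[species_b],
                     site_ids=tuple(sites), survey_ids=tuple(surveys))


def _counts_from_wide(df: pd.DataFrame, species_a, species_b) -> CountData:
    if "site" not in df.columns:
        raise ValidationError("wide counts CSV needs a 'site' column")
    species = list(dict.fromkeys(c.rsplit("_s", 1)[0] for c in df.columns if "_s" in c))
    if len(species) != 2:
        raise ValidationError(f"expected exactly 2 species in wide columns, found {species}")
    if species_a is None:
        species_a = species[0]
    if species_b is None:
        species_b = next(s for s in species if s != species_a)
    mats = {}
    for sp in (species_a, species_b):
        cols = sorted((c for c in df.columns if c.startswith(f"{sp}_s")),
                      key=lambda c: int(c.rsplit("_s", 1)[1]))
        if not cols:
            raise ValidationError(f"no wide columns found for species {sp!r}")
        if df[cols].isna().any().any():
            raise ValidationError("counts contain missing values")
        mats[sp] = df[cols].to_numpy()
    return CountData(mats[species_a], mats[species_b], site_ids=tuple(df["site"]))


def write_counts(data: CountData, path, species_a: str = "A",
                 species_b: str = "B") -> None:
    """Write counts as a long-format CSV (``site,survey,species,count``)."""
    rows = []
    for sp, mat in ((species_a, data.counts_A), (species_b, data.counts_B)):
        for i, site in enumerate(data.site_ids):
            for j, survey in enumerate(data.survey_ids):
                rows.append((site, survey, sp, int(mat[i, j])))
    pd.DataFrame(rows, columns=["site", "survey", "species", "count"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# covariate I/O
# ---------------------------------------------------------------------------


def load_site_covariates(path) -> tuple[np.ndarray, tuple, tuple]:
    """Read ``site,<cov1>,<cov2>,...`` → (matrix, covariate names, site ids)."""
    df = pd.read_csv(path, comment="#")
    if "site" not in df.columns:
        raise ValidationError("site covariates CSV needs a 'site' column")
    names = tuple(c for c in df.columns if c != "site")
    if df[list(names)].isna().any().any():
        raise ValidationError("site covariates contain missing values")
    return df[list(names)].to_numpy(float), names, tuple(df["site"])


def load_survey_covariates(path, site_ids=None, survey_ids=None):
    """Read ``site,survey,<cov1>,...`` → (array [sites × surveys × k], names)."""
    df = pd.read_csv(path, comment="#")
    if not {"site", "survey"}.issubset(df.columns):
        raise ValidationError("survey covariates CSV needs 'site' and 'survey' columns")
    names = tuple(c for c in df.columns if c not in ("site", "survey"))
    sites = list(site_ids) if site_ids is not None else list(dict.fromkeys(df["site"]))
    surveys = (list(survey_ids) if survey_ids is not None
               else list(dict.fromkeys(df["survey"])))
    arr = np.empty((len(sites), len(surveys), len(names)))
    for k, name in enumerate(names):
        piv = df.pivot_table(index="site", columns="survey", values=name,
                             dropna=False).reindex(index=sites, columns=surveys)
        if piv.isna().any().any():
            raise ValidationError(f"survey covariate {name!r} missing some cells")
        arr[:, :, k] = piv.to_numpy()
    return arr, names


def build_covariate_set(site_covs, site_names, survey_covs, survey_names) -> CovariateSet:
    return CovariateSet(site_covs, survey_covs, tuple(site_names), tuple(survey_names))


def write_site_covariates(covs: CovariateSet, path, site_ids=None) -> None:
    sites = list(site_ids) if site_ids is not None else list(range(1, covs.n_sites + 1))
    df = pd.DataFrame(covs.site_covs, columns=list(covs.site_names))
    df.insert(0, "site", sites)
    df.to_csv(path, index=False)


def write_survey_covariates(covs: CovariateSet, path, site_ids=None,
                            survey_ids=None) -> None:
    sites = list(site_ids) if site_ids is not None else list(range(1, covs.n_sites + 1))
    surveys = (list(survey_ids) if survey_ids is not None
               else list(range(1, covs.n_surveys + 1)))
    rows = []
    for i, site in enumerate(sites):
        for j, survey in enumerate(surveys):
            rows.append([site, survey, *covs.survey_covs[i, j, :]])
    pd.DataFrame(rows, columns=["site", "survey", *covs.survey_names]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# standardization & collinearity
# ---------------------------------------------------------------------------


def standardize(covs: CovariateSet) -> CovariateSet:
    """Z-score every covariate column: ``(x − mean) / SD`` with sample SD
    (``n − 1`` denominator).

    Site covariates are centred/scaled over sites; survey covariates over all
    site × survey cells jointly, since each enters a single linear predictor.
    Constant columns are rejected by name.  Raises if ``covs`` is already
    standardized.
    """
    if covs.standardized:
        raise ValidationError("covariates are already standardized")
    means: dict = {}
    sds: dict = {}
    site = covs.site_covs.copy()
    for k, name in enumerate(covs.site_names):
        col = site[:, k]
        m, s = col.mean(), col.std(ddof=1)
        if not s > 0:
            raise ValidationError(f"site covariate {name!r} is constant; cannot standardize")
        site[:, k] = (col - m) / s
        means[name], sds[name] = m, s
    survey = covs.survey_covs.copy()
    for k, name in enumerate(covs.survey_names):
        cells = survey[:, :, k]
        m, s = cells.mean(), cells.std(ddof=1)
        if not s > 0:
            raise ValidationError(f"survey covariate {name!r} is constant; cannot standardize")
        survey[:, :, k] = (cells - m) / s
        means[name], sds[name] = m, s
    return replace(covs, site_covs=site, survey_covs=survey, means=means,
                   sds=sds, standardized=True)


def destandardize(covs: CovariateSet) -> CovariateSet:
    """Invert :func:`standardize` using the stored means/SDs."""
    if not covs.standardized:
        raise ValidationError("covariates are not standardized")
    site = covs.site_covs.copy()
    for k, name in enumerate(covs.site_names):
        site[:, k] = site[:, k] * covs.sds[name] + covs.means[name]
    survey = covs.survey_covs.copy()
    for k, name in enumerate(covs.survey_names):
        survey[:, :, k] = survey[:, :, k] * covs.sds[name] + covs.means[name]
    return replace(covs, site_covs=site, survey_covs=survey, means={}, sds={},
                   standardized=False)


def collinearity_screen(covs: CovariateSet, cutoff: float = 0.7):
    """Flag covariate pairs with ``|Pearson r| ≥ cutoff``.

    All covariates are compared pairwise on the site × survey cell grid
    (site covariates are repeated across surveys so that mixed site/survey
    pairs are comparable).  Returns a list of ``(name_i, name_j, r)`` tuples;
    an empty list means the screen passed.  Model fitting refuses to run on
    a non-empty list unless explicitly overridden.
    """
    n, j = covs.n_sites, covs.n_surveys
    cols, names = [], []
    for k, name in enumerate(covs.site_names):
        cols.append(np.repeat(covs.site_covs[:, k], j))
        names.append(name)
    for k, name in enumerate(covs.survey_names):
        cols.append(covs.survey_covs[:, :, k].ravel())
        names.append(name)
    if len(cols) < 2:
        raise ValidationError("collinearity screen needs at least 2 covariates")
    x = np.vstack(cols)
    r = np.corrcoef(x)
    flagged = []
    for a, b in itertools.combinations(range(len(names)), 2):
        if abs(r[a, b]) >= cutoff:
            flagged.append((names[a], names[b], float(r[a, b])))
    return flagged
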