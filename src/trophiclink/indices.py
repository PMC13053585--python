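"""Site-level relative-abundance indices from raw scheme tables.

Every monitoring scheme reduces to the same atomic unit: one index value
per site x year x taxon.  The rules mirror the source schemes: transect
bird counts are summed across distance categories within a visit (flyover
birds excluded unless the species sings on the wing) and the maximum
across visits is the yearly index; bat passes are summed across transect
sections of completed transects, again taking the yearly maximum and
dropping never-occupied sites; species-level insect indices are summed to
order-level indices; pitfall-trap counts are converted to a yearly index
by a log-link count model with site and year fixed effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ["site_id", "easting_m", "northing_m", "year", "taxon", "value"]


def _check_counts(visits: pd.DataFrame) -> None:
    bad = visits.index[visits["count"] < 0]
    if len(bad):
        raise ValidationError(f"negative count at row {int(bad[0])}")


def _site_coords(visits: pd.DataFrame) -> pd.DataFrame:
    return visits.groupby("site_id", as_index=False)[["easting_m", "northing_m"]].first()


def bird_site_index(
    visits: pd.DataFrame, include_flyover: bool = False, taxon: str = "bird"
) -> pd.DataFrame:
    """Max-over-visits of counts summed across distance categories.

    ``include_flyover=True`` retains rows flagged as flying over (used for
    species that sing directly over their territories).
    """
    if visits.empty:
        raise ValidationError("visits table is empty")
    _check_counts(visits)
    use = visits if include_flyover else visits[visits["flag_flying_over"] == 0]
    per_visit = use.groupby(["site_id", "year", "visit"], as_index=False)["count"].sum()
    per_year = per_visit.groupby(["site_id", "year"], as_index=False)["count"].max()
    out = per_year.merge(_site_coords(visits), on="site_id")
    out["taxon"] = taxon
    out = out.rename(columns={"count": "value"})
    out["value"] = out["value"].astype(float)
    return out[INDEX_COLUMNS].sort_values(["site_id", "year"]).reset_index(drop=True)


def bat_site_index(visits: pd.DataFrame, taxon: str = "bat") -> pd.DataFrame:
    """Max-over-visits of passes summed across sections, completed transects only.

    Sites where the species was never observed (all-years maximum of zero)
    are removed entirely.
    """
    if visits.empty:
        raise ValidationError("visits table is empty")
    _check_counts(visits)
    use = visits[visits["complete"] == 1]
    per_visit = use.groupby(["site_id", "year", "visit"], as_index=False)["count"].sum()
    per_year = per_visit.groupby(["site_id", "year"], as_index=False)["count"].max()
    ever = per_year.groupby("site_id")["count"].max()
    keep = ever.index[ever > 0]
    dropped = ever.index.difference(keep)
    if len(dropped):
        logger.info("bat_site_index: removed %d never-observed sites", len(dropped))
    per_year = per_year[per_year["site_id"].isin(keep)]
    out = per_year.merge(_site_coords(visits), on="site_id")
    out["taxon"] = taxon
    out = out.rename(columns={"count": "value"})
    out["value"] = out["value"].astype(float)
    return out[INDEX_COLUMNS].sort_values(["site_id", "year"]).reset_index(drop=True)


def order_index(species_table: pd.DataFrame) -> pd.DataFrame:
    """Sum species-level index values within group per site-year.

    A group with no species rows in a site-year yields no output row
    (missing, not zero).
    """
    if species_table.empty:
        raise ValidationError("species table is empty")
    dup = species_table.duplicated(["site_id", "year", "species"])
    if dup.any():
        row = int(species_table.index[dup][0])
        raise ValidationError(f"duplicated species x site x year at row {row}")
    grouped = species_table.groupby(
        ["site_id", "year", "group"], as_index=False
    )["value"].sum()
    out = grouped.merge(_site_coords(species_table), on="site_id")
    out = out.rename(columns={"group": "taxon"})
    return out[INDEX_COLUMNS].sort_values(["site_id", "year"]).reset_index(drop=True)


def _check_connected(counts: pd.DataFrame) -> None:
    sites = pd.factorize(counts["site"])[0]
    years = pd.factorize(counts["year"])[0]
    ns, ny = sites.max() + 1, years.max() + 1
    # bipartite site-year graph; one component required for identifiability
    adj = coo_matrix(
        (np.ones(len(counts)), (sites, years + ns)), shape=(ns + ny, ns + ny)
    )
    ncomp, labels = connected_components(adj + adj.T, directed=False)
    if ncomp > 1:
        comp_sites = [
            sorted(counts["site"].unique()[labels[:ns] == k]) for k in range(ncomp)
        ]
        raise ValidationError(
            f"site x year design is disconnected into {ncomp} components: {comp_sites}"
        )


def carabid_year_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Yearly abundance index from a Poisson site+year fixed-effects model.

    Fits ``count ~ site + year`` with a log link by IRLS and returns
    ``exp(year effect)`` normalised so the reference year equals 1.  The
    reference is the earliest year observed at every site, falling back to
    the earliest year overall; standard errors come from the observed
    information via the delta method.
    """
    if counts.empty:
        raise ValidationError("counts table is empty")
    if (counts["count"] < 0).any():
        raise ValidationError("negative counts in carabid table")
    years = np.sort(counts["year"].unique())
    if len(years) < 2:
        raise ValidationError("need at least 2 years for a year index")
    _check_connected(counts)

    n_sites = counts["site"].nunique()
    common = [
        y for y in years
        if counts.loc[counts["year"] == y, "site"].nunique() == n_sites
    ]
    ref_year = common[0] if common else years[0]

    site_d = pd.get_dummies(counts["site"], prefix="site", drop_first=True, dtype=float)
    year_cat = pd.Categorical(
        counts["year"], categories=[ref_year] + [y for y in years if y != ref_year]
    )
    year_d = pd.get_dummies(year_cat, prefix="year", drop_first=True, dtype=float)
    X = pd.concat(
        [pd.Series(1.0, index=counts.index, name="const"), site_d, year_d], axis=1
    )
    fit = sm.GLM(counts["count"].to_numpy(), X, family=sm.families.Poisson()).fit()

    rows = [(int(ref_year), 1.0, 0.0)]
    for y in years:
        if y == ref_year:
            continue
        name = f"year_{y}"
        b, se = fit.params[name], fit.bse[name]
        rows.append((int(y), float(np.exp(b)), float(np.exp(b) * se)))
    out = pd.DataFrame(rows, columns=["year", "index", "se"]).sort_values("year")
    return out.reset_index(drop=True)


def select_pairings(diet_matrix: pd.DataFrame, max_importance: int = 1) -> list[tuple[str, str]]:
    """Insectivore-insect pairings from the diet matrix.

    Importance codes: 1 primary food source, 2 secondary, 3 limited or no
    evidence.  By default only primary sources (importance <= 1) are paired.
    """
    keep = diet_matrix[diet_matrix["importance"] <= max_importance]
    return list(keep[["insectivore", "insect_group"]].itertuples(index=False, name=None))
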