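"""Indicator metadata: ecosystem-service indicators and their service hierarchy.

The analysis tracks 22 plot-level indicators, each assigned to exactly one of
12 ecosystem services, which in turn belong to one of three categories
(provisioning, supporting/regulating, cultural).  An indicator can be a
*disservice* (smaller values are better, e.g. nitrate leaching) and can carry
a *log flag* (log-transformed before Gaussian modelling).

The default mapping shipped here is a synthetic, configurable stand-in for a
field campaign's own indicator dictionary: the indicator names and grouping
follow common usage for temperate agricultural grassland, but any mapping
with the same column contract can be supplied as a CSV file.
"""

from __future__ import annotations

import pandas as pd

CATEGORIES = ("provisioning", "supporting_regulating", "cultural")

SERVICE_MAP_COLUMNS = (
    "indicator",
    "cices_service",
    "category",
    "disservice_flag",
    "log_flag",
)

# indicator, service, category, disservice, log
_DEFAULT_ROWS = [
    ("biomass_yield", "biomass_production", "provisioning", False, False),
    ("digestibility", "forage_quality", "provisioning", False, False),
    ("nitrate_leaching", "water_quality_regulation", "supporting_regulating", True, True),
    ("surface_phosphorus", "water_quality_regulation", "supporting_regulating", True, True),
    ("heavy_metals", "water_quality_regulation", "supporting_regulating", True, False),
    ("n2o_emission", "climate_regulation", "supporting_regulating", True, True),
    ("carbon_stocks", "climate_regulation", "supporting_regulating", False, False),
    ("packing_density", "soil_structure_maintenance", "supporting_regulating", True, False),
    ("microbial_biomass_c", "soil_structure_maintenance", "supporting_regulating", False, False),
    ("earthworms", "soil_structure_maintenance", "supporting_regulating", False, True),
    ("root_biomass", "soil_structure_maintenance", "supporting_regulating", False, False),
    ("pathogenic_fungi", "pest_disease_control", "supporting_regulating", True, True),
    ("weed_abundance", "pest_disease_control", "supporting_regulating", True, True),
    ("leaf_damage", "pest_disease_control", "supporting_regulating", True, False),
    ("n2_fixation", "nutrient_cycling", "supporting_regulating", False, True),
    ("am_fungi", "nutrient_cycling", "supporting_regulating", False, True),
    ("plant_richness", "habitat_maintenance", "supporting_regulating", False, False),
    ("nectar_provision", "habitat_maintenance", "supporting_regulating", False, True),
    ("esthetic_appreciation", "esthetics", "cultural", False, False),
    ("edible_plants", "edible_wild_plants", "cultural", False, False),
    ("iconic_fungi", "iconic_species", "cultural", False, True),
    ("livestock_presence", "heritage_and_culture", "cultural", False, True),
]


def default_service_map() -> pd.DataFrame:
    """Return the default 22-indicator / 12-service / 3-category mapping."""
    df = pd.DataFrame(_DEFAULT_ROWS, columns=SERVICE_MAP_COLUMNS)
    validate_service_map(df)
    return df


def validate_service_map(service_map: pd.DataFrame) -> None:
    """Check the structural invariants of a service map.

    Raises ``ValueError`` on duplicated indicators, a service spanning more
    than one category, unknown categories, or missing columns.
    """
    missing = set(SERVICE_MAP_COLUMNS) - set(service_map.columns)
    if missing:
        raise ValueError(f"service map is missing columns: {sorted(missing)}")
    if service_map["indicator"].duplicated().any():
        dup = service_map.loc[service_map["indicator"].duplicated(), "indicator"]
        raise ValueError(f"duplicated indicators in service map: {list(dup)}")
    bad_cat = set(service_map["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories in service map: {sorted(bad_cat)}")
    cats_per_service = service_map.groupby("cices_service")["category"].nunique()
    if (cats_per_service > 1).any():
        bad = cats_per_service[cats_per_service > 1].index.tolist()
        raise ValueError(f"services mapped to more than one category: {bad}")


def indicator_names(service_map: pd.DataFrame | None = None) -> list[str]:
    if service_map is None:
        service_map = default_service_map()
    return list(service_map["indicator"])


def service_of_indicator(service_map: pd.DataFrame) -> pd.Series:
    return service_map.set_index("indicator")["cices_service"]


def category_of_service(service_map: pd.DataFrame) -> pd.Series:
    """Map each service to its (unique) category."""
    return service_map.groupby("cices_service")["category"].first()


def service_weight_matrix(service_map: pd.DataFrame) -> pd.DataFrame:
    """Averaging matrix ``A`` (services x indicators).

    ``A @ indicator_lrrs`` yields the per-service mean of the member
    indicators; each row sums to one.  Aggregating through ``A`` and then
    averaging services is equivalent to a grand mean over indicators weighted
    by 1 / (number of indicators in the indicator's service).
    """
    validate_service_map(service_map)
    services = service_map["cices_service"].unique()
    ind = list(service_map["indicator"])
    a = pd.DataFrame(0.0, index=pd.Index(services, name="cices_service"), columns=ind)
    for svc, grp in service_map.groupby("cices_service", sort=False):
        members = list(grp["indicator"])
        a.loc[svc, members] = 1.0 / len(members)
    return a


def read_service_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("disservice_flag", "log_flag"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    validate_service_map(df)
    return df


def write_service_map(service_map: pd.DataFrame, path) -> None:
    validate_service_map(service_map)
    service_map.to_csv(path, index=False)
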