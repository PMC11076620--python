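"""Derived management-intensity variables and computed ecosystem-service
indicators.

These are the purely computational indicator definitions: plant-available
fertilizer nitrogen, grazing livestock-unit days, degree-day-corrected
biomass yield, soil packing density, IPCC-style N2O emission, a linear
nitrate-leaching estimate, a heavy-metal contamination index, a nectar
provision index, and a symbiotic N2-fixation index.  Indicators measured
directly in the field (species richness, earthworm counts, esthetics ratings,
...) are pass-through data and only validated for type and positivity.

All literature coefficients live in a versioned YAML config
(``data/derivation_coefficients.yaml``) rather than in code; the shipped
defaults are provisional and documented as such in the file itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DerivationConfig:
    """Coefficient bundle for the derived indicators (see the YAML file)."""

    availability: dict
    n2o: dict
    leaching: dict
    packing_density: dict
    heavy_metal_reference: dict
    n2_fixation: dict

    def validate(self) -> None:
        for name, coef in self.availability.items():
            if not 0.0 <= coef <= 1.0:
                raise ValueError(f"availability coefficient for {name!r} outside [0, 1]")
        if self.availability.get("mineral") != 1.0:
            raise ValueError("mineral fertilizer availability must be 1.0 by definition")


def load_derivation_config(path=None) -> DerivationConfig:
    """Load coefficients from ``path`` or the packaged defaults."""
    if path is None:
        text = (resources.files("grassmf") / "data/derivation_coefficients.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    cfg = DerivationConfig(**raw)
    cfg.validate()
    return cfg


def available_nitrogen(
    applications: Iterable[tuple[str, float]],
    availability: Mapping[str, float],
) -> float:
    """Total plant-available fertilizer N (kg N ha-1 yr-1).

    ``applications`` is an iterable of ``(fertilizer_type, total_N)`` records;
    each contributes ``total_N * availability[type]``.  Linear in the record
    list, so yearly totals can be built up incrementally.
    """
    total = 0.0
    for ftype, amount in applications:
        if amount < 0:
            raise ValueError(f"negative N amount for application of {ftype!r}")
        if ftype not in availability:
            raise KeyError(f"unknown fertilizer type {ftype!r}: no availability coefficient")
        total += amount * availability[ftype]
    return total


def grazing_lu_days(
    grazing_events: Iterable[tuple[float, float, float]],
    n_years: int = 1,
) -> float:
    """Average livestock-unit days ha-1 yr-1 over ``n_years``.

    Each event is ``(livestock_units, days, area_ha)`` contributing
    ``LU * days / area``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    total = 0.0
    for lu, days, area in grazing_events:
        if area <= 0:
            raise ValueError(f"grazing event with non-positive area {area}")
        total += lu * days / area
    return total / n_years


def degree_day_yield(biomass: float, degree_sum: float) -> float:
    """Biomass yield corrected for sampling date: g m-2 per accumulated deg C day."""
    if degree_sum <= 0:
        raise ValueError("degree_sum must be positive")
    return biomass / degree_sum


def packing_density(bulk_density: float, clay: float, clay_coefficient: float = 0.009) -> float:
    """Soil packing density (g cm-3): bulk density plus a clay correction."""
    if bulk_density <= 0:
        raise ValueError("bulk_density must be positive")
    if not 0.0 <= clay <= 100.0:
        raise ValueError("clay content must be a mass percentage in [0, 100]")
    return bulk_density + clay_coefficient * clay


def n2o_emission(
    fertilizer_n: float,
    excreted_n: float,
    ef_fertilizer: float = 0.01,
    ef_excreta: float = 0.02,
    as_n2o_mass: bool = False,
) -> float:
    """Tier-1 style N2O emission, reported as kg N2O-N ha-1 yr-1.

    ``as_n2o_mass=True`` converts to kg N2O (x 44/28); off by default.
    """
    if fertilizer_n < 0 or excreted_n < 0:
        raise ValueError("N inputs must be non-negative")
    em = ef_fertilizer * fertilizer_n + ef_excreta * excreted_n
    return em * (44.0 / 28.0) if as_n2o_mass else em


def nitrate_leaching(
    fertilizer_n: float,
    excreta_n: float,
    fertilizer_coefficient: float = 0.1,
    excreta_coefficient: float = 0.2,
) -> float:
    """Linear nitrate-leaching estimate (kg N ha-1 yr-1) from N sources."""
    if fertilizer_n < 0 or excreta_n < 0:
        raise ValueError("N inputs must be non-negative")
    return fertilizer_coefficient * fertilizer_n + excreta_coefficient * excreta_n


def heavy_metal_index(cu: float, zn: float, cu_ref: float, zn_ref: float) -> float:
    """Dimensionless contamination index: worst ratio to the reference values."""
    if cu_ref <= 0 or zn_ref <= 0:
        raise ValueError("reference concentrations must be positive")
    if cu < 0 or zn < 0:
        raise ValueError("concentrations must be non-negative")
    return max(cu / cu_ref, zn / zn_ref)


def nectar_index(
    species_cover: Mapping[str, float],
    nectar_per_species: Mapping[str, float],
) -> float:
    """Potential nectar provision: cover-fraction-weighted sum of per-species
    nectar values.  Species missing from the nectar table contribute zero and
    are logged (not fatal)."""
    total = 0.0
    for species, cover in species_cover.items():
        if cover < 0:
            raise ValueError(f"negative cover for {species!r}")
        if species not in nectar_per_species:
            log.info("no nectar value for species %r; contributes 0", species)
            continue
        total += (cover / 100.0) * nectar_per_species[species]
    return total


def n2_fixation_index(
    biomass_yield: float,
    legume_records: Sequence[tuple[str, float, float]],
    fixed_fraction: float = 0.8,
    mass_fraction_per_cover: float = 0.01,
) -> float:
    """Symbiotic N2-fixation index.

    Each legume record is ``(species, cover_percent, n_content_percent)``;
    the legume's biomass mass fraction is modelled as
    ``mass_fraction_per_cover * cover``, and its fixed-N contribution as

        biomass_yield * mass_fraction * (N_content / 100) * fixed_fraction.

    Linear in biomass, so the index inherits the yield's strong
    productivity dependence.
    """
    if biomass_yield < 0:
        raise ValueError("biomass_yield must be non-negative")
    total = 0.0
    for species, cover, n_content in legume_records:
        if cover < 0 or n_content < 0:
            raise ValueError(f"negative cover or N content for {species!r}")
        mass_fraction = mass_fraction_per_cover * cover
        total += biomass_yield * mass_fraction * (n_content / 100.0) * fixed_fraction
    return total


def validate_passthrough(values: np.ndarray | Sequence[float], name: str = "indicator") -> np.ndarray:
    """Validate a directly measured indicator column: numeric, finite, >= 0."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: non-finite values in pass-through indicator")
    if (arr < 0).any():
        raise ValueError(f"{name}: negative values in pass-through indicator")
    return arr
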