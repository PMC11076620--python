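"""Design-faithful synthetic data for the grassland management study design.

Emulates a blocked agro-ecological sampling design: plots belong to farms,
farms come in matched organic / non-organic pairs with similar topography,
and every plot carries three binary management aspects

* ``production_system`` -- organic vs. non_organic (a farm-level property),
* ``eco_scheme`` -- enrolled in the extensive-management eco-scheme (yes/no),
* ``harvest_type`` -- pasture (grazing-dominated) vs. meadow (mowing).

Eco-scheme and pasture uptake are linked to plot inclination through a
logistic weighting, mirroring the real-world tendency to extensify steeper,
less favourable land.  Indicators are generated from a log-linear model,

    log y_ij = log b_j + sum_a 1[aspect a active] * log m_{ja}
               + u_{pair(i)} + lambda_j' z_i + eps_ij,

so that treatment effects are multiplicative on the natural scale and the
true log response ratio of indicator j under aspect a is exactly
``log m_{ja}``.  The rank-2 loading term induces shared residual covariance
across indicators, matching the two-latent-variable regression model used
downstream; ``u`` is a farm-pair random intercept.

Randomness: every generator takes an integer ``seed`` and is bit-for-bit
reproducible.  The pipeline derives per-stage seeds by spawning a
``numpy.random.SeedSequence`` from one global seed (design, management,
indicators, model initialisation, bootstrap -- in that order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .services import default_service_map, indicator_names

ASPECTS = ("production_system", "eco_scheme", "harvest_type")
#: level of each aspect treated as "active" in the multiplier table
TREATED_LEVELS = {
    "production_system": "organic",
    "eco_scheme": "yes",
    "harvest_type": "pasture",
}
REFERENCE_LEVELS = {
    "production_system": "non_organic",
    "eco_scheme": "no",
    "harvest_type": "meadow",
}

DESIGN_COLUMNS = (
    "plot_id",
    "farm_id",
    "pair_id",
    "production_system",
    "eco_scheme",
    "harvest_type",
    "soil_pH",
    "sand",
    "elevation",
    "inclination",
    "northness",
)

ENV_COVARIATES = ("soil_pH", "sand", "elevation", "inclination", "northness")

#: plots per (production_system, eco_scheme, harvest_type) cell; sums to 86
#: over 18 pairs, approximating the unbalanced 86-plot study design.
DEFAULT_CELL_COUNTS = {
    ("organic", "yes", "pasture"): 11,
    ("organic", "yes", "meadow"): 11,
    ("organic", "no", "pasture"): 10,
    ("organic", "no", "meadow"): 11,
    ("non_organic", "yes", "pasture"): 11,
    ("non_organic", "yes", "meadow"): 11,
    ("non_organic", "no", "pasture"): 10,
    ("non_organic", "no", "meadow"): 11,
}

ELEVATION_RANGE = (435.0, 1145.0)


def scale_cells(cells: dict | None = None, factor: float = 1.0) -> dict:
    """Scale per-cell plot counts by ``factor`` (rounded, min 1 per cell)."""
    cells = dict(DEFAULT_CELL_COUNTS if cells is None else cells)
    return {k: max(1, int(round(v * factor))) for k, v in cells.items()}


@dataclass
class InclinationLink:
    """Logistic-weight slopes linking inclination to management uptake.

    ``eco`` and ``pasture`` are log-odds slopes per standard deviation of
    inclination: with slope 0 assignment is uniform; positive slopes make
    steeper plots more likely to be enrolled in the eco-scheme / used as
    pasture while per-cell counts stay exact (weighted sampling without
    replacement via Gumbel keys).
    """

    eco: float = 1.2
    pasture: float = 1.2


def _weighted_subset(rng, scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of a weighted sample of size k without replacement.

    Uses Gumbel-top-k: selection probabilities proportional to exp(scores),
    reducing to uniform sampling when all scores are equal.
    """
    keys = scores + rng.gumbel(size=scores.shape[0])
    return np.argsort(keys)[::-1][:k]


def generate_design(
    n_pairs: int = 18,
    cell_counts: dict | None = None,
    inclination_link: InclinationLink | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a blocked plot-level design table.

    Parameters
    ----------
    n_pairs:
        Number of organic / non-organic farm pairs (two farms per pair).
    cell_counts:
        Plots per (production_system, eco_scheme, harvest_type) combination;
        defaults to an 86-plot allocation over the 8 cells.
    inclination_link:
        Slopes of the inclination -> uptake link; defaults to positive slopes.
    seed:
        Seed for all random draws.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    cells = dict(DEFAULT_CELL_COUNTS if cell_counts is None else cell_counts)
    for key, v in cells.items():
        if v < 0:
            raise ValueError(f"negative plot count for cell {key}")
    if sum(cells.values()) == 0:
        raise ValueError("total number of plots is zero")
    link = inclination_link or InclinationLink()
    rng = np.random.default_rng(seed)

    # pair-level topography/soil; both farms of a pair share it up to jitter
    lo, hi = ELEVATION_RANGE
    pair_elev = rng.uniform(lo, hi, n_pairs)
    pair_incl = rng.gamma(shape=4.0, scale=3.0, size=n_pairs)  # mean 12 deg
    pair_north = rng.uniform(-1.0, 1.0, n_pairs)
    pair_ph = rng.normal(6.3, 0.5, n_pairs)
    pair_sand = np.clip(rng.normal(35.0, 10.0, n_pairs), 5.0, 80.0)

    frames = []
    for prod in ("organic", "non_organic"):
        sub = {k: v for k, v in cells.items() if k[0] == prod}
        n_prod = sum(sub.values())
        if n_prod == 0:
            continue
        pair_idx = rng.permutation(np.arange(n_prod) % n_pairs)
        elev = np.clip(pair_elev[pair_idx] + rng.normal(0, 15.0, n_prod), lo, hi)
        incl = np.clip(pair_incl[pair_idx] + rng.normal(0, 1.5, n_prod), 0.0, None)
        north = np.clip(pair_north[pair_idx] + rng.normal(0, 0.05, n_prod), -1.0, 1.0)
        ph = pair_ph[pair_idx] + rng.normal(0, 0.15, n_prod)
        sand = np.clip(pair_sand[pair_idx] + rng.normal(0, 3.0, n_prod), 1.0, 95.0)

        sd = incl.std()
        z_incl = (incl - incl.mean()) / sd if sd > 0 else np.zeros(n_prod)

        eco = np.array(["no"] * n_prod, dtype=object)
        n_eco = sub.get((prod, "yes", "pasture"), 0) + sub.get((prod, "yes", "meadow"), 0)
        eco_idx = _weighted_subset(rng, link.eco * z_incl, n_eco)
        eco[eco_idx] = "yes"

        harvest = np.array(["meadow"] * n_prod, dtype=object)
        for eco_level in ("yes", "no"):
            members = np.flatnonzero(eco == eco_level)
            n_past = sub.get((prod, eco_level, "pasture"), 0)
            past_local = _weighted_subset(rng, link.pasture * z_incl[members], n_past)
            harvest[members[past_local]] = "pasture"

        tag = "org" if prod == "organic" else "con"
        frames.append(
            pd.DataFrame(
                {
                    "farm_id": [f"farm_{p:03d}_{tag}" for p in pair_idx],
                    "pair_id": [f"pair_{p:03d}" for p in pair_idx],
                    "production_system": prod,
                    "eco_scheme": eco,
                    "harvest_type": harvest,
                    "soil_pH": ph,
                    "sand": sand,
                    "elevation": elev,
                    "inclination": incl,
                    "northness": north,
                }
            )
        )
    design = pd.concat(frames, ignore_index=True)
    design.insert(0, "plot_id", [f"plot_{i:05d}" for i in range(len(design))])
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check DesignTable invariants; raise ``ValueError`` on violation."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if len(design) == 0:
        raise ValueError("design table has no plots")
    if design["plot_id"].duplicated().any():
        raise ValueError("plot_ids are not unique")
    farms_per_pair = design.groupby("pair_id")["farm_id"].nunique()
    if (farms_per_pair < 2).any():
        bad = farms_per_pair[farms_per_pair < 2].index.tolist()
        raise ValueError(f"pairs with only one farm: {bad}")
    pairs_per_farm = design.groupby("farm_id")["pair_id"].nunique()
    if (pairs_per_farm != 1).any():
        raise ValueError("a farm belongs to more than one pair")
    systems = design.groupby("pair_id")["production_system"].nunique()
    if (systems < 2).any():
        raise ValueError("a pair does not contain both production systems")
    if (design["northness"].abs() > 1).any():
        raise ValueError("northness outside [-1, 1]")
    lo, hi = ELEVATION_RANGE
    if ((design["elevation"] < lo) | (design["elevation"] > hi)).any():
        raise ValueError(f"elevation outside configured range {ELEVATION_RANGE}")


# ---------------------------------------------------------------------------
# management intensity
# ---------------------------------------------------------------------------


def _paper_fert() -> dict:
    # available fertilizer N means/SDs (kg ha-1 yr-1) on non-eco-scheme plots
    return {
        ("organic", "pasture"): (46.3, 52.4),
        ("organic", "meadow"): (82.6, 42.8),
        ("non_organic", "pasture"): (75.7, 55.8),
        ("non_organic", "meadow"): (111.6, 55.7),
    }


@dataclass
class IntensityParams:
    """Distributional parameters of the three management-intensity variables.

    Fertilizer N is zero by policy on eco-scheme plots; elsewhere it follows
    a gamma distribution with cell-specific mean/SD (kg available N ha-1
    yr-1).  Cuts per year and grazing livestock-unit days depend on harvest
    type, with eco-scheme reducing both through the stated factors.
    A standard deviation of zero yields the cell mean exactly.
    """

    fert: dict = field(default_factory=_paper_fert)
    cuts_mean: dict = field(default_factory=lambda: {"meadow": 4.5, "pasture": 1.2})
    cuts_sd: dict = field(default_factory=lambda: {"meadow": 0.9, "pasture": 0.7})
    cuts_eco_factor: float = 0.45
    grazing_mean: dict = field(default_factory=lambda: {"pasture": 160.0, "meadow": 15.0})
    grazing_sd: dict = field(default_factory=lambda: {"pasture": 60.0, "meadow": 15.0})
    grazing_eco_factor: float = 0.6

    def validate(self) -> None:
        means = (
            [m for m, _ in self.fert.values()]
            + list(self.cuts_mean.values())
            + list(self.grazing_mean.values())
        )
        if any(m < 0 for m in means):
            raise ValueError("configured intensity means must be non-negative")
        sds = (
            [s for _, s in self.fert.values()]
            + list(self.cuts_sd.values())
            + list(self.grazing_sd.values())
        )
        if any(s < 0 for s in sds):
            raise ValueError("configured intensity SDs must be non-negative")


def _gamma_draw(rng, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Vectorised gamma draw matching mean/SD exactly; sd=0 -> constant."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = mean.copy()
    pos = (sd > 0) & (mean > 0)
    if pos.any():
        shape = (mean[pos] / sd[pos]) ** 2
        scale = sd[pos] ** 2 / mean[pos]
        out[pos] = rng.gamma(shape, scale)
    return out


def generate_management(
    design: pd.DataFrame,
    intensity_params: IntensityParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-plot fertilizer N, cutting frequency, and grazing intensity."""
    validate_design(design)
    params = intensity_params or IntensityParams()
    params.validate()
    rng = np.random.default_rng(seed)
    n = len(design)

    fert_mean = np.zeros(n)
    fert_sd = np.zeros(n)
    for (prod, harv), (m, s) in params.fert.items():
        mask = (design["production_system"] == prod) & (design["harvest_type"] == harv)
        fert_mean[mask.to_numpy()] = m
        fert_sd[mask.to_numpy()] = s
    fert = _gamma_draw(rng, fert_mean, fert_sd)
    fert[(design["eco_scheme"] == "yes").to_numpy()] = 0.0  # policy: no fertilizer

    harv = design["harvest_type"].to_numpy()
    eco = (design["eco_scheme"] == "yes").to_numpy()
    cuts_mean = np.array([params.cuts_mean[h] for h in harv])
    cuts_sd = np.array([params.cuts_sd[h] for h in harv])
    cuts_mean = np.where(eco, cuts_mean * params.cuts_eco_factor, cuts_mean)
    cuts_sd = np.where(eco, cuts_sd * params.cuts_eco_factor, cuts_sd)
    cuts = _gamma_draw(rng, cuts_mean, cuts_sd)

    graz_mean = np.array([params.grazing_mean[h] for h in harv])
    graz_sd = np.array([params.grazing_sd[h] for h in harv])
    graz_mean = np.where(eco, graz_mean * params.grazing_eco_factor, graz_mean)
    graz_sd = np.where(eco, graz_sd * params.grazing_eco_factor, graz_sd)
    grazing = _gamma_draw(rng, graz_mean, graz_sd)

    return pd.DataFrame(
        {
            "plot_id": design["plot_id"].to_numpy(),
            "fertilizer_N_available": fert,
            "n_cuts": cuts,
            "grazing_intensity": grazing,
        }
    )


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

# per-indicator generative defaults:
# baseline, multiplier under organic, under eco-scheme, under pasture,
# residual log-SD.  Multipliers act on the *raw* indicator, so a value < 1 on
# a disservice (e.g. nitrate leaching under eco-scheme) is an improvement.
_DEFAULT_INDICATOR_PARAMS = {
    # indicator:            (base,   m_org, m_eco, m_past, sd)
    "biomass_yield":         (0.55,   0.95,  0.50,  0.75,  0.20),
    "digestibility":         (65.0,   1.00,  0.80,  1.08,  0.10),
    "nitrate_leaching":      (20.0,   0.85,  0.45,  1.00,  0.30),
    "surface_phosphorus":    (2.5,    1.00,  0.50,  1.00,  0.35),
    "heavy_metals":          (0.60,   1.00,  0.90,  1.00,  0.25),
    "n2o_emission":          (2.0,    0.90,  0.40,  1.15,  0.30),
    "carbon_stocks":         (60.0,   1.00,  1.15,  0.90,  0.15),
    "packing_density":       (1.50,   1.00,  0.80,  1.15,  0.10),
    "microbial_biomass_c":   (800.0,  1.00,  1.25,  1.00,  0.20),
    "earthworms":            (120.0,  1.00,  0.85,  0.70,  0.35),
    "root_biomass":          (400.0,  1.00,  1.30,  1.00,  0.25),
    "pathogenic_fungi":      (5.0,    1.00,  0.70,  1.00,  0.30),
    "weed_abundance":        (8.0,    1.00,  1.40,  1.20,  0.35),
    "leaf_damage":           (15.0,   1.00,  1.20,  1.00,  0.30),
    "n2_fixation":           (4.0,    1.00,  0.70,  0.95,  0.35),
    "am_fungi":              (8.0,    1.25,  1.50,  1.00,  0.30),
    "plant_richness":        (30.0,   1.00,  1.70,  1.20,  0.20),
    "nectar_provision":      (12.0,   1.00,  1.55,  1.00,  0.35),
    "esthetic_appreciation": (3.2,    1.00,  1.35,  1.10,  0.10),
    "edible_plants":         (6.0,    1.00,  1.55,  1.50,  0.25),
    "iconic_fungi":          (3.0,    1.00,  1.70,  1.30,  0.35),
    "livestock_presence":    (15.0,   1.00,  1.15,  4.00,  0.35),
}


def _default_loadings(names: list[str]) -> np.ndarray:
    """Fixed rank-2 loading pattern on the log scale.

    Axis 1 is a productivity/intensity axis (positive on yield-linked
    indicators, negative on extensive-management beneficiaries); axis 2 is a
    soil-biology axis.  Magnitudes are modest relative to residual SDs.
    """
    axis1 = {
        "biomass_yield": 0.20, "digestibility": 0.10, "n2_fixation": 0.25,
        "nitrate_leaching": 0.20, "surface_phosphorus": 0.18, "n2o_emission": 0.20,
        "weed_abundance": 0.10, "earthworms": 0.15,
        "plant_richness": -0.15, "nectar_provision": -0.18, "iconic_fungi": -0.15,
        "edible_plants": -0.12, "esthetic_appreciation": -0.05, "am_fungi": -0.15,
    }
    axis2 = {
        "microbial_biomass_c": 0.18, "root_biomass": 0.18, "carbon_stocks": 0.10,
        "earthworms": 0.18, "am_fungi": 0.12, "pathogenic_fungi": -0.15,
        "packing_density": -0.06, "heavy_metals": 0.10, "leaf_damage": 0.12,
        "livestock_presence": 0.15, "iconic_fungi": 0.10,
    }
    lam = np.zeros((len(names), 2))
    for j, name in enumerate(names):
        lam[j, 0] = axis1.get(name, 0.0)
        lam[j, 1] = axis2.get(name, 0.0)
    return lam


@dataclass
class EffectSpec:
    """Ground-truth generative parameters for the indicator matrix.

    ``multipliers`` holds the multiplicative treatment effect of each aspect
    (active level: organic / eco-scheme yes / pasture) per indicator, so the
    true LRR of indicator j under aspect a is ``log multipliers.loc[j, a]``.
    ``loadings`` (indicators x 2) induces rank-2 shared residual covariance;
    ``pair_sd`` is the SD of the farm-pair random intercept and
    ``residual_sd`` the per-indicator noise SD, all on the log scale.
    ``env_effects`` optionally adds log-linear effects of standardized
    environmental covariates (used to plant confounds; default none).
    """

    baselines: pd.Series
    multipliers: pd.DataFrame  # indicators x ASPECTS
    loadings: np.ndarray
    pair_sd: float = 0.15
    residual_sd: pd.Series | None = None
    env_effects: pd.DataFrame | None = None  # indicators x env covariates
    interaction_multipliers: dict | None = None  # (aspect_a, aspect_b) -> Series

    def validate(self) -> None:
        if (self.baselines <= 0).any():
            raise ValueError("baselines must be positive")
        if (self.multipliers <= 0).to_numpy().any():
            raise ValueError("treatment multipliers must be positive")
        if self.pair_sd < 0:
            raise ValueError("pair_sd must be >= 0")
        if self.residual_sd is not None and (self.residual_sd < 0).any():
            raise ValueError("residual_sd must be >= 0")
        p = len(self.baselines)
        if self.loadings.shape[0] != p:
            raise ValueError(
                f"loading matrix has {self.loadings.shape[0]} rows for {p} indicators"
            )
        if not self.multipliers.index.equals(self.baselines.index):
            raise ValueError("multipliers index does not match baselines")


def default_effect_spec() -> EffectSpec:
    """The study-condition defaults: effect pattern emulating the field study
    (eco-scheme boosting cultural and many regulating indicators at the cost
    of provisioning; pasture boosting cultural services, dominated by
    livestock presence; organic production affecting AM fungi and nitrate
    leaching only)."""
    names = indicator_names()
    base = pd.Series({k: v[0] for k, v in _DEFAULT_INDICATOR_PARAMS.items()})[names]
    mult = pd.DataFrame(
        {
            "production_system": {k: v[1] for k, v in _DEFAULT_INDICATOR_PARAMS.items()},
            "eco_scheme": {k: v[2] for k, v in _DEFAULT_INDICATOR_PARAMS.items()},
            "harvest_type": {k: v[3] for k, v in _DEFAULT_INDICATOR_PARAMS.items()},
        }
    ).loc[names]
    sd = pd.Series({k: v[4] for k, v in _DEFAULT_INDICATOR_PARAMS.items()})[names]
    return EffectSpec(
        baselines=base,
        multipliers=mult,
        loadings=_default_loadings(names),
        pair_sd=0.15,
        residual_sd=sd,
    )


def null_effect_spec() -> EffectSpec:
    """Effect spec with all treatment multipliers equal to one (no effects)."""
    spec = default_effect_spec()
    spec.multipliers.loc[:, :] = 1.0
    return spec


def generate_indicators(
    design: pd.DataFrame,
    management: pd.DataFrame | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the plots x indicators matrix from the log-linear model.

    ``management`` is accepted for interface symmetry (intensity variables do
    not feed the indicator model directly; treatment effects are parameterised
    per aspect).  All generated values are strictly positive.
    """
    validate_design(design)
    effects = effects or default_effect_spec()
    effects.validate()
    rng = np.random.default_rng(seed)

    names = list(effects.baselines.index)
    p = len(names)
    n = len(design)
    d = effects.loadings.shape[1] if effects.loadings.size else 0

    log_y = np.tile(np.log(effects.baselines.to_numpy()), (n, 1))
    for aspect in ASPECTS:
        active = (design[aspect] == TREATED_LEVELS[aspect]).to_numpy()
        log_y[active] += np.log(effects.multipliers[aspect].to_numpy())

    if effects.interaction_multipliers:
        for (a1, a2), mult in effects.interaction_multipliers.items():
            both = (
                (design[a1] == TREATED_LEVELS[a1]) & (design[a2] == TREATED_LEVELS[a2])
            ).to_numpy()
            log_y[both] += np.log(np.asarray(mult, dtype=float))

    if effects.env_effects is not None:
        for cov in effects.env_effects.columns:
            x = design[cov].to_numpy(dtype=float)
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
            log_y += np.outer(z, effects.env_effects[cov].reindex(names).to_numpy())

    if effects.pair_sd > 0:
        pair_codes, _ = pd.factorize(design["pair_id"])
        u = rng.normal(0.0, effects.pair_sd, pair_codes.max() + 1)
        log_y += u[pair_codes][:, None]

    if d > 0:
        z = rng.standard_normal((n, d))
        log_y += z @ effects.loadings.T

    sd_vec = (
        effects.residual_sd.reindex(names).to_numpy()
        if effects.residual_sd is not None
        else np.full(p, 0.25)
    )
    log_y += rng.standard_normal((n, p)) * sd_vec

    return pd.DataFrame(np.exp(log_y), index=design["plot_id"].to_numpy(), columns=names)


def true_lrr(effects: EffectSpec, aspect: str, service_map: pd.DataFrame | None = None) -> pd.Series:
    """Population log response ratio per indicator implied by the generator,
    after the disservice sign flip (positive = service improved)."""
    if service_map is None:
        service_map = default_service_map()
    signs = np.where(service_map.set_index("indicator")["disservice_flag"], -1.0, 1.0)
    lrr = np.log(effects.multipliers[aspect].reindex(service_map["indicator"]).to_numpy())
    return pd.Series(lrr * signs, index=service_map["indicator"].to_numpy())


def write_dataset(
    outdir,
    design: pd.DataFrame,
    management: pd.DataFrame,
    indicators: pd.DataFrame,
    effects: EffectSpec | None = None,
    service_map: pd.DataFrame | None = None,
) -> None:
    """Write the dataset as CSV tables plus a YAML ground-truth effects file."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design.to_csv(outdir / "design.csv", index=False)
    management.to_csv(outdir / "management.csv", index=False)
    indicators.rename_axis("plot_id").to_csv(outdir / "indicators.csv")
    if service_map is not None:
        service_map.to_csv(outdir / "service_map.csv", index=False)
    if effects is not None:
        truth = {
            "baselines": {k: float(v) for k, v in effects.baselines.items()},
            "multipliers": {
                a: {k: float(v) for k, v in effects.multipliers[a].items()} for a in ASPECTS
            },
            "pair_sd": float(effects.pair_sd),
            "residual_sd": (
                {k: float(v) for k, v in effects.residual_sd.items()}
                if effects.residual_sd is not None
                else None
            ),
            "loadings": [[float(x) for x in row] for row in effects.loadings],
        }
        with open(outdir / "true_effects.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
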