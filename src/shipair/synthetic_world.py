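"""Seeded synthetic coastal world with a known surrogate-chemistry operator.

This module generates everything a chemical-transport-model (CTM) archive
would normally provide — a coastal grid, sectoral land and shipping emission
fields, meteorology, and source-apportioned PM2.5 with components — but from
a fully specified, deterministic surrogate.  Because the "chemistry" is an
explicit closed-form operator, every downstream stage (emulator training,
scenario response surfaces, health burden) has exact ground truth.

The surrogate encodes three behaviours of the real source-apportionment
problem: (i) source contributions add exactly (tagged apportionment),
(ii) shipping-related PM2.5 responds almost linearly to shipping emission
scaling, and (iii) the response to land NOx/VOC scaling is nonlinear, with a
titration-driven dip in benefit near deep NOx cuts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import xarray as xr
from scipy import ndimage

NM_PER_KM = 1.0 / 1.852

LAND_SECTORS = ("mobile", "industry", "power", "domestic", "agriculture")
LAND_SPECIES = ("SO2", "NOx", "VOC", "PM", "NH3")
VESSEL_CLASSES = ("RV", "CV", "OGV")
SHIP_SPECIES = ("SO2", "NOx", "VOC", "PM")
MONTHS = ("Jan", "Apr", "Jul", "Nov")
SOURCE_GROUPS = ("land", "RV", "CV", "OGV", "other")
COMPONENTS = ("sulfate", "nitrate", "som", "pom")

REGION_CODES = {"none": 0, "CBS": 1, "SEC": 2, "SC": 3, "inland": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}
COASTAL_REGIONS = ("CBS", "SEC", "SC")

# National land emission totals (Mg/month) by sector (rows) x species
# (columns: SO2, NOx, VOC, PM, NH3).  Magnitudes are loosely scaled to a
# large industrialized coastal country.
BASE_LAND_TOTALS = np.array(
    [
        # SO2     NOx     VOC     PM      NH3
        [15e3, 220e3, 180e3, 40e3, 8e3],    # mobile
        [110e3, 120e3, 320e3, 90e3, 10e3],  # industry
        [80e3, 130e3, 20e3, 50e3, 2e3],     # power
        [45e3, 40e3, 120e3, 90e3, 15e3],    # domestic
        [0e3, 40e3, 60e3, 30e3, 215e3],     # agriculture
    ]
)

# Fraction of each national shipping species total carried by each vessel
# class (rows RV, CV, OGV; columns SO2, NOx, VOC, PM).  River vessels burn
# cleaner fuel (little SO2) but are VOC-heavy; ocean-going vessels dominate
# SO2/NOx.  The distinct per-species class mixes give each species channel
# its own spatial fingerprint.
VESSEL_SPECIES_SPLIT = np.array(
    [
        [0.02, 0.10, 0.55, 0.40],  # RV: clean fuel, VOC/PM-heavy small craft
        [0.18, 0.25, 0.30, 0.35],  # CV
        [0.80, 0.65, 0.15, 0.25],  # OGV: heavy fuel, SO2/NOx-dominated
    ]
)

# Shipping VOC and PM totals relative to shipping NOx (mass ratios).  VOC is
# kept small so that shipping-VOC control matters far less than shipping-NOx
# control, as is the case for real fleets.
SHIP_VOC_TO_NOX = 0.10
SHIP_PM_TO_NOX = 0.08

# Multiplicative seasonal factors by sector (Jan, Apr, Jul, Nov).
MONTH_FACTORS = {
    "mobile": (1.05, 1.0, 0.95, 1.0),
    "industry": (1.0, 1.0, 1.0, 1.0),
    "power": (1.1, 0.9, 1.15, 0.95),
    "domestic": (1.5, 0.85, 0.55, 1.25),
    "agriculture": (0.6, 1.3, 1.4, 0.7),
}
SHIP_MONTH_FACTORS = (1.0, 1.0, 1.02, 1.0)

# Annual decline of land emissions by species (fraction kept per year).
# Land SO2 falls fast (power/industry desulfurization era), NOx slowly.
LAND_TREND = {"SO2": 0.935, "NOx": 0.97, "VOC": 0.99, "PM": 0.95, "NH3": 1.0}

# Interannual shipping trends (fraction kept per year): the regional
# sulfur-control policy erodes shipping SO2 by ~27% over the four training
# years (before the global fuel-switch cut) while traffic holds NOx/VOC
# steady.  The contrast between the shipping species trends is what makes
# the per-species sensitivities identifiable from a handful of yearly
# samples; the land/shipping differential stays small enough to keep the
# national emission share near its target.
SHIP_TREND = {"SO2": 0.90, "NOx": 1.02, "VOC": 1.04, "PM": 0.93}

MET_CLIMO = {  # month -> (ws10 m/s, t2 K, rh %, pblh m)
    "Jan": (4.5, 272.0, 55.0, 420.0),
    "Apr": (5.0, 288.0, 62.0, 850.0),
    "Jul": (4.0, 300.0, 78.0, 1250.0),
    "Nov": (4.2, 281.0, 60.0, 600.0),
}


class WorldError(ValueError):
    """Raised for invalid world-construction requests."""


@dataclass
class GridSpec:
    """Rectangular coastal grid with a single north-south coastline.

    ``dist_coast_nm`` is the signed distance (nautical miles) from each cell
    centre to the coastline; positive over sea, negative over land, crossing
    zero at the land/sea interface.  ``region_id`` labels coastal land cells
    with three latitude bands (CBS north, SEC centre, SC south).
    """

    nx: int
    ny: int
    cell_km: float
    land_mask: np.ndarray
    dist_coast_nm: np.ndarray
    region_id: np.ndarray
    river_mask: np.ndarray
    port_mask: np.ndarray
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_id == REGION_CODES[name]

    def coastal_land_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for name in COASTAL_REGIONS:
            out |= self.region_mask(name)
        return out


@dataclass
class EmissionBundle:
    """Gridded monthly emissions (Mg/month/cell).

    ``land`` has shape (sector, species, ny, nx) over ``LAND_SECTORS`` x
    ``LAND_SPECIES``; ``shipping`` has shape (vessel, species, ny, nx) over
    ``VESSEL_CLASSES`` x ``SHIP_SPECIES``.
    """

    land: np.ndarray
    shipping: np.ndarray

    def copy(self) -> "EmissionBundle":
        return EmissionBundle(self.land.copy(), self.shipping.copy())

    def land_species(self, species: str) -> np.ndarray:
        """Summed-over-sectors land field for one species."""
        return self.land[:, LAND_SPECIES.index(species)].sum(axis=0)

    def shipping_species(self, species: str) -> np.ndarray:
        """Summed-over-vessel-classes shipping field for one species."""
        return self.shipping[:, SHIP_SPECIES.index(species)].sum(axis=0)

    def validate(self, grid: Optional[GridSpec] = None) -> None:
        if np.any(self.land < 0) or np.any(self.shipping < 0):
            raise WorldError("emissions must be non-negative")
        if grid is not None:
            off_water = grid.land_mask & ~grid.river_mask
            if np.any(self.shipping[:, :, off_water] > 0):
                raise WorldError("shipping emissions on land outside river corridor")


@dataclass
class MetBundle:
    """Five gridded meteorological fields."""

    ws10: np.ndarray  # m/s
    wd10: np.ndarray  # deg
    t2: np.ndarray    # K
    rh: np.ndarray    # %
    pblh: np.ndarray  # m

    FIELDS = ("ws10", "wd10", "t2", "rh", "pblh")

    def as_stack(self) -> np.ndarray:
        return np.stack([getattr(self, f) for f in self.FIELDS])

    def validate(self) -> None:
        if np.any(self.rh < 0) or np.any(self.rh > 100):
            raise WorldError("rh outside [0, 100]")
        if np.any(self.pblh <= 0):
            raise WorldError("pblh must be positive")
        if np.any(self.ws10 < 0):
            raise WorldError("ws10 must be non-negative")


@dataclass
class SourcePMBundle:
    """Source-apportioned PM2.5 (µg/m³) with components, by tagged group.

    ``pm25`` has shape (group, ny, nx) over ``SOURCE_GROUPS``; ``components``
    has shape (group, component, ny, nx) over ``COMPONENTS``.  Tagging is
    additive: the total field is exactly the sum over groups.
    """

    pm25: np.ndarray
    components: np.ndarray

    def group_pm25(self, group: str) -> np.ndarray:
        return self.pm25[SOURCE_GROUPS.index(group)]

    def group_component(self, group: str, comp: str) -> np.ndarray:
        return self.components[SOURCE_GROUPS.index(group), COMPONENTS.index(comp)]

    def shipping_pm25(self) -> np.ndarray:
        """Shipping-related PM2.5: RV + CV + OGV contributions."""
        idx = [SOURCE_GROUPS.index(v) for v in VESSEL_CLASSES]
        return self.pm25[idx].sum(axis=0)

    def shipping_component(self, comp: str) -> np.ndarray:
        gi = [SOURCE_GROUPS.index(v) for v in VESSEL_CLASSES]
        return self.components[gi, COMPONENTS.index(comp)].sum(axis=0)

    def total_pm25(self) -> np.ndarray:
        return self.pm25.sum(axis=0)

    def total_component(self, comp: str) -> np.ndarray:
        return self.components[:, COMPONENTS.index(comp)].sum(axis=0)

    def validate(self) -> None:
        if np.any(self.pm25 < -1e-12) or np.any(self.components < -1e-12):
            raise WorldError("concentrations must be non-negative")
        if np.any(self.components.sum(axis=1) > self.pm25 + 1e-9):
            raise WorldError("components exceed group PM2.5")


@dataclass
class MonthSample:
    """One modelled month: predictors plus (optionally) apportioned truth."""

    year_index: int
    month_label: str
    emissions: EmissionBundle
    met: MetBundle
    truth: Optional[SourcePMBundle] = None
    is_test: bool = False

    def __post_init__(self) -> None:
        if self.month_label not in MONTHS:
            raise WorldError(f"month_label must be one of {MONTHS}")


@dataclass
class WorldParams:
    """Tunable constants of the synthetic world and surrogate chemistry.

    The oxidant factor X(n, v) = v**p * (n**q + gamma*exp(-(n-n0)**2/w)),
    normalized to X(1, 1) = 1, multiplies all secondary-aerosol yields; n and
    v are domain-total land NOx and VOC emissions relative to the stored
    reference totals.  The Gaussian bump at n0 produces the titration dip in
    benefit when land NOx cuts approach 1 - n0.
    """

    sigma0: float = 0.35               # dispersion width coefficient (cells)
    sigma_bounds: tuple = (1.0, 5.0)   # kernel width clip range (cells)
    mixing_coeff: float = 16.0         # emission -> concentration scaling
    sulfate_yield: float = 0.25
    nitrate_yield: float = 0.25
    som_yield: float = 0.22
    pom_yield: float = 0.70            # fraction of dispersed primary PM as POM
    other_primary_frac: float = 0.30   # non-organic remainder of primary PM
    oxidant_p: float = 0.6             # VOC exponent p (> 0: X increases with v)
    oxidant_q: float = 1.0             # NOx exponent q
    titration_gamma: float = 0.35      # amplitude of the titration bump
    titration_center: float = 0.17     # n* in (0, 0.5): dip at ~80% NOx cut
    titration_width: float = 0.01      # Gaussian width parameter w
    background: float = 16.0           # "other + boundary" PM2.5 (µg/m³)
    background_comp_frac: tuple = (0.12, 0.14, 0.20, 0.18)
    shipping_share_target: float = 0.13  # national shipping share of SO2/NOx
    emission_noise: float = 0.20       # lognormal sigma of cell-level noise
    fuel_switch_year_index: int = 4    # final year: global fuel-sulfur cap
    fuel_switch_so2_factor: float = 0.30
    fuel_switch_pm_factor: float = 0.85
    n_ports: int = 5
    n_cities: int = 6
    ref_land_nox: Optional[float] = None  # oxidant reference totals (Mg/month)
    ref_land_voc: Optional[float] = None

    def validate(self) -> None:
        if not (0.0 < self.titration_center < 0.5):
            raise WorldError("titration_center must lie in (0, 0.5)")
        for name in ("sulfate_yield", "nitrate_yield", "som_yield", "pom_yield"):
            if getattr(self, name) < 0:
                raise WorldError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def _coast_columns(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Monotone-north-to-south randomized coastline column per row."""
    base = 0.45 * nx
    rough = np.cumsum(rng.standard_normal(ny))
    rough = ndimage.gaussian_filter1d(rough, sigma=max(2.0, ny / 12.0))
    rough = rough - rough.mean()
    scale = (0.06 * nx) / max(rough.std(), 1e-9)
    cols = np.clip(base + rough * scale, 0.25 * nx, 0.62 * nx)
    return np.round(cols).astype(int)


def build_grid(nx: int, ny: int, cell_km: float = 36.0, seed: int = 0) -> GridSpec:
    """Construct a seeded coastal grid.

    The coastline is a randomized north-south curve splitting the domain into
    one connected land component (west) and one connected sea component
    (east).  Coastal land is banded into three latitude regions, a river
    corridor crosses the coast, and ports are the highest-traffic sea cells
    adjacent to land.

    Raises :class:`WorldError` if the grid is smaller than 16 cells a side or
    the sea extent cannot contain the 200-Nm control band.
    """
    if nx < 16 or ny < 16:
        raise WorldError("grid must be at least 16x16 cells")
    rng = np.random.default_rng(seed)
    coast = _coast_columns(nx, ny, rng)
    xs = np.arange(nx)[None, :]
    land_mask = xs < coast[:, None]

    # Signed distance to the land/sea interface, in cell units then Nm.  The
    # half-cell offset puts the zero crossing on the interface itself.
    d_sea = ndimage.distance_transform_edt(~land_mask)
    d_land = ndimage.distance_transform_edt(land_mask)
    dist_cells = np.where(land_mask, -(d_land - 0.5), d_sea - 0.5)
    dist_nm = dist_cells * cell_km * NM_PER_KM
    if dist_nm.max() <= 200.0:
        raise WorldError(
            "sea extent too small to contain the 200-Nm control band; "
            "use a larger grid or coarser cells"
        )

    region_id = np.zeros((ny, nx), dtype=np.int8)
    coastal_band_nm = 130.0
    coastal_land = land_mask & (dist_nm > -coastal_band_nm)
    band = np.digitize(np.arange(ny), [ny / 3.0, 2.0 * ny / 3.0])  # 0,1,2 N->S
    band_code = np.array([REGION_CODES["CBS"], REGION_CODES["SEC"], REGION_CODES["SC"]])
    region_id[coastal_land] = band_code[band][:, None].repeat(nx, axis=1)[coastal_land]
    region_id[land_mask & ~coastal_land] = REGION_CODES["inland"]

    # River corridor: a single row of land cells reaching inland from the coast.
    y_r = int(ny * 0.5 + rng.integers(-ny // 8, ny // 8))
    river_len = max(4, nx // 8)
    river_mask = np.zeros((ny, nx), dtype=bool)
    x0 = max(0, coast[y_r] - river_len)
    river_mask[y_r, x0:coast[y_r]] = True

    grid = GridSpec(
        nx=nx, ny=ny, cell_km=cell_km, land_mask=land_mask,
        dist_coast_nm=dist_nm, region_id=region_id, river_mask=river_mask,
        port_mask=np.zeros((ny, nx), dtype=bool), seed=int(seed),
    )
    intensity = shipping_intensity(grid).sum(axis=0)
    adj_sea = ~land_mask & (ndimage.binary_dilation(land_mask, np.ones((3, 3))))
    cand = np.argwhere(adj_sea)
    order = np.argsort(intensity[adj_sea])[::-1]
    n_ports = min(5, len(cand))
    for y, x in cand[order[:n_ports]]:
        grid.port_mask[y, x] = True
    return grid


def shipping_intensity(grid: GridSpec) -> np.ndarray:
    """Deterministic relative shipping-activity template, (vessel, ny, nx).

    CVs follow a near-coast lane, OGVs an offshore lane, RVs the river
    corridor and the adjacent estuary.  Along-shore modulation is seeded by
    the grid seed, so the template is a fixed property of the world.
    """
    rng = np.random.default_rng([int(grid.seed), 7])
    d = grid.dist_coast_nm
    sea = ~grid.land_mask
    mod = ndimage.gaussian_filter1d(rng.lognormal(0.0, 0.5, grid.ny), 2.0)[:, None]

    cv = np.exp(-((d - 12.0) / 10.0) ** 2) * sea * mod
    ogv = np.exp(-((d - 55.0) / 30.0) ** 2) * sea * mod
    river_rows = np.where(grid.river_mask.any(axis=1))[0]
    y_r = int(river_rows[0]) if len(river_rows) else grid.ny // 2
    yy = np.arange(grid.ny)[:, None]
    estuary = np.exp(-(((yy - y_r) / 2.0) ** 2)) * np.exp(-(d / 8.0) ** 2) * sea
    rv = grid.river_mask * 1.0 + estuary
    out = np.stack([rv, cv, ogv])
    # Port hotspots (if already assigned) concentrate all classes.
    if grid.port_mask.any():
        out = out + grid.port_mask * out.sum(axis=(1, 2), keepdims=True) * 0.02
    return out


# ---------------------------------------------------------------------------
# Emissions and meteorology
# ---------------------------------------------------------------------------

def _normalized(field: np.ndarray) -> np.ndarray:
    s = field.sum()
    if s <= 0:
        raise WorldError("degenerate spatial template")
    return field / s


def _land_templates(grid: GridSpec, params: WorldParams) -> dict:
    """Per-sector spatial templates (normalized to unit sum), seeded by grid."""
    rng = np.random.default_rng([int(grid.seed), 11])
    land = grid.land_mask
    d = grid.dist_coast_nm
    cand = np.argwhere(land & (d > -140.0))
    k = min(params.n_cities, len(cand))
    centers = cand[rng.choice(len(cand), size=k, replace=False)]
    weights = rng.lognormal(0.0, 0.6, k)
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    cities = np.zeros(grid.shape)
    for (cy, cx), w in zip(centers, weights):
        cities += w * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5 ** 2)))
    cities *= land
    broad = ndimage.gaussian_filter(rng.lognormal(0.0, 0.4, grid.shape), 3.0) * land
    templates = {}
    for sector in LAND_SECTORS:
        jitter = ndimage.gaussian_filter(rng.lognormal(0.0, 0.3, grid.shape), 2.0)
        if sector == "agriculture":
            base = broad * jitter
        elif sector == "domestic":
            base = (0.6 * cities + 0.4 * broad) * jitter
        else:
            base = (0.9 * cities + 0.1 * broad) * jitter
        templates[sector] = _normalized(base)
    return templates


def base_shipping_totals(params: WorldParams) -> np.ndarray:
    """National shipping totals (vessel, species) meeting the share target.

    Shipping SO2 and NOx are set so that shipping/(shipping + land) equals
    ``shipping_share_target`` at year-0 annual-mean land totals; VOC and PM
    follow fixed mass ratios to NOx.
    """
    share = params.shipping_share_target
    month_mean = {
        s: np.mean([
            sum(BASE_LAND_TOTALS[i, LAND_SPECIES.index(s)] * MONTH_FACTORS[sec][m]
                for i, sec in enumerate(LAND_SECTORS))
            for m in range(len(MONTHS))
        ])
        for s in ("SO2", "NOx")
    }
    ship_so2 = share / (1.0 - share) * month_mean["SO2"]
    ship_nox = share / (1.0 - share) * month_mean["NOx"]
    totals = np.array([ship_so2, ship_nox, SHIP_VOC_TO_NOX * ship_nox,
                       SHIP_PM_TO_NOX * ship_nox])
    return VESSEL_SPECIES_SPLIT * totals[None, :]


def _smooth_noise(shape, rng, sigma_ln, corr=2.5) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr)
    f = f / max(f.std(), 1e-9) * sigma_ln
    return np.exp(f - 0.5 * sigma_ln ** 2)


def generate_month(grid: GridSpec, params: WorldParams, year_index: int,
                   month_label: str, seed: int = 0) -> MonthSample:
    """Generate one month of emissions and meteorology (truth unset).

    Land emissions follow per-species interannual declines and per-sector
    seasonal factors; shipping activity is seasonally modulated but has no
    interannual trend except in ``fuel_switch_year_index``, where the global
    fuel-sulfur cap cuts shipping SO2 to 30% and primary PM to 85% of their
    prior level, making the final year the extreme held-out sample.
    """
    if month_label not in MONTHS:
        raise WorldError(f"month_label must be one of {MONTHS}")
    m = MONTHS.index(month_label)
    rng = np.random.default_rng([int(seed), int(year_index), m, 3])

    templates = _land_templates(grid, params)
    land = np.zeros((len(LAND_SECTORS), len(LAND_SPECIES)) + grid.shape)
    for i, sector in enumerate(LAND_SECTORS):
        noise = _smooth_noise(grid.shape, rng, params.emission_noise)
        for j, species in enumerate(LAND_SPECIES):
            total = (BASE_LAND_TOTALS[i, j]
                     * LAND_TREND[species] ** year_index
                     * MONTH_FACTORS[sector][m])
            land[i, j] = total * templates[sector] * noise

    def ship_year_factor(species: str) -> float:
        # In the fuel-switch year the global sulfur cap resets shipping SO2
        # to 30% of its year-0 level and trims primary PM; other species keep
        # their trend.
        if year_index == params.fuel_switch_year_index:
            if species == "SO2":
                return params.fuel_switch_so2_factor
            if species == "PM":
                return (SHIP_TREND["PM"] ** year_index
                        * params.fuel_switch_pm_factor)
        return SHIP_TREND[species] ** year_index

    ship_totals = base_shipping_totals(params)
    intensity = shipping_intensity(grid)
    ship = np.zeros((len(VESSEL_CLASSES), len(SHIP_SPECIES)) + grid.shape)
    for i, vessel in enumerate(VESSEL_CLASSES):
        tmpl = _normalized(intensity[i])
        for j, species in enumerate(SHIP_SPECIES):
            noise = _smooth_noise(grid.shape, rng, params.emission_noise)
            total = ship_totals[i, j] * SHIP_MONTH_FACTORS[m] * ship_year_factor(species)
            ship[i, j] = total * tmpl * noise

    # Cell-level noise perturbs totals slightly; restore exact species totals
    # so domain aggregates (shares, interannual ratios) are deterministic.
    for j in range(len(LAND_SPECIES)):
        for i, sector in enumerate(LAND_SECTORS):
            want = (BASE_LAND_TOTALS[i, j] * LAND_TREND[LAND_SPECIES[j]] ** year_index
                    * MONTH_FACTORS[sector][m])
            got = land[i, j].sum()
            if got > 0:
                land[i, j] *= want / got
    for j, species in enumerate(SHIP_SPECIES):
        for i in range(len(VESSEL_CLASSES)):
            want = ship_totals[i, j] * SHIP_MONTH_FACTORS[m] * ship_year_factor(species)
            got = ship[i, j].sum()
            if got > 0:
                ship[i, j] *= want / got

    ws_c, t2_c, rh_c, pblh_c = MET_CLIMO[month_label]
    lat = np.linspace(1.0, -1.0, grid.ny)[:, None] * np.ones(grid.shape)
    met = MetBundle(
        ws10=np.clip(ws_c * _smooth_noise(grid.shape, rng, 0.15, 3.0), 0.1, None),
        wd10=np.mod(180.0 + 120.0 * ndimage.gaussian_filter(
            rng.standard_normal(grid.shape), 4.0), 360.0),
        t2=t2_c - 4.0 * lat + ndimage.gaussian_filter(
            rng.standard_normal(grid.shape), 3.0),
        rh=np.clip(rh_c * _smooth_noise(grid.shape, rng, 0.08, 3.0), 5.0, 100.0),
        pblh=np.clip(pblh_c * _smooth_noise(grid.shape, rng, 0.12, 3.0), 100.0, None),
    )
    emis = EmissionBundle(land=land, shipping=ship)
    emis.validate(grid)
    met.validate()
    return MonthSample(year_index=year_index, month_label=month_label,
                       emissions=emis, met=met)


# ---------------------------------------------------------------------------
# Surrogate chemistry
# ---------------------------------------------------------------------------

def oxidant_factor(n: float, v: float, params: WorldParams) -> float:
    """Oxidant regime factor X(n, v), normalized so X(1, 1) = 1.

    Monotone increasing in the VOC ratio v; non-monotone in the NOx ratio n,
    with a Gaussian titration bump centred at ``titration_center``.
    """
    def raw(nn, vv):
        bump = params.titration_gamma * np.exp(
            -((nn - params.titration_center) ** 2) / params.titration_width)
        return vv ** params.oxidant_p * (nn ** params.oxidant_q + bump)

    return raw(n, v) / raw(1.0, 1.0)


def dispersion_sigma(met: MetBundle, params: WorldParams) -> float:
    """Met-dependent Gaussian kernel width in cells, clipped to bounds."""
    sig = params.sigma0 * float(met.ws10.mean()) / (float(met.pblh.mean()) / 1000.0)
    return float(np.clip(sig, *params.sigma_bounds))


def surrogate_chemistry(emissions: EmissionBundle, met: MetBundle,
                        params: WorldParams) -> SourcePMBundle:
    """Closed-form stand-in for CTM source apportionment.

    Each tagged group's primary PM is dispersed by a met-dependent Gaussian
    kernel; secondary sulfate, nitrate and organic matter are yield-scaled
    dispersed precursor emissions, all multiplied by the shared oxidant
    factor X computed from domain-total land NOx and VOC.  The "other" group
    is a static background.  Deterministic; additive over groups.
    """
    params.validate()
    if np.any(emissions.land < 0) or np.any(emissions.shipping < 0):
        raise WorldError("negative emissions rejected")
    sigma = dispersion_sigma(met, params)
    conv = params.mixing_coeff / float(met.pblh.mean())

    def disp(f):
        return ndimage.gaussian_filter(f, sigma, mode="nearest")

    nox_total = float(emissions.land_species("NOx").sum())
    voc_total = float(emissions.land_species("VOC").sum())
    ref_n = params.ref_land_nox if params.ref_land_nox else nox_total
    ref_v = params.ref_land_voc if params.ref_land_voc else voc_total
    X = oxidant_factor(nox_total / ref_n, voc_total / ref_v, params)

    shape = emissions.land.shape[-2:]
    pm25 = np.zeros((len(SOURCE_GROUPS),) + shape)
    comps = np.zeros((len(SOURCE_GROUPS), len(COMPONENTS)) + shape)

    def fill(gi, so2, nox, voc, pm):
        sulfate = params.sulfate_yield * X * conv * disp(so2)
        nitrate = params.nitrate_yield * X * conv * disp(nox)
        som = params.som_yield * X * conv * disp(voc)
        pom = params.pom_yield * conv * disp(pm)
        other_prim = params.other_primary_frac * conv * disp(pm)
        comps[gi] = np.stack([sulfate, nitrate, som, pom])
        pm25[gi] = sulfate + nitrate + som + pom + other_prim

    fill(SOURCE_GROUPS.index("land"),
         emissions.land_species("SO2"), emissions.land_species("NOx"),
         emissions.land_species("VOC"), emissions.land_species("PM"))
    for vessel in VESSEL_CLASSES:
        vi = VESSEL_CLASSES.index(vessel)
        gi = SOURCE_GROUPS.index(vessel)
        fill(gi, emissions.shipping[vi, SHIP_SPECIES.index("SO2")],
             emissions.shipping[vi, SHIP_SPECIES.index("NOx")],
             emissions.shipping[vi, SHIP_SPECIES.index("VOC")],
             emissions.shipping[vi, SHIP_SPECIES.index("PM")])

    gi = SOURCE_GROUPS.index("other")
    pm25[gi] = params.background * np.ones(shape)
    for ci, frac in enumerate(params.background_comp_frac):
        comps[gi, ci] = params.background * frac * np.ones(shape)

    bundle = SourcePMBundle(pm25=pm25, components=comps)
    bundle.validate()
    return bundle


def set_oxidant_reference(params: WorldParams, samples: list) -> None:
    """Fix the oxidant-normalization reference to the mean land totals of the
    earliest year present in ``samples`` (idempotent if already set)."""
    if params.ref_land_nox is not None and params.ref_land_voc is not None:
        return
    y0 = min(s.year_index for s in samples)
    base = [s for s in samples if s.year_index == y0]
    params.ref_land_nox = float(np.mean(
        [s.emissions.land_species("NOx").sum() for s in base]))
    params.ref_land_voc = float(np.mean(
        [s.emissions.land_species("VOC").sum() for s in base]))


# ---------------------------------------------------------------------------
# Dataset assembly and NetCDF round-trip
# ---------------------------------------------------------------------------

def make_dataset(grid: GridSpec, params: WorldParams, n_years: int = 5,
                 seed: int = 0) -> list:
    """Generate the full multi-year dataset with surrogate truth attached.

    Four months per year; the final year is flagged as the held-out test
    year (it carries the fuel-switch emission discontinuity).
    """
    if n_years < 2:
        raise WorldError("need at least 2 years (train + test)")
    samples = []
    for year in range(n_years):
        for month in MONTHS:
            samples.append(generate_month(grid, params, year, month, seed))
    set_oxidant_reference(params, samples)
    for s in samples:
        s.truth = surrogate_chemistry(s.emissions, s.met, params)
        s.is_test = s.year_index == n_years - 1
    return samples


def _grid_to_vars(grid: GridSpec) -> dict:
    return {
        "land_mask": (("y", "x"), grid.land_mask.astype(np.int8)),
        "dist_coast_nm": (("y", "x"), grid.dist_coast_nm),
        "region_id": (("y", "x"), grid.region_id.astype(np.int8)),
        "river_mask": (("y", "x"), grid.river_mask.astype(np.int8)),
        "port_mask": (("y", "x"), grid.port_mask.astype(np.int8)),
    }


def save_dataset(path, samples: list, grid: GridSpec, params: WorldParams) -> None:
    """Write samples + grid + params to a NetCDF file (scipy engine)."""
    try:
        n = len(samples)
        ds = xr.Dataset(
            data_vars={
                "land_emis": (("time", "sector", "species", "y", "x"),
                              np.stack([s.emissions.land for s in samples])),
                "ship_emis": (("time", "vessel", "ship_species", "y", "x"),
                              np.stack([s.emissions.shipping for s in samples])),
                "met": (("time", "met_var", "y", "x"),
                        np.stack([s.met.as_stack() for s in samples])),
                "pm25": (("time", "group", "y", "x"),
                         np.stack([s.truth.pm25 for s in samples])),
                "pm25_components": (("time", "group", "component", "y", "x"),
                                    np.stack([s.truth.components for s in samples])),
                "year_index": (("time",), np.array([s.year_index for s in samples])),
                "month_index": (("time",),
                                np.array([MONTHS.index(s.month_label) for s in samples])),
                "is_test": (("time",), np.array([s.is_test for s in samples], dtype=np.int8)),
                **_grid_to_vars(grid),
            },
            attrs={
                "cell_km": grid.cell_km, "grid_seed": grid.seed,
                "sector_labels": ",".join(LAND_SECTORS),
                "species_labels": ",".join(LAND_SPECIES),
                "vessel_labels": ",".join(VESSEL_CLASSES),
                "ship_species_labels": ",".join(SHIP_SPECIES),
                "met_labels": ",".join(MetBundle.FIELDS),
                "group_labels": ",".join(SOURCE_GROUPS),
                "component_labels": ",".join(COMPONENTS),
                "emission_units": "Mg/month/cell",
                "concentration_units": "ug/m3",
                "params_yaml": _params_to_yaml(params),
            },
        )
        ds.to_netcdf(path, engine="scipy")
    except OSError as exc:  # surface I/O failures with path context
        raise OSError(f"failed writing dataset to {path}: {exc}") from exc


def _params_to_yaml(params: WorldParams) -> str:
    import yaml

    d = dataclasses.asdict(params)
    d["sigma_bounds"] = list(d["sigma_bounds"])
    d["background_comp_frac"] = list(d["background_comp_frac"])
    return yaml.safe_dump(d)


def _params_from_yaml(text: str) -> WorldParams:
    import yaml

    d = yaml.safe_load(text)
    d["sigma_bounds"] = tuple(d["sigma_bounds"])
    d["background_comp_frac"] = tuple(d["background_comp_frac"])
    return WorldParams(**d)


def load_dataset(path):
    """Read a dataset written by :func:`save_dataset`.

    Returns ``(samples, grid, params)`` with arrays bitwise-identical to the
    ones written.
    """
    try:
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
    except OSError as exc:
        raise OSError(f"failed reading dataset from {path}: {exc}") from exc
    grid = GridSpec(
        nx=ds.sizes["x"], ny=ds.sizes["y"], cell_km=float(ds.attrs["cell_km"]),
        land_mask=ds["land_mask"].values.astype(bool),
        dist_coast_nm=ds["dist_coast_nm"].values,
        region_id=ds["region_id"].values.astype(np.int8),
        river_mask=ds["river_mask"].values.astype(bool),
        port_mask=ds["port_mask"].values.astype(bool),
        seed=int(ds.attrs["grid_seed"]),
    )
    params = _params_from_yaml(ds.attrs["params_yaml"])
    samples = []
    for t in range(ds.sizes["time"]):
        samples.append(MonthSample(
            year_index=int(ds["year_index"][t]),
            month_label=MONTHS[int(ds["month_index"][t])],
            emissions=EmissionBundle(land=ds["land_emis"][t].values,
                                     shipping=ds["ship_emis"][t].values),
            met=MetBundle(*[ds["met"][t, i].values
                            for i in range(len(MetBundle.FIELDS))]),
            truth=SourcePMBundle(pm25=ds["pm25"][t].values,
                                 components=ds["pm25_components"][t].values),
            is_test=bool(ds["is_test"][t]),
        ))
    return samples, grid, params
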