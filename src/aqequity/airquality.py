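"""Reduced-complexity atmospheric model.

Annual-average, sector-averaged Gaussian plume dispersion maps each
source county's NOx, SO2 and primary PM2.5 emissions onto ambient
PM2.5 at every receptor county (population-weighted centroids serve
as both discharge and receptor points).  Sources release from one of
four effective-height bins (ground for on-road traffic; low, medium
or tall for point sources — most fossil EGUs fall in the medium,
250-500 m, bin).

Secondary inorganic PM forms at the receptor: dispersed SO2 and NOx
are partially oxidised to sulfate and nitric acid, which partition
against a fixed county ammonia budget — sulfate is neutralised first
(as ammonium sulfate when ammonia suffices, sulfuric acid otherwise)
and nitrate PM (ammonium nitrate) forms only from the free ammonia
that remains.  Because this partition is nonlinear, marginal
concentrations are computed with an add-one-ton algorithm against a
fixed baseline inventory: add 1 ton at the source, recompute the full
speciated field, subtract the baseline field, reset.  Multiplying
scenario emissions by these marginal concentrations gives the total
PM2.5-equivalent field, additive by source sector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRAMS_PER_SHORT_TON = 907_184.74
SECONDS_PER_YEAR = 3.15576e7
N_SECTORS = 16

# Molar masses, g/mol.
MW = {"SO2": 64.0, "NO2": 46.0, "SO4": 96.0, "NO3": 62.0, "AMSO4": 132.0, "AMNO3": 80.0, "H2SO4": 98.0}

BIN_HEIGHTS = {"ground": 0.0, "low": 125.0, "medium": 375.0, "tall": 750.0}


@dataclass(frozen=True)
class MetConfig:
    """Annual meteorology for the plume kernels.

    A single annual wind rose (16 sectors), one transport speed, a
    rural neutral-stability vertical-dispersion closure
    sigma_z(x) = a*x / (1 + b*x)^c with x in metres, and a well-mixed
    boundary-layer cap.
    """

    sector_freq: tuple = tuple([1.0 / N_SECTORS] * N_SECTORS)
    wind_speed: float = 4.0  # m/s
    sigma_z_coeffs: tuple = (0.06, 0.0015, 0.5)
    mixing_height: float = 1000.0  # m
    bin_height: dict = field(default_factory=lambda: dict(BIN_HEIGHTS))
    calibration: float = 1.0  # multiplicative scalar (monitor calibration stand-in)

    def __post_init__(self):
        f = np.asarray(self.sector_freq)
        if len(f) != N_SECTORS or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("sector frequencies must be 16 nonnegative values summing to 1")
        if self.wind_speed <= 0:
            raise ValueError("wind speed must be positive")


@dataclass(frozen=True)
class ChemConfig:
    """Receptor-side inorganic chemistry parameters.

    ``frac_so2_to_so4`` / ``frac_nox_to_hno3`` are the annual-average
    fractions of the dispersed precursor oxidised at the receptor.
    ``ammonia_budget_umol`` is each county's available ammonia in
    µmol/m³ against which sulfate and nitrate partition.
    """

    frac_so2_to_so4: float = 0.15
    frac_nox_to_hno3: float = 0.25
    default_ammonia_umol: float = 0.5
    ammonia_budget_umol: dict = field(default_factory=dict)  # county_id -> µmol/m³

    def __post_init__(self):
        if not (0 <= self.frac_so2_to_so4 <= 1 and 0 <= self.frac_nox_to_hno3 <= 1):
            raise ValueError("conversion fractions must lie in [0, 1]")
        if any(v < 0 for v in self.ammonia_budget_umol.values()) or self.default_ammonia_umol < 0:
            raise ValueError("ammonia budgets must be nonnegative")

    def ammonia(self, county_id: str) -> float:
        return self.ammonia_budget_umol.get(county_id, self.default_ammonia_umol)


def sigma_z(x, coeffs=(0.06, 0.0015, 0.5)):
    """Vertical dispersion coefficient sigma_z(x) = a*x/(1+b*x)^c, metres."""
    a, b, c = coeffs
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("downwind distance must be positive")
    return a * x / (1.0 + b * x) ** c


def plume_kernel(distance, height_bin: str, met: MetConfig, emission_rate: float = 1.0,
                 sector_frequency: float | None = None):
    """Sector-averaged annual ground-level concentration, µg/m³.

    C = min( 2 Q f_s / (sqrt(2 pi) sigma_z u w) * exp(-H^2 / (2 sigma_z^2)),
             Q f_s / (w z_mix u) )
    with w = 2 pi x / 16 the sector arc width, Q the emission rate
    converted from short tons/yr to g/s, and H the bin release height.
    The second limb caps the near-ground reflection solution with a
    well-mixed boundary-layer box.  ``distance`` in metres.
    """
    if emission_rate < 0:
        raise ValueError("emission rate must be nonnegative")
    x = np.asarray(distance, dtype=float)
    f_s = (1.0 / N_SECTORS) if sector_frequency is None else sector_frequency
    q = emission_rate * GRAMS_PER_SHORT_TON / SECONDS_PER_YEAR  # g/s
    sz = sigma_z(x, met.sigma_z_coeffs)
    w = 2.0 * np.pi * x / N_SECTORS
    h = met.bin_height[height_bin]
    gauss = (
        2.0 * q * f_s / (np.sqrt(2.0 * np.pi) * sz * met.wind_speed * w)
        * np.exp(-(h * h) / (2.0 * sz * sz))
    )
    box = q * f_s / (w * met.mixing_height * met.wind_speed)
    c_g_m3 = np.minimum(gauss, box)
    return c_g_m3 * 1e6 * met.calibration  # µg/m³


def _bearing_sector(dx, dy):
    """Wind-rose sector (0-15) of the source -> receptor bearing."""
    ang = np.arctan2(dy, dx) % (2.0 * np.pi)
    return (np.floor(ang / (2.0 * np.pi / N_SECTORS)).astype(int)) % N_SECTORS


class KernelSet:
    """Precomputed plume kernel matrices K[bin][i, j]: µg/m³ at
    receptor j per short ton/yr released in county i from the bin.

    Distances are between population-weighted centroids (km in the
    geography, converted to metres); the self-receptor distance is
    floored at 0.5*sqrt(area/pi) to avoid the x -> 0 singularity, and
    any shorter inter-county distance is clamped to the same floor.
    """

    def __init__(self, counties: pd.DataFrame, met: MetConfig):
        self.county_ids = counties["county_id"].tolist()
        self.met = met
        px = counties["pw_x"].to_numpy() * 1000.0
        py = counties["pw_y"].to_numpy() * 1000.0
        dx = px[None, :] - px[:, None]
        dy = py[None, :] - py[:, None]
        dist = np.hypot(dx, dy)
        x_min = 0.5 * np.sqrt(counties["area"].to_numpy() * 1e6 / np.pi)
        clamped = (dist < x_min[:, None]) & ~np.eye(len(px), dtype=bool)
        if clamped.any():
            logging.getLogger(__name__).debug(
                "%d inter-county distances clamped to the near-field floor", clamped.sum()
            )
        dist = np.maximum(dist, x_min[:, None])
        freq = np.asarray(met.sector_freq)[_bearing_sector(dx, dy)]
        self.matrices = {
            b: plume_kernel(dist, b, met, 1.0, sector_frequency=freq)
            for b in BIN_HEIGHTS
        }

    def kernel(self, height_bin: str) -> np.ndarray:
        return self.matrices[height_bin]


def _emissions_matrix(emissions: pd.DataFrame, county_ids: list, pollutant: str,
                      height_bin: str, period=None, sector=None) -> np.ndarray:
    """Vector of tons/yr by source county for one species/bin slice."""
    e = emissions[(emissions["pollutant"] == pollutant) & (emissions["height_bin"] == height_bin)]
    if period is not None:
        e = e[e["period"] == period]
    if sector is not None:
        e = e[e["sector"] == sector]
    v = e.groupby("county_id")["tons"].sum()
    idx = pd.Index(county_ids)
    return v.reindex(idx, fill_value=0.0).to_numpy()


def speciated_field(
    emissions: pd.DataFrame,
    kernels: KernelSet,
    chem: ChemConfig,
    period=None,
    sector=None,
) -> pd.DataFrame:
    """Full speciated PM2.5 field from a county emission table.

    Each precursor/bin slice is dispersed with its kernel; sulfate and
    nitrate then partition against the receptor ammonia budget.
    Returns a per-receptor DataFrame with columns ``primary``,
    ``sulfate``, ``nitrate`` and ``total`` (µg/m³), indexed by
    county_id.
    """
    ids = kernels.county_ids
    n = len(ids)
    primary = np.zeros(n)
    so2 = np.zeros(n)
    nox = np.zeros(n)
    for b in BIN_HEIGHTS:
        k = kernels.kernel(b)
        primary += _emissions_matrix(emissions, ids, "PM2.5", b, period, sector) @ k
        so2 += _emissions_matrix(emissions, ids, "SO2", b, period, sector) @ k
        nox += _emissions_matrix(emissions, ids, "NOx", b, period, sector) @ k

    sulfate_umol = so2 * chem.frac_so2_to_so4 / MW["SO2"]  # µmol/m³
    nitrate_demand_umol = nox * chem.frac_nox_to_hno3 / MW["NO2"]
    ammonia = np.array([chem.ammonia(c) for c in ids])

    sulf_pm = np.empty(n)
    nitr_pm = np.empty(n)
    for j in range(n):
        s, nd = partition_inorganic(sulfate_umol[j], nitrate_demand_umol[j], ammonia[j])
        sulf_pm[j] = s
        nitr_pm[j] = nd
    return pd.DataFrame(
        {
            "primary": primary,
            "sulfate": sulf_pm,
            "nitrate": nitr_pm,
            "total": primary + sulf_pm + nitr_pm,
        },
        index=pd.Index(ids, name="county_id"),
    )


def partition_inorganic(sulfate_umol: float, nitrate_demand_umol: float,
                        ammonia_umol: float) -> tuple[float, float]:
    """Partition sulfate and nitrate against the ammonia budget.

    Sulfate always forms PM: as ammonium sulfate (mass factor 132/96
    on sulfate mass) when free ammonia covers 2 mol NH3 per mol
    sulfate, otherwise as sulfuric acid (98/96).  Ammonium nitrate
    forms only from ammonia left after sulfate neutralisation:
    nitrate PM = min(demand, free ammonia) * 80/62 on nitrate mass.

    Inputs in µmol/m³; returns (sulfate PM, nitrate PM) in µg/m³.
    """
    if sulfate_umol < 0 or nitrate_demand_umol < 0 or ammonia_umol < 0:
        raise ValueError("partition inputs must be nonnegative")
    if ammonia_umol >= 2.0 * sulfate_umol:
        sulf_pm = sulfate_umol * MW["AMSO4"]
    else:
        sulf_pm = sulfate_umol * MW["H2SO4"]
    free = max(0.0, ammonia_umol - 2.0 * sulfate_umol)
    nitr_pm = min(nitrate_demand_umol, free) * MW["AMNO3"]
    return sulf_pm, nitr_pm


@dataclass
class SourceReceptorSet:
    """Marginal concentrations per (source county, pollutant, bin).

    ``matrices[(pollutant, bin)]`` is an (n_sources, n_receptors)
    array of µg/m³ per short ton/yr, computed by the add-one-ton
    algorithm against the stored baseline.  Entries are clipped at
    zero (a marginal ton of SO2 can displace ammonium nitrate at an
    ammonia-limited receptor; the clip keeps the matrices physically
    interpretable as nonnegative transfer coefficients).
    """

    county_ids: list
    matrices: dict

    def matrix(self, pollutant: str, height_bin: str) -> np.ndarray:
        return self.matrices[(pollutant, height_bin)]

    def to_frame(self) -> pd.DataFrame:
        """Dense long-format serialisation (source, pollutant, bin, receptor, value)."""
        rows = []
        for (pol, b), m in self.matrices.items():
            df = pd.DataFrame(m, index=self.county_ids, columns=self.county_ids)
            df.index.name = "source_county"
            long = df.reset_index().melt(
                id_vars="source_county", var_name="receptor_county", value_name="ug_m3_per_ton"
            )
            long.insert(1, "pollutant", pol)
            long.insert(2, "height_bin", b)
            rows.append(long)
        return pd.concat(rows, ignore_index=True)


def marginal_concentrations(
    source_county: str,
    pollutant: str,
    height_bin: str,
    baseline: pd.DataFrame,
    kernels: KernelSet,
    chem: ChemConfig,
    tons: float = 1.0,
) -> np.ndarray:
    """Add-one-ton marginal concentration vector for one source.

    Computes the full speciated field from the baseline inventory,
    adds ``tons`` of the pollutant at the source county in the given
    height bin, recomputes, and returns (new - baseline) per receptor,
    normalised per ton and clipped at zero.  The baseline is never
    mutated.  For primary PM2.5 the result is baseline-independent
    (the chemistry is linear in it); for SO2 and NOx it reflects the
    receptor ammonia remaining after the baseline.
    """
    if pollutant not in ("NOx", "SO2", "PM2.5"):
        raise ValueError(f"unknown pollutant {pollutant!r}")
    if tons == 0:
        return np.zeros(len(kernels.county_ids))
    base_field = speciated_field(baseline, kernels, chem)["total"].to_numpy()
    bump = pd.DataFrame(
        [
            {
                "county_id": source_county,
                "sector": "marginal",
                "pollutant": pollutant,
                "height_bin": height_bin,
                "period": 0,
                "tons": tons,
            }
        ]
    )
    pert = pd.concat([baseline, bump], ignore_index=True)
    new_field = speciated_field(pert, kernels, chem)["total"].to_numpy()
    return np.clip((new_field - base_field) / tons, 0.0, None)


def build_source_receptor_set(
    counties: pd.DataFrame,
    baseline: pd.DataFrame,
    met: MetConfig,
    chem: ChemConfig,
    bins_by_pollutant: dict | None = None,
) -> SourceReceptorSet:
    """Marginal-concentration matrices for every source county.

    ``bins_by_pollutant`` restricts which height bins are computed per
    pollutant (default: ground and medium for all three species, the
    bins the two modelled sectors actually use).

    The add-one-ton differencing is vectorised: all sources of one
    (pollutant, bin) pair share the baseline fields, and the partition
    step is evaluated per receptor on the perturbed precursor columns.
    """
    bins_by_pollutant = bins_by_pollutant or {
        p: ["ground", "medium"] for p in ("NOx", "SO2", "PM2.5")
    }
    kernels = KernelSet(counties, met)
    ids = kernels.county_ids
    n = len(ids)
    ammonia = np.array([chem.ammonia(c) for c in ids])

    # Baseline precursor concentrations by receptor.
    base_prim = np.zeros(n)
    base_so2 = np.zeros(n)
    base_nox = np.zeros(n)
    for b in BIN_HEIGHTS:
        k = kernels.kernel(b)
        base_prim += _emissions_matrix(baseline, ids, "PM2.5", b) @ k
        base_so2 += _emissions_matrix(baseline, ids, "SO2", b) @ k
        base_nox += _emissions_matrix(baseline, ids, "NOx", b) @ k

    def total_from(prim, so2, nox):
        sulf_umol = so2 * chem.frac_so2_to_so4 / MW["SO2"]
        nitr_umol = nox * chem.frac_nox_to_hno3 / MW["NO2"]
        rich = ammonia >= 2.0 * sulf_umol
        sulf_pm = np.where(rich, sulf_umol * MW["AMSO4"], sulf_umol * MW["H2SO4"])
        free = np.maximum(0.0, ammonia - 2.0 * sulf_umol)
        nitr_pm = np.minimum(nitr_umol, free) * MW["AMNO3"]
        return prim + sulf_pm + nitr_pm

    base_total = total_from(base_prim, base_so2, base_nox)

    matrices = {}
    for pol, bins in bins_by_pollutant.items():
        for b in bins:
            k = kernels.kernel(b)  # row i = field of 1 ton from county i
            m = np.empty((n, n))
            for i in range(n):
                if pol == "PM2.5":
                    new_total = total_from(base_prim + k[i], base_so2, base_nox)
                elif pol == "SO2":
                    new_total = total_from(base_prim, base_so2 + k[i], base_nox)
                else:
                    new_total = total_from(base_prim, base_so2, base_nox + k[i])
                m[i] = np.clip(new_total - base_total, 0.0, None)
            matrices[(pol, b)] = m
    return SourceReceptorSet(county_ids=ids, matrices=matrices)


def total_pm_field(
    emissions: pd.DataFrame,
    sr: SourceReceptorSet,
    by_sector: bool = False,
) -> pd.DataFrame:
    """Total PM2.5-equivalent field: emissions x marginal concentrations.

    C(j) = sum over sources, pollutants, bins of E(s, p, bin) *
    M(s, p, bin -> j), per period (and per sector when requested, so
    source-sector attribution survives the totalisation).

    Returns a tidy frame ``county_id, period[, sector], conc``.
    """
    ids = sr.county_ids
    need = (
        emissions.loc[emissions["tons"] > 0, ["pollutant", "height_bin"]]
        .drop_duplicates()
    )
    missing = [
        (p, b) for p, b in need.itertuples(index=False) if (p, b) not in sr.matrices
    ]
    if missing:
        raise KeyError(f"source-receptor set lacks entries for: {missing}")
    group_cols = ["period", "sector"] if by_sector else ["period"]
    out = []
    for keys, grp in emissions.groupby(group_cols):
        conc = np.zeros(len(ids))
        for (pol, b), sub in grp.groupby(["pollutant", "height_bin"]):
            e = sub.groupby("county_id")["tons"].sum().reindex(ids, fill_value=0.0).to_numpy()
            conc += e @ sr.matrix(pol, b)
        rec = pd.DataFrame({"county_id": ids, "conc": conc})
        for c, v in zip(group_cols, keys if isinstance(keys, tuple) else (keys,)):
            rec[c] = v
        out.append(rec)
    cols = ["county_id"] + group_cols + ["conc"]
    return pd.concat(out, ignore_index=True)[cols]
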