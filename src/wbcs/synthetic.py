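"""Synthetic climate grids with the structure of a strongly continental
mid-latitude territory, plus deterministic fixtures covering every
classification branch.

:func:`generate_grids` emulates the statistical features the analysis
assumes from a regional-climate-model climatology over a large Central
Asian country: a south-to-north cooling and wetting gradient, very high
annual thermal amplitude on the plains (continentality index mostly in
the eucontinental 28–46 band), summer-dry precipitation regimes in the
south grading to summer-wet in the north, a small fraction of high
mountain cells (cooler, wetter, more summer rain), and per-period
climate-change deltas with summer warming exceeding winter warming and
near-stable precipitation.

:func:`branch_fixtures` engineers a small noiseless grid directly from
the ruleset's interval midpoints so that every bioclimate, thermotype,
ombrotype, variant and continentality subtype reported for the study
territory is exercised by at least one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CANONICAL_COLUMNS, CellRecord, ClimateGrid
from .ruleset import ClassificationRuleset, RulesetError, default_ruleset

__all__ = ["SyntheticGridSpec", "generate_grids", "branch_fixtures"]

_MONTHS = np.arange(1, 13)
# seasonal shape: +1 in July, -1 in January
_SEASON = np.cos(2.0 * np.pi * (_MONTHS - 7) / 12.0)


@dataclass
class SyntheticGridSpec:
    """Parameters of the synthetic climatology; defaults are the study
    conditions (a 4569-cell, 0.22-degree continental territory spanning
    roughly 40.5-55.5 N with three 25-year periods under strong warming).
    """

    n_cells: int = 4569
    lat_bounds: tuple[float, float] = (40.5, 55.5)
    lon_bounds: tuple[float, float] = (46.5, 87.2)
    resolution_deg: float = 0.22
    cell_area_km2: float = 590.9
    mountain_fraction: float = 0.08
    mountain_elev_range: tuple[float, float] = (1200.0, 3500.0)
    plain_elev_range: tuple[float, float] = (100.0, 600.0)
    baseline_T: float = 10.0          # deg C annual mean at reference_lat, 200 m
    reference_lat: float = 43.0
    lat_lapse: float = 0.55           # deg C per degree latitude northward
    elev_lapse: float = 0.6           # deg C per 100 m
    amplitude: float = 17.0           # deg C, half peak-to-trough seasonal cycle
    amplitude_jitter: float = 2.0     # per-cell spread of the amplitude
    diurnal_half_range: float = 5.0   # tmax/tmin = Ti +/- this
    precip_south: float = 110.0       # mm / year at the southern edge
    precip_north: float = 380.0       # mm / year at the northern edge
    orographic_factor_per_km: float = 0.9
    summer_dryness_south: float = -0.05  # ~uniform rain; aridity driven by heat
    summer_dryness_north: float = -0.55  # markedly summer-peaked regime
    mountain_summer_dryness_delta: float = -0.25
    # (winter offset, summer offset) in deg C per period, and precip scale
    period_temp_offsets: tuple = ((0.0, 0.0), (1.2, 1.8), (2.2, 3.2))
    period_precip_scale: tuple = (1.0, 1.0, 0.98)
    period_labels: tuple = ("1980-2004", "2010-2034", "2035-2059")
    noise_temp_sd: float = 0.3        # deg C on monthly means
    noise_precip_frac: float = 0.05   # multiplicative on monthly totals
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if len(self.period_temp_offsets) != len(self.period_precip_scale):
            raise ValueError("period offset/scale lengths disagree")
        if any(s < w for w, s in self.period_temp_offsets):
            raise ValueError("summer offset must be >= winter offset")


def generate_grids(spec: SyntheticGridSpec) -> list[ClimateGrid]:
    """One ClimateGrid per period; fully determined by the spec and seed."""
    rng = np.random.default_rng(spec.seed)
    lat0, lat1 = spec.lat_bounds
    lon0, lon1 = spec.lon_bounds

    # regular lattice, row-major from the south-west corner
    nlon = max(int(np.floor((lon1 - lon0) / spec.resolution_deg)), 1)
    k = np.arange(spec.n_cells)
    lat = lat0 + (k // nlon) * spec.resolution_deg
    lon = lon0 + (k % nlon) * spec.resolution_deg
    if np.any(lat > lat1):
        raise ValueError("n_cells does not fit in the lat/lon bounds")

    n = spec.n_cells
    n_mtn = int(round(spec.mountain_fraction * n))
    # mountains sit preferentially in the east/south-east of the domain
    pref = np.argsort(-(0.6 * (lon - lon0) / max(lon1 - lon0, 1e-9)
                        + 0.4 * (lat1 - lat) / max(lat1 - lat0, 1e-9)))
    mountain = np.zeros(n, dtype=bool)
    mountain[pref[: 3 * n_mtn + 1][rng.permutation(min(3 * n_mtn + 1, n))[:n_mtn]]] = True
    elev = rng.uniform(*spec.plain_elev_range, size=n)
    elev[mountain] = rng.uniform(*spec.mountain_elev_range, size=mountain.sum())

    amp = spec.amplitude + rng.normal(0.0, spec.amplitude_jitter, size=n)
    amp = np.clip(amp, 5.0, None)

    tmean = (
        spec.baseline_T
        - spec.lat_lapse * (lat - spec.reference_lat)
        - spec.elev_lapse * (elev - 200.0) / 100.0
    )
    frac_n = (lat - lat0) / max(lat1 - lat0, 1e-9)
    annual_p = spec.precip_south + (spec.precip_north - spec.precip_south) * frac_n
    annual_p = annual_p * (1.0 + spec.orographic_factor_per_km * np.minimum(elev, 3000.0) / 1000.0)
    dryness = (
        spec.summer_dryness_south
        + (spec.summer_dryness_north - spec.summer_dryness_south) * frac_n
    )
    dryness = dryness + spec.mountain_summer_dryness_delta * mountain
    dryness = np.clip(dryness, -0.95, 0.95)

    grids = []
    for (w_off, s_off), p_scale, label in zip(
        spec.period_temp_offsets, spec.period_precip_scale, spec.period_labels
    ):
        offset = w_off + (s_off - w_off) * (1.0 + _SEASON) / 2.0  # (12,)
        ti = (
            tmean[:, None]
            + amp[:, None] * _SEASON[None, :]
            + offset[None, :]
            + rng.normal(0.0, spec.noise_temp_sd, size=(n, 12))
        )
        shape = 1.0 - dryness[:, None] * _SEASON[None, :]
        prec = (annual_p[:, None] / 12.0) * shape * p_scale
        prec = prec * (1.0 + rng.normal(0.0, spec.noise_precip_frac, size=(n, 12)))
        prec = np.clip(prec, 0.0, None)

        df = pd.DataFrame({"cell_id": [f"c{i:05d}" for i in range(n)]})
        df["lat"], df["lon"], df["elev_m"] = lat, lon, elev
        for j in range(12):
            df[f"tmin_{j + 1:02d}"] = ti[:, j] - spec.diurnal_half_range
        for j in range(12):
            df[f"tmax_{j + 1:02d}"] = ti[:, j] + spec.diurnal_half_range
        for j in range(12):
            df[f"prec_{j + 1:02d}"] = prec[:, j]
        grids.append(
            ClimateGrid(
                df[CANONICAL_COLUMNS], label, spec.resolution_deg, spec.cell_area_km2
            )
        )
    return grids


# --------------------------------------------------------------------------
# engineered branch fixtures
# --------------------------------------------------------------------------

_SUMMER_BLOCK = slice(3, 9)  # Apr..Sep hold the warm plateau


def _engineer_cell(
    rs: ClassificationRuleset,
    cell_id: str,
    *,
    ic: float,
    tp: float,
    io: float,
    regime: str,        # "dry" (summer-arid) or "wet" / "wet-sbm" / "wet-nor"
    tp200: float | None = None,
    lat: float = 48.0,
    lon: float = 68.0,
    diurnal: float = 5.0,
) -> CellRecord:
    """Build a 6-month-plateau cell hitting the given Ic, Tp and Io exactly.

    Monthly means are a two-level profile (Apr-Sep warm plateau ``s``,
    other months ``w = s - ic``); precipitation is placed on April and
    September only (dry regime, producing uncompensated summer aridity)
    or mostly on the summer quarter (wet regimes, suppressing it).
    ``tp200`` requests an elevation such that the 200-m-reduced positive
    temperature hits that value (used to steer the macrobioclimate).
    """
    s0 = tp / 60.0
    if s0 - ic <= 0:
        s = s0
    else:
        s = (tp / 60.0 + ic) / 2.0
    w = s - ic
    if s <= 0:
        raise RulesetError(f"{cell_id}: cannot host plateau (s={s})")
    ti = np.full(12, w)
    ti[_SUMMER_BLOCK] = s

    if tp200 is None:
        elev = 200.0
    else:
        delta = tp200 / 60.0 - s
        if w + delta > 0:
            raise RulesetError(f"{cell_id}: reduction target not reachable")
        elev = 200.0 + 100.0 * delta / rs.reduction_coeff

    prec = np.zeros(12)
    if regime == "dry":
        x = io * tp / 20.0
        prec[3] = prec[8] = x  # April and September; none near the summer quarter
    elif regime in ("wet", "wet-sbm", "wet-nor"):
        jun = (2.6 if regime == "wet-sbm" else 3.2) * s
        prec[5], prec[6], prec[7] = jun, 3.2 * s, 3.2 * s
        pp = io * tp / 10.0
        rem = pp - prec[5:8].sum()
        if rem < 0:
            raise RulesetError(f"{cell_id}: Io target below the summer rain floor")
        prec[3] = prec[8] = rem / 2.0
    else:
        raise ValueError(f"unknown regime {regime!r}")

    return CellRecord(
        cell_id=cell_id,
        lat=lat,
        lon=lon,
        elevation=elev,
        tmin=ti - diurnal,
        tmax=ti + diurnal,
        prec=prec,
    )


def _mid(table, code: str) -> float:
    return table.midpoints()[code]


def branch_fixtures(
    ruleset: ClassificationRuleset | None = None,
) -> tuple[ClimateGrid, pd.DataFrame]:
    """Deterministic fixture grid covering every reported class.

    Returns the grid and a table of the engineered target labels
    (bioclimate, thermotype, ombrotype, variant, continentality subtype)
    per cell.  Raises :class:`RulesetError` if the loaded ruleset cannot
    host a fixture for some class combination.
    """
    rs = ruleset or default_ruleset()
    med_tp = rs.thermotype_by_tp["MEDITERRANEAN"].midpoints()
    tem_tp = rs.thermotype_by_tp["TEMPERATE"].midpoints()
    bor_tp = rs.thermotype_by_tp["BOREAL"].midpoints()
    omb = rs.ombrotype.midpoints()

    # itc-route helper for oceanic (Ic < 21) mediterranean cells:
    # It = 10*(3s - 2.5*ic) on the plateau profile with w > 0
    def tp_for_itc(itc: float, ic: float) -> float:
        s = (itc / 10.0 + 2.5 * ic) / 3.0
        return 60.0 * (2.0 * s - ic)

    med_itc = rs.thermotype_by_itc["MEDITERRANEAN"].midpoints()

    F: list[tuple[dict, CellRecord]] = []

    def add(name, target, **kw):
        F.append((target, _engineer_cell(rs, name, **kw)))

    ic_eu, ic_sub, ic_semi, ic_hyp = 33.0, 24.5, 18.0, 50.0
    gel_tp = rs.gelid_tp_max / 2.0

    add("f01", dict(bioclimate="MEPC", thermotype="Sme", ombrotype="Sec", variant="Stp",
                    continentality_subtype="Eucontinental"),
        ic=ic_eu, tp=med_tp["Sme"], io=omb["Sec"], regime="dry")
    add("f02", dict(bioclimate="MEPC", thermotype="Ome", ombrotype="Shu", variant="Stp"),
        ic=ic_eu, tp=med_tp["Ome"], io=omb["Shu"], regime="dry", tp200=900.0)
    add("f03", dict(bioclimate="MEPC", thermotype="Ome", ombrotype="Hum", variant="Nor"),
        ic=ic_eu, tp=med_tp["Ome"], io=omb["Hum"], regime="dry", tp200=900.0)
    add("f04", dict(bioclimate="MEPC", thermotype="Cme", ombrotype="Shu"),
        ic=ic_eu, tp=med_tp["Cme"], io=omb["Shu"], regime="dry", tp200=900.0)
    add("f05", dict(bioclimate="MEXO", thermotype="Sme", ombrotype="Sar",
                    continentality_subtype="Semicontinental"),
        ic=ic_semi, tp=tp_for_itc(med_itc["Sme"], ic_semi), io=omb["Sar"], regime="dry")
    add("f06", dict(bioclimate="MEXC", thermotype="Sme", ombrotype="Sar",
                    continentality_subtype="Subcontinental"),
        ic=ic_sub, tp=med_tp["Sme"], io=omb["Sar"], regime="dry")
    add("f07", dict(bioclimate="MEXC", thermotype="Mme", ombrotype="Sar",
                    continentality_subtype="Hypercontinental"),
        ic=ic_hyp, tp=med_tp["Mme"], io=omb["Sar"], regime="dry")
    add("f08", dict(bioclimate="MEDO", thermotype="Mme", ombrotype="Ari"),
        ic=ic_semi, tp=tp_for_itc(med_itc["Mme"], ic_semi), io=omb["Ari"], regime="dry")
    add("f09", dict(bioclimate="MEDC", thermotype="Sme", ombrotype="Ari", variant="Stp"),
        ic=ic_eu, tp=med_tp["Sme"], io=omb["Ari"], regime="dry")
    add("f10", dict(bioclimate="MEDC", thermotype="Tme", ombrotype="Ari"),
        ic=ic_eu, tp=med_tp["Tme"], io=omb["Ari"], regime="dry")
    add("f11", dict(bioclimate="MEDC", thermotype="Mme", ombrotype="Har"),
        ic=ic_eu, tp=med_tp["Mme"], io=omb["Har"], regime="dry")
    add("f12", dict(bioclimate="MEHC", thermotype="Sme", ombrotype="Uha", variant="Nor"),
        ic=ic_eu, tp=med_tp["Sme"], io=omb["Uha"], regime="dry")
    add("f13", dict(bioclimate="TECO", thermotype="Ote", ombrotype="Shu", variant="Sbm"),
        ic=ic_eu, tp=tem_tp["Ote"], io=omb["Shu"], regime="wet-sbm", tp200=900.0)
    add("f14", dict(bioclimate="TECO", thermotype="Cte", ombrotype="Hum"),
        ic=ic_eu, tp=tem_tp["Cte"], io=omb["Hum"], regime="wet-sbm", tp200=900.0)
    add("f15", dict(bioclimate="TECO", thermotype="Gel", ombrotype="Ssnw"),
        ic=ic_eu, tp=gel_tp, io=40.0, regime="wet-sbm", tp200=900.0)
    add("f16", dict(bioclimate="TEXE", thermotype="Ste", ombrotype="Sec", variant="Nor"),
        ic=ic_eu, tp=tem_tp["Ste"], io=omb["Sec"], regime="wet")
    add("f17", dict(bioclimate="BOCO", thermotype="Obo", ombrotype="Hum"),
        ic=ic_eu, tp=bor_tp["Obo"], io=omb["Hum"], regime="wet")
    add("f18", dict(bioclimate="BOCO", thermotype="Cbo", ombrotype="Hum"),
        ic=ic_eu, tp=bor_tp["Cbo"], io=omb["Hum"], regime="wet",
        tp200=(rs.macrobioclimate["polar_tp200_max"] + rs.macrobioclimate["boreal_tp200_max"]) / 2.0)
    add("f19", dict(bioclimate="BOXE", thermotype="Obo", ombrotype="Sec"),
        ic=ic_eu, tp=bor_tp["Obo"], io=omb["Sec"], regime="wet")
    add("f20", dict(bioclimate="TECO", thermotype="Cte", ombrotype="Uhh"),
        ic=ic_eu, tp=tem_tp["Cte"], io=omb["Uhh"], regime="wet", tp200=900.0)
    add("f21", dict(bioclimate="TECO", thermotype="Ote", ombrotype="Hhu"),
        ic=ic_eu, tp=tem_tp["Ote"], io=omb["Hhu"], regime="wet", tp200=900.0)

    targets = pd.DataFrame(
        [dict(cell_id=c.cell_id, **t) for t, c in F]
    )
    grid = ClimateGrid.from_cells([c for _, c in F], period_label="fixtures")

    # verify the engineered cells classify to their targets
    from .classifier import classify_cell  # local import to avoid a cycle

    mism = []
    for t, c in F:
        got = classify_cell(c, rs)
        for key in ("bioclimate", "thermotype", "ombrotype"):
            if t.get(key) and getattr(got, key) != t[key]:
                mism.append(f"{c.cell_id}: {key} {getattr(got, key)} != {t[key]}")
        if t.get("variant") and got.variant != t["variant"]:
            mism.append(f"{c.cell_id}: variant {got.variant} != {t['variant']}")
        if t.get("continentality_subtype") and got.continentality[1] != t["continentality_subtype"]:
            mism.append(
                f"{c.cell_id}: subtype {got.continentality[1]} != {t['continentality_subtype']}"
            )
    if mism:
        raise RulesetError("ruleset cannot host fixtures: " + "; ".join(mism))
    return grid, targets
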