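"""Hierarchical WBCS unit assignment.

Applies the threshold ruleset in the canonical order: continentality,
macrobioclimate (on the 200-m-reduced values), bioclimate (Ic and Io),
bioclimatic variant (steppic / submediterranean / normal), thermotype
(with the Ic >= 21 or Itc < 120 dispatch onto the Tp belts), ombrotype
(shared Io belts) and finally the isobioclimate assembly
``bioclimate + " " + thermotype + " " + ombrotype``.

Two routes again: scalar :func:`classify_cell` evaluates the rules one
cell at a time on top of the brute-force index route, while
:func:`classify_grid` is the vectorised production path.  Both must
agree exactly; the test suite enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CellRecord, ClimateGrid
from .indices import BioclimaticIndices, compute_indices, indices_cell
from .ruleset import ClassificationRuleset, default_ruleset

__all__ = [
    "BioclimaticClassification",
    "classify_continentality",
    "classify_macrobioclimate",
    "classify_bioclimate",
    "classify_variant",
    "classify_thermotype",
    "classify_ombrotype",
    "classify_cell",
    "classify_grid",
    "build_isobioclimate_catalog",
    "apply_catalog",
    "isobioclimate_long_name",
    "LABEL_COLUMNS",
]

LABEL_COLUMNS = [
    "cell_id",
    "continentality_type",
    "continentality_subtype",
    "continentality_level",
    "Ic",
    "macrobioclimate",
    "bioclimate",
    "variant",
    "thermotype",
    "ombrotype",
    "isobioclimate",
]


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class BioclimaticClassification:
    """The seven WBCS unit labels for one cell."""

    cell_id: str
    continentality: tuple[str, str, str, float]  # (type, subtype, level, Ic)
    macrobioclimate: str
    bioclimate: str
    variant: str
    thermotype: str
    ombrotype: str
    isobioclimate: str
    catalog_key: int | None = None

    def __post_init__(self):
        expected = f"{self.bioclimate} {self.thermotype} {self.ombrotype}"
        assert self.isobioclimate == expected


# --------------------------------------------------------------- unit rules

def classify_continentality(ic: float, ruleset: ClassificationRuleset | None = None):
    """Continentality type, subtype and level from the Ic interval table."""
    rs = ruleset or default_ruleset()
    if ic < 0:
        raise ClassificationError(f"negative continentality index {ic}")
    row = rs.continentality.rows[int(rs.continentality.lookup(ic))]
    return row["type"], row["subtype"], row["level"]


def classify_macrobioclimate(
    tp200: float, summer_arid: bool, lat: float,
    ruleset: ClassificationRuleset | None = None,
) -> str:
    """First-level unit from the reduced positive temperature and mediterraneity."""
    rs = (ruleset or default_ruleset()).macrobioclimate
    if abs(lat) < rs["tropical_lat_max"]:
        return "TROPICAL"
    if tp200 < rs["polar_tp200_max"]:
        return "POLAR"
    if tp200 < rs["boreal_tp200_max"]:
        return "BOREAL"
    return "MEDITERRANEAN" if summer_arid else "TEMPERATE"


def classify_bioclimate(
    macro: str, ic: float, io: float, ruleset: ClassificationRuleset | None = None
) -> str:
    """Second-level unit from Io bands with the oceanic/continental Ic split.

    An undefined Io (Tp = 0) takes the wettest band of its macrobioclimate.
    """
    rs = ruleset or default_ruleset()
    table = rs.bioclimate[macro]
    io_eff = table.los[-1] if np.isnan(io) else io
    row = table.rows[int(table.lookup(io_eff))]
    if ic >= rs.bioclimate_splits["oceanic_ic_split"]:
        return row["continental"]
    if ic >= rs.bioclimate_splits["hyperoceanic_ic_split"]:
        return row["oceanic"]
    return row["hyperoceanic"]


def classify_variant(
    macro: str, indices: BioclimaticIndices,
    ruleset: ClassificationRuleset | None = None,
) -> str:
    """Steppic / submediterranean / normal variant.

    Steppic: Ps >= Pw, 0.2 < Io <= 6.0 and every summer month with
    Psi < 3*Ti.  Submediterranean (temperate/boreal/polar only): at
    least one summer month with Pi < 2.8*Ti.  Steppic takes precedence.
    """
    rs = ruleset or default_ruleset()
    stp = rs.variants["steppic"]
    sbm = rs.variants["submediterranean"]
    pm = indices.summer_precip
    tm = indices.summer_temp
    io = indices.Io
    if macro in stp["macros"]:
        io_ok = (not np.isnan(io)) and (stp["io_lo_exclusive"] < io <= stp["io_hi_inclusive"])
        monthly_ok = all(p < stp["monthly_factor"] * t for p, t in zip(pm, tm))
        if indices.Ps >= indices.Pw and io_ok and monthly_ok:
            return "Stp"
    if macro in sbm["macros"]:
        if any(p < sbm["monthly_factor"] * t for p, t in zip(pm, tm)):
            return "Sbm"
    return "Nor"


def classify_thermotype(
    macro: str, ic: float, itc: float, tp: float,
    ruleset: ClassificationRuleset | None = None,
) -> str:
    """Thermal belt; mediterranean/temperate dispatch on Ic >= 21 or Itc < 120."""
    rs = ruleset or default_ruleset()
    by_itc = rs.thermotype_by_itc.get(macro)
    if by_itc is not None:
        if ic >= rs.thermotype_dispatch["ic"] or itc < rs.thermotype_dispatch["itc_min"]:
            table = rs.thermotype_by_tp[macro]
            return table.codes[int(table.lookup(max(tp, 0.0)))]
        return by_itc.codes[int(by_itc.lookup(itc))]
    table = rs.thermotype_by_tp[macro]
    return table.codes[int(table.lookup(max(tp, 0.0)))]


def classify_ombrotype(
    io: float, tp: float, ruleset: ClassificationRuleset | None = None
) -> str:
    """Humidity belt from the shared Io table; gelid cells are supersnowy."""
    rs = ruleset or default_ruleset()
    if tp < rs.gelid_tp_max:
        return rs.gelid_ombrotype
    if np.isnan(io):
        raise ClassificationError("undefined Io outside the gelid belt")
    return rs.ombrotype.codes[int(rs.ombrotype.lookup(io))]


# ------------------------------------------------------------ cell pipeline

def classify_cell(
    cell: CellRecord, ruleset: ClassificationRuleset | None = None
) -> BioclimaticClassification:
    """Classify one cell through all seven units (reference route)."""
    rs = ruleset or default_ruleset()
    try:
        idx = indices_cell(cell.tmin, cell.tmax, cell.prec, cell.lat, rs, cell.elevation)
        ctype, csub, clev = classify_continentality(idx.Ic, rs)
        macro = classify_macrobioclimate(idx.Tp200, idx.summer_arid, cell.lat, rs)
        bio = classify_bioclimate(macro, idx.Ic, idx.Io, rs)
        variant = classify_variant(macro, idx, rs)
        thermo = classify_thermotype(macro, idx.Ic, idx.Itc, idx.Tp, rs)
        ombro = classify_ombrotype(idx.Io, idx.Tp, rs)
    except Exception as exc:
        raise ClassificationError(f"cell {cell.cell_id}: {exc}") from exc
    return BioclimaticClassification(
        cell_id=cell.cell_id,
        continentality=(ctype, csub, clev, idx.Ic),
        macrobioclimate=macro,
        bioclimate=bio,
        variant=variant,
        thermotype=thermo,
        ombrotype=ombro,
        isobioclimate=f"{bio} {thermo} {ombro}",
    )


# ------------------------------------------------------------ grid pipeline

def classify_grid(
    grid: ClimateGrid, ruleset: ClassificationRuleset | None = None
) -> pd.DataFrame:
    """Vectorised classification of a whole grid.

    Returns one row per cell with the seven unit labels
    (:data:`LABEL_COLUMNS`), in grid order.
    """
    rs = ruleset or default_ruleset()
    idx = compute_indices(grid.tmin, grid.tmax, grid.prec, grid.lat, grid.elevation, rs)
    n = len(idx)
    lat = grid.lat

    # continentality
    crow = rs.continentality.lookup(idx["Ic"].to_numpy())
    ctype = np.array([rs.continentality.rows[i]["type"] for i in crow], dtype=object)
    csub = np.array([rs.continentality.rows[i]["subtype"] for i in crow], dtype=object)
    clev = np.array([rs.continentality.rows[i]["level"] for i in crow], dtype=object)

    # macrobioclimate
    mb = rs.macrobioclimate
    tp200 = idx["Tp200"].to_numpy()
    macro = np.select(
        [
            np.abs(lat) < mb["tropical_lat_max"],
            tp200 < mb["polar_tp200_max"],
            tp200 < mb["boreal_tp200_max"],
            idx["summer_arid"].to_numpy(bool),
        ],
        ["TROPICAL", "POLAR", "BOREAL", "MEDITERRANEAN"],
        default="TEMPERATE",
    ).astype(object)

    # bioclimate
    ic = idx["Ic"].to_numpy()
    io = idx["Io"].to_numpy()
    splits = rs.bioclimate_splits
    side = np.select(
        [ic >= splits["oceanic_ic_split"], ic >= splits["hyperoceanic_ic_split"]],
        ["continental", "oceanic"],
        default="hyperoceanic",
    ).astype(object)
    bio = np.empty(n, dtype=object)
    for mac in np.unique(macro):
        sel = macro == mac
        table = rs.bioclimate[mac]
        io_eff = np.where(np.isnan(io[sel]), table.los[-1], io[sel])
        rows_i = table.lookup(io_eff)
        bio[sel] = [table.rows[i][s] for i, s in zip(rows_i, side[sel])]

    # variant
    stp, sbm = rs.variants["steppic"], rs.variants["submediterranean"]
    pm = idx[["Psm_1", "Psm_2", "Psm_3"]].to_numpy()
    tm = idx[["Tsm_1", "Tsm_2", "Tsm_3"]].to_numpy()
    with np.errstate(invalid="ignore"):
        io_ok = (io > stp["io_lo_exclusive"]) & (io <= stp["io_hi_inclusive"])
        stp_ok = (
            np.isin(macro, stp["macros"])
            & (idx["Ps"].to_numpy() >= idx["Pw"].to_numpy())
            & np.where(np.isnan(io), False, io_ok)
            & (pm < stp["monthly_factor"] * tm).all(axis=1)
        )
        sbm_ok = np.isin(macro, sbm["macros"]) & (
            pm < sbm["monthly_factor"] * tm
        ).any(axis=1)
    variant = np.select([stp_ok, sbm_ok], ["Stp", "Sbm"], default="Nor").astype(object)

    # thermotype
    tp = np.maximum(idx["Tp"].to_numpy(), 0.0)
    itc = idx["Itc"].to_numpy()
    thermo = np.empty(n, dtype=object)
    for mac in np.unique(macro):
        sel = macro == mac
        tp_table = rs.thermotype_by_tp[mac]
        by_itc = rs.thermotype_by_itc.get(mac)
        if by_itc is None:
            thermo[sel] = tp_table.lookup_codes(tp[sel])
        else:
            use_tp = (ic[sel] >= rs.thermotype_dispatch["ic"]) | (
                itc[sel] < rs.thermotype_dispatch["itc_min"]
            )
            out = np.empty(sel.sum(), dtype=object)
            out[use_tp] = tp_table.lookup_codes(tp[sel][use_tp])
            out[~use_tp] = by_itc.lookup_codes(itc[sel][~use_tp])
            thermo[sel] = out

    # ombrotype
    gel = idx["Tp"].to_numpy() < rs.gelid_tp_max
    if np.any(np.isnan(io) & ~gel):
        bad = grid.cell_ids[np.isnan(io) & ~gel].tolist()
        raise ClassificationError(f"undefined Io outside the gelid belt: {bad}")
    ombro = np.empty(n, dtype=object)
    ombro[~gel] = rs.ombrotype.lookup_codes(io[~gel])
    ombro[gel] = rs.gelid_ombrotype

    iso = np.array([f"{b} {t} {o}" for b, t, o in zip(bio, thermo, ombro)], dtype=object)
    return pd.DataFrame(
        {
            "cell_id": grid.cell_ids.astype(str).to_numpy(),
            "continentality_type": ctype,
            "continentality_subtype": csub,
            "continentality_level": clev,
            "Ic": ic,
            "macrobioclimate": macro,
            "bioclimate": bio,
            "variant": variant,
            "thermotype": thermo,
            "ombrotype": ombro,
            "isobioclimate": iso,
        }
    )


# ---------------------------------------------------------------- catalog

def build_isobioclimate_catalog(
    label_frames: list[pd.DataFrame], ruleset: ClassificationRuleset | None = None
) -> dict[str, int]:
    """Stable key numbering of every isobioclimate seen across the periods.

    Distinct codes are ordered by (bioclimate, thermotype warmest-first,
    ombrotype driest-first) rank and numbered from 1; adding a period
    with no new codes leaves the catalog unchanged.
    """
    rs = ruleset or default_ruleset()
    bio_rank = {c: i for i, c in enumerate(rs.all_bioclimate_codes())}
    th_rank = rs.thermotype_rank()
    om_rank = rs.ombrotype_rank()
    seen = set()
    for frame in label_frames:
        seen.update(frame["isobioclimate"].unique().tolist())

    def sort_key(code: str):
        b, t, o = code.split(" ")
        return bio_rank[b], th_rank[t], om_rank[o]

    return {code: i + 1 for i, code in enumerate(sorted(seen, key=sort_key))}


def apply_catalog(labels: pd.DataFrame, catalog: dict[str, int]) -> pd.DataFrame:
    out = labels.copy()
    out["catalog_key"] = out["isobioclimate"].map(catalog).astype("Int64")
    return out


def isobioclimate_long_name(
    code: str, ruleset: ClassificationRuleset | None = None
) -> str:
    """Spelled-out name, e.g. 'MEDC Sme Ari' ->
    'mediterranean desertic continental, supramediterranean, arid'."""
    rs = ruleset or default_ruleset()
    b, t, o = code.split(" ")
    names = rs.long_names
    return ", ".join(
        [names["bioclimate"][b], names["thermotype"][t], names["ombrotype"][o]]
    )
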