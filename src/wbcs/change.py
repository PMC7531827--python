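"""Multi-period comparison of classified grids.

Given 2–3 classified label tables on the same cell set, this module
builds per-unit area tables (counts and percent of territory per class
and period, with a final-minus-first delta column), per-cell change and
stability masks, aggregate gain/loss summaries over declared class
groupings (warm vs cold thermal belts, mountain belts, continental
bioclimates, arid ombrotypes) and the loss-of-diversity summary
(bioclimatic homogenization).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .grid import AlignmentError
from .ruleset import ClassificationRuleset, default_ruleset

__all__ = [
    "UNITS",
    "unit_column",
    "area_table",
    "stability_fraction",
    "change_mask",
    "diversity_summary",
    "trend_summary",
    "directional_change_fraction",
    "standard_groupings",
]

UNITS = [
    "continentality",
    "macrobioclimate",
    "bioclimate",
    "variant",
    "thermotype",
    "ombrotype",
    "isobioclimate",
]


def unit_column(labels: pd.DataFrame, unit: str) -> pd.Series:
    """The class label per cell for one bioclimatic unit."""
    if unit == "continentality":
        lev = labels["continentality_level"].astype(str)
        return (
            labels["continentality_subtype"].astype(str)
            + np.where(lev != "", " " + lev, "")
        ).rename("continentality")
    col = unit if unit in labels.columns else None
    if col is None:
        raise KeyError(f"unknown unit {unit!r}")
    return labels[col]


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_alignment(frames: list[pd.DataFrame]) -> None:
    ids0 = set(frames[0]["cell_id"])
    for f in frames[1:]:
        if set(f["cell_id"]) != ids0:
            raise AlignmentError("periods classified on different cell sets")


def area_table(
    frames: list[pd.DataFrame],
    unit: str,
    period_labels: list[str] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Counts and percent of territory per class and period.

    The ``delta_pct`` column is final-period percent minus first-period
    percent (rounded half-up to ``decimals``); counts are exact integers
    and per period sum to the grid size.
    """
    _check_alignment(frames)
    if period_labels is None:
        period_labels = [f"period_{i + 1}" for i in range(len(frames))]
    n = len(frames[0])
    classes: list[str] = []
    for f in frames:
        for c in unit_column(f, unit):
            if c not in classes:
                classes.append(c)
    out = pd.DataFrame(index=pd.Index(classes, name=unit))
    for f, lab in zip(frames, period_labels):
        counts = unit_column(f, unit).value_counts()
        out[f"count_{lab}"] = [int(counts.get(c, 0)) for c in classes]
        out[f"pct_{lab}"] = [
            round_half_up(100.0 * counts.get(c, 0) / n, decimals) for c in classes
        ]
    first, last = period_labels[0], period_labels[-1]
    out["delta_pct"] = [
        round_half_up(b - a, decimals)
        for a, b in zip(out[f"pct_{first}"], out[f"pct_{last}"])
    ]
    return out


def stability_fraction(frames: list[pd.DataFrame], unit: str) -> tuple[float, float]:
    """Percent of cells keeping the same class in every period, and its
    complement (percent changing in at least one transition)."""
    if len(frames) < 2:
        raise ValueError("need at least two periods")
    _check_alignment(frames)
    base = unit_column(frames[0], unit).to_numpy()
    stable = np.ones(len(frames[0]), dtype=bool)
    order = frames[0]["cell_id"].to_numpy()
    for f in frames[1:]:
        cur = unit_column(f.set_index("cell_id").loc[order].reset_index(), unit).to_numpy()
        stable &= cur == base
    pct = 100.0 * stable.sum() / len(stable)
    return pct, 100.0 - pct


def change_mask(
    period_a: pd.DataFrame, period_b: pd.DataFrame, unit: str
) -> pd.DataFrame:
    """Per-cell changed/stable flags between two classified periods."""
    _check_alignment([period_a, period_b])
    order = period_a["cell_id"].to_numpy()
    a = unit_column(period_a, unit).to_numpy()
    b = unit_column(
        period_b.set_index("cell_id").loc[order].reset_index(), unit
    ).to_numpy()
    return pd.DataFrame(
        {"cell_id": order, "changed": a != b, "from": a, "to": b}
    )


def diversity_summary(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Loss of bioclimatic diversity across the study interval.

    Baseline per unit = distinct classes seen in any period; final =
    classes present in the last period; loss percent = disappeared /
    baseline x 100 (one decimal).
    """
    _check_alignment(frames)
    rows = []
    for unit in ("macrobioclimate", "bioclimate", "thermotype", "ombrotype", "isobioclimate"):
        union: set = set()
        for f in frames:
            union |= set(unit_column(f, unit))
        final = set(unit_column(frames[-1], unit))
        gone = union - final
        rows.append(
            {
                "unit": unit,
                "n_initial": len(union),
                "n_final": len(final),
                "n_disappeared": len(gone),
                "pct_loss": round_half_up(100.0 * len(gone) / len(union), 1),
            }
        )
    return pd.DataFrame(rows).set_index("unit")


def standard_groupings(ruleset: ClassificationRuleset | None = None) -> dict:
    """The class groupings used in the aggregate trend tables."""
    rs = ruleset or default_ruleset()
    warm_prefix = ("I", "T", "M")  # infra-, thermo-, meso- belts
    all_thermo = list(rs.thermotype_rank())
    warm = [c for c in all_thermo if c[0] in warm_prefix and c != "Gel"]
    cold = [c for c in all_thermo if c not in warm]
    return {
        "warm_thermotypes": warm,
        "cold_thermotypes": cold,
        "mountain_thermotypes": ["Ote", "Cte", "Obo", "Cbo", "Gel"],
        "mountain_ombrotypes": ["Hum", "Hhu", "Uhh", "Ssnw"],
        "continental_bioclimates": ["MEPC", "MEXC", "MEDC", "MEHC", "TECO", "BOCO", "POCO"],
        "arid_ombrotypes": ["Uha", "Har", "Sar"],
    }


def trend_summary(area: pd.DataFrame, grouping: dict[str, list[str]]) -> pd.DataFrame:
    """Sum of final-minus-first percent deltas over each declared group."""
    rows = []
    for name, classes in grouping.items():
        present = [c for c in classes if c in area.index]
        rows.append(
            {
                "group": name,
                "delta_pct": round_half_up(float(area.loc[present, "delta_pct"].sum()), 2)
                if present
                else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def directional_change_fraction(
    frames: list[pd.DataFrame],
    unit: str,
    direction: str,
    ruleset: ClassificationRuleset | None = None,
) -> float:
    """Percent of cells whose class moved in a stated direction between the
    first and last period.

    Directions: ``'warmer'`` (thermotype), ``'drier'`` (ombrotype),
    ``'more_continental'`` (continentality).
    """
    rs = ruleset or default_ruleset()
    _check_alignment(frames)
    first, last = frames[0], frames[-1]
    order = first["cell_id"].to_numpy()
    last = last.set_index("cell_id").loc[order].reset_index()
    if direction == "warmer":
        rank = rs.thermotype_rank()  # warmest-first: smaller is warmer
        a = first["thermotype"].map(rank).to_numpy()
        b = last["thermotype"].map(rank).to_numpy()
        moved = b < a
    elif direction == "drier":
        rank = rs.ombrotype_rank()  # driest-first: smaller is drier
        a = first["ombrotype"].map(rank).to_numpy()
        b = last["ombrotype"].map(rank).to_numpy()
        moved = b < a
    elif direction == "more_continental":
        a = rs.continentality.lookup(first["Ic"].to_numpy())
        b = rs.continentality.lookup(last["Ic"].to_numpy())
        moved = b > a
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return 100.0 * moved.sum() / len(moved)
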