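"""Climatic parameters and bioclimatic indices of the WBCS.

For each grid cell with 12 monthly mean minimum temperatures, 12 monthly
mean maximum temperatures and 12 monthly precipitation totals, this
module computes the full set of WBCS quantities: monthly means Ti,
thermal parameters (T, Tmax, Tmin, M, m, Tp, Tps, Ic, It), precipitation
parameters (P, Pp, Ps, Pw, Pps, Ppw, Pss, Psw, Pcm1..3), the
ombrothermic family (Io, Iosi, Ios2, Iosc3, Iosc4, Iod2), the
continentality-compensated thermicity Itc = It + C(Ic), the
summer-aridity (mediterraneity) decision, and the 200-m-reduced values
used for macrobioclimate identification.

Two routes are provided on purpose:

* :func:`indices_cell` — a plain-Python, loop-based reference
  implementation for a single cell (brute-force window scans);
* :func:`compute_indices` — the vectorised implementation for whole
  grids, returning one row per cell.

The test suite asserts the two agree bit-for-bit on every fixture.

Conventions
-----------
Summer quarter: June–August in the northern hemisphere, December–
February in the southern (resolved by the sign of the latitude); the
winter quarter is the opposite one.  Windowed quantities (Pcm1, Pss,
Ios2, Iod2) use contiguous calendar windows with wrap-around, ties
broken towards the earliest start month.  Tp is expressed in tenths of
a degree Celsius, as are all temperature sums entering ombrothermic
ratios.  Cells with Tp = 0 carry an undefined (NaN) Io and are routed
by the classifier, never divided through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ruleset import ClassificationRuleset, default_ruleset

__all__ = [
    "BioclimaticIndices",
    "indices_cell",
    "compute_indices",
    "summer_aridity",
    "INDEX_COLUMNS",
]


def summer_aridity(ios2, iosc3, iosc4, io, ruleset: ClassificationRuleset | None = None):
    """Mediterraneity decision: dry summer (Ios2 <= 2) minus compensation.

    The drought is compensated — the cell is *not* summer-arid — when the
    whole summer quarter is wet enough (Iosc3 above the gate), or when the
    four-month window adding the pre-summer month is (Iosc4 above the
    gate) in territories that are not annually dry (Io at or above the
    ruleset's floor).  Accepts scalars or arrays; NaN inputs fail their
    branch.
    """
    rs = ruleset or default_ruleset()
    sa = rs.summer_aridity
    ios2 = np.asarray(ios2, dtype=float)
    iosc3 = np.asarray(iosc3, dtype=float)
    iosc4 = np.asarray(iosc4, dtype=float)
    io = np.asarray(io, dtype=float)
    dry = np.where(np.isnan(ios2), False, ios2 <= sa["ios2_gate"])
    comp3 = np.where(np.isnan(iosc3), False, iosc3 > sa["iosc3_gate"])
    comp4 = np.where(np.isnan(iosc4), False, iosc4 > sa["iosc4_gate"]) & np.where(
        np.isnan(io), False, io >= sa["iosc4_io_floor"]
    )
    out = dry & ~(comp3 | comp4)
    return bool(out) if out.ndim == 0 else out

_NH_SUMMER = (5, 6, 7)    # Jun, Jul, Aug (0-based)
_SH_SUMMER = (11, 0, 1)   # Dec, Jan, Feb


@dataclass
class BioclimaticIndices:
    """Every WBCS climatic parameter and bioclimatic index for one cell."""

    Ti: np.ndarray
    T: float
    Tmax: float
    Tmin: float
    M: float
    m: float
    Tp: float
    Tps: float
    Ic: float
    It: float
    C: float
    Itc: float
    P: float
    Pp: float
    Ps: float
    Pw: float
    Pps: float
    Ppw: float
    Pss: float
    Psw: float
    Pcm1: float
    Pcm2: float
    Pcm3: float
    Io: float
    Iosi: np.ndarray
    Ios2: float
    Iosc3: float
    Iosc4: float
    Iod2: float
    summer_months: tuple[int, int, int]
    summer_precip: np.ndarray
    summer_temp: np.ndarray
    hemisphere: str
    summer_arid: bool
    T200: float
    M200: float
    Itc200: float
    Tp200: float

    def __post_init__(self):
        assert self.Ic >= 0 and self.Tp >= self.Tps >= 0
        assert self.Pp <= self.P + 1e-9 and self.M >= self.m


def _ombro(prec, ti, months) -> float:
    """Ombrothermic ratio 10 * sum(P) / sum(Tp-tenths) over ``months``.

    Only months with Ti > 0 contribute (same convention as Pp/Tp); NaN
    when no month in the set has a positive mean temperature.
    """
    num = den = 0.0
    for i in months:
        if ti[i] > 0:
            num += prec[i]
            den += 10.0 * ti[i]
    return 10.0 * num / den if den > 0 else float("nan")


def _window(start: int, length: int) -> list[int]:
    return [(start + j) % 12 for j in range(length)]


def _best_window(values, length: int, largest: bool = True) -> int:
    """Start of the contiguous window extremising the sum; earliest on ties."""
    best_start, best_sum = 0, None
    for s in range(12):
        tot = sum(values[i] for i in _window(s, length))
        if best_sum is None or (tot > best_sum if largest else tot < best_sum):
            best_start, best_sum = s, tot
    return best_start


def indices_cell(
    tmin,
    tmax,
    prec,
    lat: float,
    ruleset: ClassificationRuleset | None = None,
    elevation: float = 200.0,
) -> BioclimaticIndices:
    """Reference (brute-force) computation of all indices for one cell."""
    rs = ruleset or default_ruleset()
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    ti = (tmin + tmax) / 2.0

    hemisphere = "north" if lat >= 0 else "south"
    summer = _NH_SUMMER if hemisphere == "north" else _SH_SUMMER
    winter = _SH_SUMMER if hemisphere == "north" else _NH_SUMMER

    T = float(np.mean(ti))
    Tmax, Tmin = float(np.max(ti)), float(np.min(ti))
    cold = min(range(12), key=lambda i: (ti[i], i))
    M, m = float(tmax[cold]), float(tmin[cold])
    Tp = 10.0 * sum(t for t in ti if t > 0)
    Tps = 10.0 * sum(ti[i] for i in summer if ti[i] > 0)
    Ic = Tmax - Tmin
    It = (T + m + M) * 10.0
    C = float(rs.compensation_C(Ic))
    Itc = It + C

    P = float(np.sum(prec))
    Pp = sum(prec[i] for i in range(12) if ti[i] > 0)
    Ps = sum(prec[i] for i in summer)
    Pw = sum(prec[i] for i in winter)
    Pps = sum(prec[i] for i in summer if ti[i] > 0)
    Ppw = sum(prec[i] for i in winter if ti[i] > 0)
    s6 = _best_window(ti, 6, largest=True)
    c6 = _best_window(ti, 6, largest=False)
    Pss = sum(prec[i] for i in _window(s6, 6))
    Psw = sum(prec[i] for i in _window(c6, 6))
    s4 = _best_window(ti, 4, largest=True)
    Pcm1 = sum(prec[i] for i in _window(s4, 4))
    Pcm2 = sum(prec[i] for i in _window((s4 + 4) % 12, 4))
    Pcm3 = sum(prec[i] for i in _window((s4 - 4) % 12, 4))

    Io = 10.0 * Pp / Tp if Tp > 0 else float("nan")
    Iosi = np.array(
        [10.0 * prec[i] / (10.0 * ti[i]) if ti[i] > 0 else np.nan for i in summer]
    )
    # warmest contiguous two-month sub-window of the summer quarter
    pair0, pair1 = summer[:2], summer[1:]
    pair = pair0 if ti[pair0[0]] + ti[pair0[1]] >= ti[pair1[0]] + ti[pair1[1]] else pair1
    Ios2 = _ombro(prec, ti, pair)
    Iosc3 = _ombro(prec, ti, summer)
    prev = (summer[0] - 1) % 12
    Iosc4 = _ombro(prec, ti, (prev,) + tuple(summer))
    dq = _best_window(prec, 3, largest=False)
    dqm = _window(dq, 3)
    # two driest months of the driest quarter: drop the (first) wettest one
    wettest = max(range(3), key=lambda j: prec[dqm[j]])
    d2 = [dqm[j] for j in range(3) if j != wettest]
    Iod2 = _ombro(prec, ti, d2)

    arid_flag = summer_aridity(Ios2, Iosc3, Iosc4, Io, rs)

    # 200-m reduction: shift monthly temperatures and recompute T, M, Itc, Tp
    delta = rs.reduction_coeff * (elevation - rs.reduction_reference_m) / 100.0
    ti_r, tmin_r, tmax_r = ti + delta, tmin + delta, tmax + delta
    T200 = float(np.mean(ti_r))
    cold_r = min(range(12), key=lambda i: (ti_r[i], i))
    M200, m200 = float(tmax_r[cold_r]), float(tmin_r[cold_r])
    Tp200 = 10.0 * sum(t for t in ti_r if t > 0)
    It200 = (T200 + m200 + M200) * 10.0
    Itc200 = It200 + float(rs.compensation_C(float(np.max(ti_r) - np.min(ti_r))))

    return BioclimaticIndices(
        Ti=ti, T=T, Tmax=Tmax, Tmin=Tmin, M=M, m=m, Tp=Tp, Tps=Tps, Ic=Ic,
        It=It, C=C, Itc=Itc, P=P, Pp=Pp, Ps=Ps, Pw=Pw, Pps=Pps, Ppw=Ppw,
        Pss=Pss, Psw=Psw, Pcm1=Pcm1, Pcm2=Pcm2, Pcm3=Pcm3, Io=Io, Iosi=Iosi,
        Ios2=Ios2, Iosc3=Iosc3, Iosc4=Iosc4, Iod2=Iod2,
        summer_months=tuple(summer),
        summer_precip=np.array([prec[i] for i in summer]),
        summer_temp=np.array([ti[i] for i in summer]),
        hemisphere=hemisphere,
        summer_arid=arid_flag, T200=T200, M200=M200, Itc200=Itc200,
        Tp200=Tp200,
    )


# --------------------------------------------------------------------------
# vectorised route
# --------------------------------------------------------------------------

INDEX_COLUMNS = [
    "T", "Tmax", "Tmin", "M", "m", "Tp", "Tps", "Ic", "It", "C", "Itc",
    "P", "Pp", "Ps", "Pw", "Pps", "Ppw", "Pss", "Psw", "Pcm1", "Pcm2",
    "Pcm3", "Io", "Ios2", "Iosc3", "Iosc4", "Iod2", "summer_arid",
    "T200", "M200", "Itc200", "Tp200",
]

_W = {L: np.array([[(s + j) % 12 for j in range(L)] for s in range(12)]) for L in (3, 4, 6)}


def _wsum(x: np.ndarray, L: int) -> np.ndarray:
    """(n, 12) array of wrap-around window sums of length L."""
    return x[:, _W[L]].sum(axis=2)


def _ombro_vec(prec: np.ndarray, ti: np.ndarray) -> np.ndarray:
    """Row-wise ombrothermic ratio over the month subsets given as columns."""
    pos = ti > 0
    num = np.where(pos, prec, 0.0).sum(axis=1)
    den = 10.0 * np.where(pos, ti, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, 10.0 * num / den, np.nan)


def compute_indices(
    tmin: np.ndarray,
    tmax: np.ndarray,
    prec: np.ndarray,
    lat: np.ndarray,
    elevation: np.ndarray | None = None,
    ruleset: ClassificationRuleset | None = None,
) -> pd.DataFrame:
    """Vectorised WBCS indices for a grid; one row per cell.

    Parameters are (n, 12) monthly arrays plus per-cell latitude and
    elevation.  Returns a DataFrame with :data:`INDEX_COLUMNS` plus the
    per-summer-month ``Iosi_1..3``.
    """
    rs = ruleset or default_ruleset()
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = tmin.shape[0]
    if elevation is None:
        elevation = np.full(n, rs.reduction_reference_m)
    elevation = np.asarray(elevation, dtype=float)

    ti = (tmin + tmax) / 2.0
    rows = np.arange(n)

    north = lat >= 0
    summer_idx = np.where(
        north[:, None], np.array(_NH_SUMMER)[None, :], np.array(_SH_SUMMER)[None, :]
    )
    winter_idx = np.where(
        north[:, None], np.array(_SH_SUMMER)[None, :], np.array(_NH_SUMMER)[None, :]
    )

    T = ti.mean(axis=1)
    Tmax_ = ti.max(axis=1)
    Tmin_ = ti.min(axis=1)
    cold = ti.argmin(axis=1)
    M = tmax[rows, cold]
    m = tmin[rows, cold]
    pos = ti > 0
    Tp = 10.0 * np.where(pos, ti, 0.0).sum(axis=1)
    ti_s = np.take_along_axis(ti, summer_idx, axis=1)
    pr_s = np.take_along_axis(prec, summer_idx, axis=1)
    Tps = 10.0 * np.where(ti_s > 0, ti_s, 0.0).sum(axis=1)
    Ic = Tmax_ - Tmin_
    It = (T + m + M) * 10.0
    C = rs.compensation_C(Ic)
    Itc = It + C

    P = prec.sum(axis=1)
    Pp = np.where(pos, prec, 0.0).sum(axis=1)
    Ps = pr_s.sum(axis=1)
    pr_w = np.take_along_axis(prec, winter_idx, axis=1)
    ti_w = np.take_along_axis(ti, winter_idx, axis=1)
    Pw = pr_w.sum(axis=1)
    Pps = np.where(ti_s > 0, pr_s, 0.0).sum(axis=1)
    Ppw = np.where(ti_w > 0, pr_w, 0.0).sum(axis=1)

    t6 = _wsum(ti, 6)
    p6 = _wsum(prec, 6)
    Pss = p6[rows, t6.argmax(axis=1)]
    Psw = p6[rows, t6.argmin(axis=1)]
    t4 = _wsum(ti, 4)
    p4 = _wsum(prec, 4)
    s4 = t4.argmax(axis=1)
    Pcm1 = p4[rows, s4]
    Pcm2 = p4[rows, (s4 + 4) % 12]
    Pcm3 = p4[rows, (s4 - 4) % 12]

    with np.errstate(invalid="ignore", divide="ignore"):
        Io = np.where(Tp > 0, 10.0 * Pp / Tp, np.nan)
        Iosi = np.where(ti_s > 0, 10.0 * pr_s / (10.0 * ti_s), np.nan)

    # warmest contiguous summer pair (earliest on ties)
    first_pair = ti_s[:, 0] + ti_s[:, 1] >= ti_s[:, 1] + ti_s[:, 2]
    pair_p = np.where(first_pair[:, None], pr_s[:, :2], pr_s[:, 1:])
    pair_t = np.where(first_pair[:, None], ti_s[:, :2], ti_s[:, 1:])
    Ios2 = _ombro_vec(pair_p, pair_t)
    Iosc3 = _ombro_vec(pr_s, ti_s)
    prev = (summer_idx[:, :1] - 1) % 12
    idx4 = np.concatenate([prev, summer_idx], axis=1)
    Iosc4 = _ombro_vec(
        np.take_along_axis(prec, idx4, axis=1), np.take_along_axis(ti, idx4, axis=1)
    )

    p3 = _wsum(prec, 3)
    dq = p3.argmin(axis=1)
    dq_months = _W[3][dq]
    dq_p = prec[rows[:, None], dq_months]
    dq_t = ti[rows[:, None], dq_months]
    wet = dq_p.argmax(axis=1)
    keep = np.ones_like(dq_p, dtype=bool)
    keep[rows, wet] = False
    d2_p = dq_p[keep].reshape(n, 2)
    d2_t = dq_t[keep].reshape(n, 2)
    Iod2 = _ombro_vec(d2_p, d2_t)

    summer_arid = summer_aridity(Ios2, Iosc3, Iosc4, Io, rs)

    delta = rs.reduction_coeff * (elevation - rs.reduction_reference_m) / 100.0
    ti_r = ti + delta[:, None]
    T200 = ti_r.mean(axis=1)
    cold_r = ti_r.argmin(axis=1)
    M200 = (tmax + delta[:, None])[rows, cold_r]
    m200 = (tmin + delta[:, None])[rows, cold_r]
    Tp200 = 10.0 * np.where(ti_r > 0, ti_r, 0.0).sum(axis=1)
    Itc200 = (T200 + m200 + M200) * 10.0 + rs.compensation_C(
        ti_r.max(axis=1) - ti_r.min(axis=1)
    )

    out = pd.DataFrame(
        {
            "T": T, "Tmax": Tmax_, "Tmin": Tmin_, "M": M, "m": m, "Tp": Tp,
            "Tps": Tps, "Ic": Ic, "It": It, "C": C, "Itc": Itc, "P": P,
            "Pp": Pp, "Ps": Ps, "Pw": Pw, "Pps": Pps, "Ppw": Ppw,
            "Pss": Pss, "Psw": Psw, "Pcm1": Pcm1, "Pcm2": Pcm2,
            "Pcm3": Pcm3, "Io": Io, "Ios2": Ios2, "Iosc3": Iosc3,
            "Iosc4": Iosc4, "Iod2": Iod2, "summer_arid": summer_arid,
            "T200": T200, "M200": M200, "Itc200": Itc200, "Tp200": Tp200,
        }
    )
    for k in range(3):
        out[f"Iosi_{k + 1}"] = Iosi[:, k]
        out[f"Psm_{k + 1}"] = pr_s[:, k]
        out[f"Tsm_{k + 1}"] = ti_s[:, k]
    return out
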