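"""Versioned threshold ruleset for the WBCS classifier.

All numeric boundaries (continentality rows, macrobioclimate bands,
bioclimate Io splits, thermotype Itc/Tp belts, ombrotype Io belts, the
C(Ic) thermicity compensation tranches and the 200-m reduction
coefficient) live in a human-readable YAML file packaged with the
library.  The classifier code never hard-wires a threshold.

Interval convention, uniformly: lower-closed, upper-open; the final
interval of every table is upper-closed (tables whose scale is open
above encode the last upper bound as ``inf``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["ClassificationRuleset", "IntervalTable", "load_ruleset", "default_ruleset"]


class RulesetError(ValueError):
    """Raised when a ruleset file is malformed or an interval list has gaps."""


@dataclass(frozen=True)
class IntervalTable:
    """An ordered list of half-open intervals tiling ``[lo0, hiN]``.

    Lookup follows the lower-closed/upper-open convention; a value equal
    to the last upper bound is assigned to the last interval.
    """

    name: str
    codes: tuple[str, ...]
    los: np.ndarray
    his: np.ndarray
    rows: tuple[dict, ...] = field(default_factory=tuple)

    @classmethod
    def from_rows(cls, name: str, rows: Sequence[dict], code_key: str = "code") -> "IntervalTable":
        los = np.asarray([float(r["lo"]) for r in rows])
        his = np.asarray([float(r["hi"]) for r in rows])
        if not np.all(los[1:] == his[:-1]):
            raise RulesetError(f"{name}: intervals do not tile (gap or overlap)")
        if np.any(his <= los):
            raise RulesetError(f"{name}: empty or inverted interval")
        codes = tuple(str(r[code_key]) for r in rows)
        return cls(name, codes, los, his, tuple(dict(r) for r in rows))

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.los[0]), float(self.his[-1])

    def lookup(self, x):
        """Vectorised interval lookup returning integer row indices.

        Values below the domain raise; values at/above the final upper
        bound clamp into the last row (upper-closed tail).
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < self.los[0]):
            raise ValueError(f"{self.name}: value below domain {self.domain}")
        idx = np.searchsorted(self.los, x, side="right") - 1
        return np.minimum(idx, len(self.codes) - 1)

    def lookup_codes(self, x) -> np.ndarray:
        return np.asarray(self.codes, dtype=object)[self.lookup(x)]

    def midpoints(self) -> dict[str, float]:
        """Representative mid-interval value per code (finite tail capped)."""
        out = {}
        for code, lo, hi in zip(self.codes, self.los, self.his):
            hi = hi if np.isfinite(hi) else lo * 1.5 + 100.0
            out[code] = (lo + hi) / 2.0
        return out


@dataclass(frozen=True)
class ClassificationRuleset:
    """Parsed, validated WBCS threshold ruleset."""

    version: str
    continentality: IntervalTable
    compensation_neutral: tuple[float, float]
    compensation_tranches: tuple[dict, ...]
    reduction_reference_m: float
    reduction_coeff: float
    summer_aridity: dict
    macrobioclimate: dict
    bioclimate: dict          # macro -> {"io_bands": IntervalTable-like rows}
    bioclimate_splits: dict   # {"oceanic_ic_split", "hyperoceanic_ic_split"}
    variants: dict
    thermotype_dispatch: dict  # {"ic", "itc_min"}
    thermotype_by_tp: dict[str, IntervalTable]
    thermotype_by_itc: dict[str, IntervalTable]
    ombrotype: IntervalTable
    gelid_tp_max: float
    gelid_ombrotype: str
    long_names: dict

    # ---------------------------------------------------------------- C(Ic)
    def compensation_C(self, ic):
        """Stepwise-linear thermicity compensation term C(Ic).

        Zero inside the neutral band, monotone non-decreasing elsewhere.
        Negative Ic is a configuration/input error.
        """
        ic = np.asarray(ic, dtype=float)
        if np.any(ic < self.compensation_tranches[0]["lo"]):
            raise ValueError("Ic below the compensation table domain")
        c = np.full(ic.shape, np.nan)
        for tr in self.compensation_tranches:
            lo, hi = tr["lo"], tr["hi"]
            sel = (ic >= lo) & (ic < hi) if np.isfinite(hi) else (ic >= lo)
            c = np.where(sel, tr["c_lo"] + tr["slope"] * (ic - lo), c)
        return c if c.ndim else float(c)

    def bioclimate_codes(self, macro: str) -> IntervalTable:
        return self.bioclimate[macro]

    def all_bioclimate_codes(self) -> list[str]:
        """Bioclimate codes in catalog order (ruleset declaration order)."""
        seen: list[str] = []
        for macro in ("MEDITERRANEAN", "TEMPERATE", "BOREAL", "POLAR", "TROPICAL"):
            for row in reversed(self.bioclimate[macro].rows):
                for key in ("continental", "oceanic", "hyperoceanic"):
                    if row[key] not in seen:
                        seen.append(row[key])
        return seen

    def thermotype_rank(self) -> dict[str, int]:
        """Warmest-first rank across all macros, for catalog ordering."""
        order: list[str] = []
        for macro in ("MEDITERRANEAN", "TEMPERATE", "BOREAL", "POLAR", "TROPICAL"):
            table = self.thermotype_by_tp[macro]
            for code in reversed(table.codes):  # tables run cold -> warm
                if code not in order:
                    order.append(code)
        return {c: i for i, c in enumerate(order)}

    def ombrotype_rank(self) -> dict[str, int]:
        """Driest-first rank; the supersnowy belt sorts last."""
        rank = {c: i for i, c in enumerate(self.ombrotype.codes)}
        rank[self.gelid_ombrotype] = len(rank)
        return rank


def _parse(doc: dict) -> ClassificationRuleset:
    try:
        cont = IntervalTable.from_rows("continentality", doc["continentality"])
        comp = doc["compensation_C"]
        tranches = tuple(
            {k: float(v) for k, v in tr.items()} for tr in comp["tranches"]
        )
        for a, b in zip(tranches[:-1], tranches[1:]):
            if a["hi"] != b["lo"]:
                raise RulesetError("compensation_C tranches do not tile")
        red = doc["reduction"]
        bio = {}
        for macro, block in doc["bioclimate"].items():
            if macro.endswith("_ic_split"):
                continue
            if isinstance(block, dict) and "io_bands" in block:
                bio[macro] = IntervalTable.from_rows(
                    f"bioclimate[{macro}]", block["io_bands"], code_key="continental"
                )
        th_tp, th_itc = {}, {}
        for macro, block in doc["thermotype"].items():
            if macro in ("dispatch_ic", "dispatch_itc_min"):
                continue
            th_tp[macro] = IntervalTable.from_rows(f"thermotype[{macro}].by_tp", block["by_tp"])
            if "by_itc" in block:
                th_itc[macro] = IntervalTable.from_rows(
                    f"thermotype[{macro}].by_itc", block["by_itc"]
                )
        omb = doc["ombrotype"]
        return ClassificationRuleset(
            version=str(doc["version"]),
            continentality=cont,
            compensation_neutral=tuple(float(x) for x in comp["neutral"]),
            compensation_tranches=tranches,
            reduction_reference_m=float(red["reference_elevation_m"]),
            reduction_coeff=float(red["coeff_c_per_100m"]),
            summer_aridity={k: float(v) for k, v in doc["summer_aridity"].items()},
            macrobioclimate={k: float(v) for k, v in doc["macrobioclimate"].items()},
            bioclimate=bio,
            bioclimate_splits={
                "oceanic_ic_split": float(doc["bioclimate"]["oceanic_ic_split"]),
                "hyperoceanic_ic_split": float(doc["bioclimate"]["hyperoceanic_ic_split"]),
            },
            variants=doc["variants"],
            thermotype_dispatch={
                "ic": float(doc["thermotype"]["dispatch_ic"]),
                "itc_min": float(doc["thermotype"]["dispatch_itc_min"]),
            },
            thermotype_by_tp=th_tp,
            thermotype_by_itc=th_itc,
            ombrotype=IntervalTable.from_rows("ombrotype", omb["by_io"]),
            gelid_tp_max=float(omb["gelid_tp_max"]),
            gelid_ombrotype=str(omb["gelid_code"]),
            long_names=doc.get("long_names", {}),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise RulesetError(f"ruleset missing required section: {exc}") from exc


def load_ruleset(path: str | Path) -> ClassificationRuleset:
    """Load and validate a ruleset YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse(yaml.safe_load(fh))


_DEFAULT: ClassificationRuleset | None = None


def default_ruleset() -> ClassificationRuleset:
    """The packaged WBCS ruleset (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = importlib.resources.files("wbcs.data").joinpath("wbcs_ruleset.yaml")
        _DEFAULT = _parse(yaml.safe_load(ref.read_text(encoding="utf-8")))
    return _DEFAULT
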