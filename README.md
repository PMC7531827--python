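# wbcs — Worldwide Bioclimatic Classification System for gridded climate

`wbcs` implements the Rivas-Martínez Worldwide Bioclimatic Classification
System (WBCS) for gridded monthly climatologies, together with a
multi-period change analysis.  It is aimed at bioclimatologists,
vegetation scientists and climate-impact analysts who have per-cell
monthly mean minimum/maximum temperatures and monthly precipitation
(e.g. regional-climate-model output) and want, for every cell, the
seven hierarchical WBCS units:

continentality → macrobioclimate → bioclimate → bioclimatic variant →
thermotype → ombrotype → isobioclimate,

and, across two or three time slices, area tables, per-cell change and
stability masks, aggregate warming/aridification trends and the loss of
bioclimatic diversity.

## The indices and the classifier

From the twelve monthly means `Ti = (tmin_i + tmax_i)/2` the package
computes every WBCS climatic parameter and bioclimatic index, notably

- continentality index `Ic = Tmax − Tmin` (annual thermal amplitude, °C);
- positive annual temperature `Tp = 10·Σ{Ti : Ti > 0}` (tenths of °C);
- thermicity index `It = (T + m + M)·10`, compensated to
  `Itc = It ± C(Ic)` under extreme oceanicity/continentality;
- annual ombrothermic index `Io = 10·Pp/Tp`, with the summer family
  `Iosi`, `Ios2`, `Iosc3`, `Iosc4`, `Iod2` used to diagnose and possibly
  compensate summer aridity (`Ios2 ≤ 2` uncompensated = mediterraneity);
- windowed precipitation totals (`Pcm1..3`, `Pss`, `Psw`, quarter sums).

Classification is a pure threshold hierarchy: macrobioclimates use
`T`, `M`, `Itc`, `Tp` recomputed as if each cell stood at 200 m
elevation; bioclimates split on `Io` bands and the oceanic/continental
boundary `Ic = 21`; variants apply the steppic conditions
(`Ps ≥ Pw`, `0.2 < Io ≤ 6.0`, every summer month `Psi < 3·Ti`) and the
submediterranean condition (some summer month `Pi < 2.8·Ti`);
thermotypes follow the dispatch rule "if `Ic ≥ 21` or `Itc < 120`,
classify by `Tp`, otherwise by `Itc`"; ombrotypes share one `Io` table.
Every numeric threshold lives in a versioned YAML ruleset
(`src/wbcs/data/wbcs_ruleset.yaml`) — nothing is hard-wired — so the
whole system is auditable and overridable.

## Worked example

```python
import wbcs
from wbcs.change import area_table, stability_fraction, diversity_summary

spec = wbcs.SyntheticGridSpec(n_cells=1200, seed=42)   # continental test grid
grids = wbcs.generate_grids(spec)                      # three 25-year periods
labels = [wbcs.classify_grid(g) for g in grids]

print(area_table(labels, "macrobioclimate", [g.period_label for g in grids]))
stable, changed = stability_fraction(labels, "thermotype")
print(f"thermotype stability: {stable:.1f}% stable / {changed:.1f}% changing")

cell = next(iter(grids[0].cells()))
c = wbcs.classify_cell(cell)
print(c.isobioclimate, "->", wbcs.isobioclimate_long_name(c.isobioclimate))
```

prints

```
                 count_1980-2004  pct_1980-2004  ...  pct_2035-2059  delta_pct
macrobioclimate                                  ...
MEDITERRANEAN               1132          94.33  ...          95.08       0.75
TEMPERATE                     68           5.67  ...           4.92      -0.75

thermotype stability: 21.0% stable / 79.0% changing
MEDC Sme Ari -> mediterranean desertic continental, supramediterranean, arid
```

The area table counts cells per class and period with the final-minus-
first percentage delta; the stability line is the fraction of cells
keeping one thermotype through all periods (warming moves many cells
from the supramediterranean into the mesomediterranean belt, hence the
low thermal stability); `MEDC Sme Ari` is the isobioclimate of a
desert-steppe cell — mediterranean desertic continental bioclimate,
supramediterranean thermotype, arid ombrotype.

## Command line

```sh
wbcs synth -o data/                 # write synthetic period CSVs
wbcs classify data/climate_1980-2004.csv -o p1.csv
wbcs run data/climate_*.csv -o out/ # full pipeline: tables, masks, maps
wbcs compare p1.csv p2.csv p3.csv -o cmp/
```

`run` writes per-period classified grids (CSV + GeoJSON cell polygons),
one area table per unit, change/stability masks, trend and diversity
summaries, optional PNG maps, and a manifest with the ruleset version
and input checksums.

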