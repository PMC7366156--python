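# Plot-bundle data dictionary

The measurement stage serializes one CSV per table, keyed by `plot_id`
(and `part_id` where applicable).  Text columns are read back as strings
verbatim; empty cells are the only missing-value marker.

## plots.csv
| column | type | meaning |
|---|---|---|
| plot_id | any | plot identifier |
| x, y | float, m | plot centre, projected coordinates |
| droppings | int | moose/red-deer dropping patches on the 100 m² circle |
| vegetation_type | str | dominant vegetation type code of the stand |
| n_parts | int | 1, or 2 if the plot is split at a stand border |

## trees.csv — stems with dbh ≥ 5 cm on the 250 m² plot
| column | type | meaning |
|---|---|---|
| part_id | int | plot part containing the stem (1 or 2) |
| tree_id | int | stable stem identifier across inventory cycles |
| species | str | species code (e.g. `spruce`, `scots_pine`, `birch`) |
| species_group | str | tally group: `spruce` / `pine` / `deciduous` |
| dbh_cm | float | diameter at breast height (1.3 m), cm |
| height_m | float | tree height, m (measured on h-trees) |
| status | str | `live` / `dead` / `removed` |
| standing | bool | false for downed dead stems |
| distance_m | float | horizontal distance from plot centre |
| azimuth_deg | float | azimuth from plot centre, degrees [0, 360) |

## smalltrees.csv — stems with dbh < 5 cm on the four 5.3 m² subplots
| column | type | meaning |
|---|---|---|
| subplot | str | `N`/`E`/`S`/`W`, 5 m from centre |
| n_class1 | int | count with dbh < 2.5 cm |
| n_class2 | int | count with dbh 2.5–5 cm |

## regen.csv — regeneration on the five 16 m² subplots
| column | type | meaning |
|---|---|---|
| subplot | str | `C` (centre) or `N`/`E`/`S`/`W` at 12 m |
| n_trees | int | stems taller than 30 cm |

## deadwood.csv — pieces intersecting the two 18 m transects
| column | type | meaning |
|---|---|---|
| transect_id | str | `EW` or `NS` |
| species_group | str | as above |
| decay_class | int | ordinal decay stage (1 = fresh … 5 = decomposed) |
| length_m | float | piece length |
| diameter_cm | float | diameter at the transect intersection point |
| d_root_cm, d_cross_cm, d_top_cm | float | diameters at root end, middle, top |

## berry.csv
| column | type | meaning |
|---|---|---|
| quadrat | str | `N`/`E`/`S`/`W`, 0.25 m² squares at 5 m |
| species | str | `bilberry` or `lingonberry` |
| cover | float | cover fraction in [0, 1] |
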