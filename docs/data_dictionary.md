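# Data dictionary

Column schemas for every delimited file the package reads or writes.

## Trait file (`traits.csv`) — written by `classify`/`simulate`, read by `reconstruct`/`delta`

| column | type | meaning |
|---|---|---|
| taxon | str | tip label matching the tree |
| state | int 1–6 | six-state pattern code |

## Descriptor file — read by `classify`

| column | type | meaning |
|---|---|---|
| specimen_id | str | unique specimen identifier |
| pronotum_colour | str | one of black, red, orange, yellow, metallic, green, other |
| elytra_zones | str | semicolon-joined `zone:colour` pairs, e.g. `basal:red;apical:black` |
| arrangement | str | uniform, pronotum_vs_elytra, bicoloured_elytra, fasciate, striate, punctate, reticulate, tricoloured, other |
| n_distinct_dorsal_colours | int ≥1 | distinct colours on the dorsum |
| elytra_shape | str | normal, posteriorly_widened, globuliform |

## Contrast report (`contrast.csv`)

| column | type | meaning |
|---|---|---|
| specimen_id | str | specimen identifier |
| part | str | bright, dark, or `bright\|dark` for the IC row |
| leaf | str | background leaf id (empty for IC) |
| side | str | upper / bottom (empty for IC) |
| measure | str | EC-DeltaE or IC-DeltaE |
| delta_e | float ≥0 | ΔE76 value |

One row per (part × background) plus exactly one IC row.

## Reconstruction export (`reconstruction.csv`)

| column | type | meaning |
|---|---|---|
| node | int | internal node index (tips occupy indices below `n_tips`) |
| map_state | int | MAP state, ties broken toward the lower index |
| p1..pk | float | marginal posterior probability of each state (sums to 1) |

## Origin report (`origins.csv`)

| column | type | meaning |
|---|---|---|
| state | int | derived state of the event |
| node | int | child node of the transition branch |
| rtu_age | float in [0,1] | age of that node in relative time units |
| parent_state | int | parent's MAP state |
| is_reversal | bool | state equals some strict ancestor's MAP state |

Rows are sorted oldest-first.

## δ report (`delta.csv`)

| column | type | meaning |
|---|---|---|
| clade | str | clade name (or `all`) |
| n_tips | int ≥20 | taxa in the clade |
| delta | float ≥0 | δ statistic |
| p_value | float (0,1] | add-one shuffle p (empty when no null requested) |
| n_shuffles | int | permutations in the null |
| seed | int | settings seed |

## Regional table (`regional.csv`)

| column | type | meaning |
|---|---|---|
| region | str | unique region name |
| n_tribes | int ≥0 | tribes recorded (phylogenetic-diversity proxy) |
| n_species | int ≥0 | described species (alpha diversity) |
| n_patterns | int ≥0 | distinct colour patterns |
| abundance_class | str | low / medium / high (optional) |

## Regression report (`regressions.csv`)

| column | type | meaning |
|---|---|---|
| predictor | str | n_tribes or n_species |
| slope, intercept | float | OLS fit of n_patterns on the predictor |
| r_squared | float [0,1] | coefficient of determination |
| n | int ≥2 | regions used |

## True-change sidecar (`true_changes.csv`, synthetic runs)

| column | type | meaning |
|---|---|---|
| node | int | child node of the branch carrying the change |
| time | float | time along the branch from its rootward end |
| from_state, to_state | int | simulated transition |

## Manifest (`manifest.json`)

JSON object with `tool`, `version`, `config` (the exact run parameters,
including the seed) and `inputs` (path → SHA-256). Re-running with the same
config reproduces every output byte for byte.

## Group / clade maps

Two-column CSV `tip,group` assigning every tip label to a tribe (pruning)
or subfamily (δ clade splitting).
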