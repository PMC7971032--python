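# mimevo

Toolkit for the comparative analysis of aposematic (warning) colour patterns:
how conspicuous they are, how they are distributed over a phylogeny, when
they originated, and what predicts their regional diversity. The package was
built with Müllerian-mimicry systems such as net-winged beetles in mind —
lineages in which hundreds of chemically defended species share, and
repeatedly reinvent, a modest set of warning patterns — but every component
is generic.

## What it computes

**Conspicuousness.** Specimen and background colours are expressed in CIE
1976 La\*b\* and compared with the Euclidean colour distance

ΔE₇₆ = √((L₁−L₂)² + (a₁−a₂)² + (b₁−b₂)²).

Two scores follow: external contrast (EC-ΔE) of a body part against each
leaf background (upper and bottom leaf surfaces separately), and internal
contrast (IC-ΔE) between the bright and the dark part of a bicoloured
dorsum. Patch colours come from replicate 31×31-pixel windows averaged in
Lab space; a least-squares affine calibration in linear RGB is available
for uncalibrated sensors.

**Pattern coding.** A structured colouration descriptor is projected onto a
fine 19-category vocabulary (uniform black/yellow/orange/red, metallic,
bicoloured forms, fasciate, striate, punctate, reticulate, tricoloured,
named rare combinations) with an open overflow class, and onto the coarse
six-state trait used for comparative analysis: (1) uniform dorsum,
(2) pronotum–elytra contrast, (3) bicoloured elytra, (4) fasciate,
(5) striate, (6) non-categorized.

**Trait evolution.** The six-state trait evolves under the Mk model — a
continuous-time Markov chain with rate matrix Q on a rooted tree. The
package provides Felsenstein-pruning likelihoods, ML estimation of the
equal-rates transition rate with a likelihood-ratio interval, marginal and
Bayesian (MCMC) ancestral-state reconstruction, and origin events: nodes
whose most-probable state differs from their parent's, dated in relative
time units (RTU; root age 1.0, tips 0.0), with reversals to ancestral
states flagged.

**Phylogenetic signal.** The δ statistic for categorical traits: posterior
ancestral-state probabilities give per-node Shannon entropies, a Beta(α, β)
model is fitted to them by MCMC, and δ = mean(β)/mean(α). Larger δ means
the trait tracks the tree more closely; a tip-shuffle null provides
p-values. Clades under 20 taxa are refused.

**Regional diversity.** OLS regressions of pattern richness on tribe count
(a phylogenetic-diversity proxy) and species count (alpha diversity),
summarised by R², plus the three-level abundance classification
(<100 individuals/collector/month = low, 100–300 = medium, >300 = high).

**Synthetic data.** Everything above is testable without external data:
birth–death relative-time trees, Mk traits with recorded change histories,
rendered two-patch specimens on leaf backgrounds with sensor noise, and
regional tables with a controllable species↔pattern correlation.

## Worked example

`examples/` holds one short script per capability. `01_contrast_scoring.py`
renders a noisy two-patch specimen and scores it:

```
IC-dE (bright vs dark part): 90.65  (noiseless truth 90.72)
EC-dE of the bright part against each leaf background:
  leaf1/bottom:   86.85
  leaf1/upper :   91.60
  leaf2/bottom:   84.48
  leaf2/upper :   92.10
  leaf3/bottom:   82.85
  leaf3/upper :   88.48
```

The internal contrast (90.65) exceeds every external contrast — the
signature of a bicoloured warning signal — and the recovered value sits
0.07 ΔE from the noiseless truth. `03_ancestral_origins.py` simulates a
120-tip tree with a known history and recovers its origins:

```
true rate 0.3, ML estimate 0.274 (log-likelihood -90.70)
simulated changes: 31; inferred origin events: 21
  state 6 -> 5 at 0.603 RTU
  state 6 -> 4 at 0.478 RTU
  ...
```

A thin CLI binds the stages into a deterministic workflow:

```bash
mimevo pipeline --seed 7 --out run/     # simulate -> contrast -> reconstruct
                                        #   -> delta -> diversity, + manifest
mimevo delta --tree t.nwk --traits x.csv --out d/
```

Column schemas for every CSV are documented in `docs/data_dictionary.md`.

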