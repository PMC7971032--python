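# Methods

This note documents the models implemented in mimevo, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
data can and cannot establish about real material.

## Colour conversion and contrast

Device RGB is interpreted as sRGB (IEC 61966-2.1): inverse companding,
the standard linear-RGB→XYZ matrix, and the CIE 1976 La\*b\* transform with
the D65 illuminant and 2° observer. The reference white is taken as the row
sums of the conversion matrix (equal to the published D65 tristimulus
values to 1e-7); this makes RGB (1,1,1) map exactly to L=100, a\*=b\*=0
rather than inheriting the ~0.003 rounding residue of the 7-digit matrix.
The implementation agrees with scikit-image's conversion within 0.006 ΔE
across the gamut; scikit-image is used only as an independent cross-check
in the tests, never as the implementation.

Colour distance is ΔE₇₆, the Euclidean distance in Lab — deliberately not
ΔE₂₀₀₀: the contrast scores are defined in terms of the 1976 metric and no
perceptual-uniformity correction is applied. External contrast (EC-ΔE) is
the distance of a body part's mean colour from a background colour, scored
separately per leaf and per leaf side (upper/bottom); internal contrast
(IC-ΔE) is the distance between the bright and the dark body part, and is
undefined for uniformly coloured specimens.

Patch sampling takes five replicate windows of 31×31 pixels (both
caller-configurable); each replicate is averaged per-pixel **after**
conversion to Lab, and the replicate means are averaged again in Lab. The
averaging space is a genuine design choice (sources rarely state it); Lab
was chosen because the reported quantity is a Lab position and ΔE is
computed there. Window centres are caller-supplied coordinates (0-based
row/col, windows fully inside the image); a jitter helper scatters
replicates around a seed point. 8- and 16-bit integer images are rescaled
by the type maximum.

Sensor calibration is a least-squares affine map (3×3 matrix + offset) on
linear RGB fitted from ≥4 measured/reference patch pairs, with the RMS
residual reported. This is a simple stand-in for full ICC-profile colour
management, which is out of scope.

## Pattern taxonomy

The fine classification uses a 19-entry controlled vocabulary plus an open
"non-categorized" overflow whose free-text descriptions count as distinct
patterns in richness tallies. The vocabulary lives in one editable registry
file (`pattern_registry.py`) and is explicitly provisional: the historical
19-way scheme was never published as a closed list, so the registry
reconstructs it from described pattern groups and should be amended to
match one's own material. Two entries (black-amethyst, red-blue) name
colours outside the descriptor's colour-class vocabulary; they can be
assigned directly to records but are not reachable from a descriptor.

The six-state coding is the analysis trait. State 1 is reserved for uniform
black/yellow/orange/red dorsa; uniformly green or metallic animals are
state 6. States 2 and 3 require a genuine dark/bright contrast (black
versus red/orange/yellow) between the pronotum and elytra, or between
elytral parts; other two-colour combinations (red pronotum + metallic
elytra, red/green, green/black) are state 6, as are punctate, reticulate
and tricoloured arrangements. The 19→6 projection commutes with direct
six-state classification on every descriptor (property-tested), so
collection records coded at either granularity land in the same analysis
states. Specimens are coded independently — polymorphism appears as
different codes for conspecific specimens, and sexually dimorphic sexes
fall in the same six-state class.

## Trees and relative time

Newick I/O is delegated to dendropy; round-trips preserve topology, labels
and branch lengths to 10 significant digits. Node age is distance to the
tips (0 at the present). Ultrametricity is checked with a relative
tolerance of 1e-6 × tree height to absorb round-off from decimal branch
lengths. The RTU transform divides all branch lengths by the root age and
then absorbs residual float error into the tip edges, so the root age is
exactly 1.0 and tip ages exactly 0.0; the transform is idempotent and
invariant to uniform rescaling of the input.

Representative pruning reduces each group (e.g. tribe) to 3–5 terminals
"spanning its deepest splits". That phrase does not pin down an algorithm,
so it is operationalised as greedy phylogenetic-diversity maximisation:
seed with the two tips realising the group's deepest divergence, then
repeatedly add the tip whose path to the already-retained subtree is
longest (ties broken by label). The greedy rule is deterministic, seed-free
and provably optimal for retained subtree length; pairwise path lengths
among retained tips are preserved exactly in the induced subtree.

## Mk model machinery

The trait model is the k-state Mk CTMC. The default structure is equal
rates (ER) with a uniform root prior — the minimal defensible default when
the generating process is unknown; symmetric/all-rates-different matrices
are accepted by the likelihood and reconstruction code. ER transition
probabilities use the closed form P_ii(t) = 1/k + (k−1)/k·e^(−kμt) rather
than a matrix exponential (the two agree to machine precision and are
cross-checked in tests); general Q falls back to `expm`.

The likelihood is Felsenstein pruning with per-node rescaling. ML rate
estimation is a bounded 1-D optimisation of the log-rate (convergence 1e-8);
a constant trait sits at the μ=0 boundary and is reported as such with a
warning rather than an error. The 95% confidence interval is the profile
likelihood-ratio interval (logL drop of χ²₁(0.95)/2).

Marginal ancestral reconstruction uses the standard inside/outside passes
and renormalises per node. MAP calls break ties toward the lower state
index, and every tie is recorded on the result — origin events depend on
MAP calls, so tie handling must be auditable. The Bayesian variant runs a
Metropolis chain on the log rate (exponential prior with mean at the ML
estimate) and takes one joint ancestral draw (forward-filter,
backward-sample) per retained sample; node vectors are posterior state
frequencies after discarding a 25% burn-in. Desk defaults are 10⁶
generations sampled every 10³; larger production settings are plain
arguments. The rate-chain effective sample size is reported, and ESS < 100
warns without failing.

Origin events are nodes whose MAP state differs from their parent's MAP
state. The event age is the RTU age of the **child** node — the
conservative, latest-possible origin reading of a transition branch; an
event is a reversal when its state matches the MAP state of some strict
ancestor above the parent. Counting events per state gives
independent-origin counts. Under MAP reconstruction multiple hits on one
branch collapse into one apparent event, so origin counts are a lower
bound on the true change count; the origin-detection tests quantify the
match rate under low rates instead of hiding the discrepancy.

## δ statistic

δ follows the published entropy-based recipe for categorical traits: a
Metropolis chain over the ER rate (exponential prior centred on the ML
estimate) yields marginal ancestral probability vectors averaged over
retained rate samples; node Shannon entropies normalised by log k are
modelled as Beta(α, β) with independent exponential priors (rate 0.1) via
an alternating Metropolis chain (proposal s.d. 0.5); δ = mean(β)/mean(α)
over the retained samples. Strong signal → confident ancestral states →
entropies near 0 → β inflated relative to α → large δ.

`DeltaSettings` carries the chain controls; the defaults
(sim=1,000,000, thin=100, burn=2500) reproduce the original analysis
settings, while the tests and the acceptance script run desk-scale chains
(sim=10,000–50,000, thin=10, ~10 rate samples) — the statistic stabilises
far below the default lengths on trees of this size. Entropies are clipped
to [1e-6, 1−1e-6] before the Beta fit; a constant trait (zero entropy
everywhere) is refused as degenerate, as is any tree under 20 tips — the
computation never silently runs below that threshold. Significance uses
tip-label permutation with the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n); an identity permutation still counts.
Per-node entropies and the chains are exposed on the result object so the
computation is auditable.

## Regional diversity

Pattern richness is regressed on tribe count and species count by ordinary
least squares (scipy), with R² = 1 − SS_res/SS_tot. OLS (not rank
correlation) matches the R² framing of the question. The abundance
classification is driven solely by individuals/collector/month (<100 low,
100–300 medium, >300 high; the boundary values read as medium under the
stated interval notation); the companion species-per-site ranges are
advisory — reported as consistent/inconsistent, never overriding the
classification — because the two criteria can conflict and no precedence
rule exists. The sensitivity helper substitutes one region's species count
and reports the before/after R² ratio.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of a seeded recipe; metadata sidecars make
every fixture regenerable. Defaults were fixed once as the study
conditions:

- **Trees**: birth–death (birth 1.0, death 0.5 — a moderate extinction
  fraction typical of empirical fits), conditioned on 200 extant tips,
  scaled to height 1 so node ages are already RTU. The 2-tip case is a
  height-1 cherry by construction.
- **Trait**: k=6, ER rate 0.5 per height-1 tree (moderately conserved —
  tens of changes on a 200-tip tree); the change history (branch, time,
  from, to) is recorded as ground truth and replays exactly to the tip
  states.
- **Images**: 256×256, dark pronotum over orange-red elytra on one of six
  leaf-green backgrounds (3 leaves × upper/bottom), additive Gaussian sRGB
  noise σ=0.01, five legal 31×31 window centres per patch.
- **Regional tables**: 12 regions; species counts log-uniform on
  [20, 1300]; pattern counts linear in species with noise solved from a
  target correlation of 0.6; tribe counts independent, emulating the
  decoupling of phylogenetic diversity from pattern richness.

Passing tests on these data show the estimators are correct and calibrated
under their own model. They do not show that real photographs meet the
noise model (specular highlights, uneven illumination and segmentation
error are absent), that real pattern evolution is ER-Markovian, or that
real regional tables follow a linear species→pattern response. The printed
quantities of the motivating study (mean EC 32–53, IC 62–66, δ 2.13–5.90,
origin ages 0.09–0.59 RTU, R² 0.057/0.23) depend on photographs, codings
and tables that were never machine-readably deposited, so they are not
reproduction targets; the package's acceptance surface is the property
suite plus the synthetic-study quantities recomputed by
`scripts/acceptance.py`.

## Numerical choices and limitations

- MAP ties: lower state index wins, ties logged.
- Pruning rescales per node; impossible configurations return −inf.
- The δ Beta chain uses sufficient statistics, so chain cost is independent
  of tree size; the rate chain dominates instead.
- `estimate_rate` searches μ ∈ [1e-8, 100] on the log scale; hits of either
  bound are flagged as boundary estimates.
- Joint (global-MAP) reconstruction, correlated-trait models and
  trait-dependent diversification are out of scope; the Bayesian
  reconstruction samples only the ER rate, not the tree.
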