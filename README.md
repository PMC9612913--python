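# morphograd

Quantitative analysis of morphogen gradient formation in early embryos,
built around the zebrafish Nodal system: how a secreted TGF-β-family ligand
(Squint/Cyclops) spreads from its source at the embryonic margin, how
receptors and co-receptors hinder its diffusion, and how far the resulting
signaling gradient (read out as nuclear pSmad2/3) reaches.

The package is aimed at developmental biologists and image analysts who
want a tested, scriptable re-implementation of this analysis chain that can
be exercised end to end on synthetic embryo data with known ground truth —
every quantification stage is scoreable against the generator's truth
record, with no manual annotation.

## What it computes

**Synthesis–diffusion–clearance model.** Extracellular ligand at
concentration *c(x, t)* obeys

    ∂c/∂t = D ∂²c/∂x² + p(x) − k c

with effective diffusivity *D* (µm²/s), production *p* (restricted to a
source region such as the yolk syncytial layer) and first-order clearance
*k* (1/s). Its steady state from a localized source is exponential,
*c(x) = c₀ exp(−x/λ)* with length scale *λ = √(D/k)*. Transient binding to
immobile regulators (receptors, proteoglycans) hinders diffusion:
*D_eff = D_free / (1 + K)* for bound-to-free ratio *K*.

**FRAP** (`morphograd.frap`) — simulate and fit fluorescence recovery after
photobleaching with the full diffusion–production–clearance forward model
to estimate *D*, with the four recovery-curve exclusion criteria (overall
R² < 0.8, high local variability, linear increase, early-kinetics
mismatch).

**FDAP** (`morphograd.fdap`) — fit fluorescence decay after photoconversion
with *c(t) = c₀ e^(−kt) + offset* to estimate the clearance rate constant,
excluding saturated/artifact frames; records with R² < 0.88 fail QC.

**Gradient profiles** (`morphograd.gradient`) — source masking (iterative
intermeans threshold), maximum projection, distance-binned profile
extraction with artifact masking, control-median background subtraction,
the inter-embryo normalization model *Iₙ(x) = Aₙ·c̄(x) + bₙ* (per-embryo
least squares against the mean profile), origin normalization, punctum
detection, and radial clone-edge profiles.

**Nuclear quantification** (`morphograd.psmad`) — DAPI nuclear masking,
margin-to-animal-pole pSmad profiles, contiguous positive-tier counting
(the signaling-range unit: one 8 µm nucleus-wide band parallel to the
margin), 3-D transplanted-cell counting, per-cell-normalized transplant
range profiles, and animal-pole-positive nucleus counts.

**Statistics** (`morphograd.stats`) — equal/unequal-variance two-tailed t
tests, two-tailed variance-ratio F test, Shapiro–Wilk, tie-corrected
Wilcoxon rank-sum with continuity-corrected normal approximation, and
Hedges-bias-corrected Cohen's d (sign convention: condition − reference).

**Synthetic embryos** (`morphograd.synthetic`) — deterministic generators
for all of the above, with a `SceneTruth` sidecar sufficient to score every
downstream operation.

## Worked example

Simulate a wild-type-like FRAP experiment (D = 2 µm²/s, clearance
1e-4 /s, 40 µm bleach window on a 200 µm domain, 1% measurement noise) and
fit it back:

```python
from morphograd import RDParams, Domain1D, simulate_frap, fit_frap, effective_diffusivity
from morphograd.synthetic import default_frap_frames

params = RDParams(D=2.0, p=1e-2, k=1e-4)
domain = Domain1D(length_um=200.0, dx_um=2.0)
record = simulate_frap(params, domain, default_frap_frames(2.0),
                       bleach_interval=(80.0, 120.0), bleach_depth=0.8,
                       noise_sd=0.01, seed=42)
fit = fit_frap(record)
print(f"D = {fit.D_hat:.2f} um^2/s   R^2 = {fit.r_squared:.4f}   qc_pass = {fit.qc_pass}")
print(f"D_eff at K=9: {effective_diffusivity(40.0, 9.0)} um^2/s")
```

prints

```
D = 2.05 um^2/s   R^2 = 0.9987   qc_pass = True
D_eff at K=9: 4.0 um^2/s
```

i.e. the fitter recovers the true effective diffusivity within a few
percent and the record passes all four QC criteria; the second line is the
hindered-diffusion arithmetic — a free diffusivity of 40 µm²/s slowed one
order of magnitude by a binding ratio of K = 9.

The same chains are reachable from the command line:

```sh
morphograd simulate --scenario frap-recovery --seed 1 --out run/
morphograd quantify-psmad --seed 0 --positive-tiers 12 --out tiers.json
morphograd stats measurements.csv --reference-label wt --out stats.csv
```

## Layout

```
src/morphograd/
  rd.py         reaction-diffusion core (closed forms, implicit solver)
  frap.py       FRAP simulation + model fitting + QC
  fdap.py       FDAP exponential fits + frame exclusion
  gradient.py   profile extraction, normalization model, puncta, clone edges
  psmad.py      nuclear masks, tiers, transplants, counts
  stats.py      two-sample tests and effect sizes
  synthetic.py  ground-truth generators
  pipeline.py   config, seeding, reproduce scenarios
  cli.py        `morphograd` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
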