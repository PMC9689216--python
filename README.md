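# tgnet

Time-varying conditional-dependence networks for non-negative keyword
panels: truncated-Gaussian graphical models estimated by generalized score
matching, with fused-lasso clustering of periods into phases, followed by
small-world / scale-free network statistics, hub identification, Louvain
module detection, and topic-strength series.

## Who this is for

Researchers doing quantitative linguistic or media analysis — or anyone
with per-period matrices of non-negative measurements over a fixed variable
set — who want to know (a) which variables are conditionally dependent in
each period, (b) when that dependence structure changes, and (c) what the
resulting networks look like topologically.

## Model and method

Within period m, an observation vector y ∈ ℝ₊ᵖ (e.g. one report's adjusted
keyword frequencies) follows a truncated Gaussian with density proportional
to `exp(−½ yᵀΘ⁽ᵐ⁾y + η⁽ᵐ⁾ᵀ(y−1))` on the non-negative orthant.  Keywords
l, j are conditionally dependent iff θ_lj ≠ 0 — the edges of the period's
network.  Because the normalizing constant is intractable, (Θ, η) are
estimated by an h-weighted score-matching loss (quadratic and convex), and
all M periods are fitted jointly:

    min  Σₘ Ĵₘ(Θ⁽ᵐ⁾,η⁽ᵐ⁾) + λ₁ Σₘ |Θ⁽ᵐ⁾⁻| + λ₂ Σₘ ‖Θ⁽ᵐ⁾⁻ − Θ⁽ᵐ⁺¹⁾⁻‖_F

The ℓ₁ term gives sparse networks; the fused Frobenius term ties adjacent
periods exactly, so maximal runs of tied periods form *phases* and their
boundaries are *change points*.  Solved by consensus ADMM with exact
proximal steps for both penalties.  See `docs/methods.md` for the full
account, including the tuning rules and the network-statistics conventions.

## Worked example

Recover a known phase structure from synthetic data (the package's own
validation experiment), then inspect a phase network:

```python
from tgnet import make_scenario, sample_panel, recovery_experiment
from tgnet.validation import detect_change_points, recover_edges
from tgnet.fitter import refit_structure
from tgnet.netstats import build_network, indicators
from tgnet.tgm import pooled_scale

res = recovery_experiment(seed=1)
print("change points:", res.change_points, "true:", res.true_change_points)
print("edge F1:", res.f1)

scen = make_scenario(seed=1)          # p=10 keywords, 12 periods, 3 phases
mats = sample_panel(scen)
cps, phases = detect_change_points(mats)
supports = recover_edges(mats, phases)
scales = pooled_scale(mats)
ests = refit_structure([m / scales for m in mats], phases, supports)
net = build_network(ests[0].Theta)
ind = indicators(net)
print(f"phase 1 network: {net.q} edges, avg degree {ind.avg_degree:.3f}, "
      f"ASPL {ind.aspl:.3f}/{ind.aspl_r:.3f}, CC {ind.cc:.3f}/{ind.cc_r:.3f}, "
      f"sigma {ind.sigma:.3f}")
```

prints

```
change points: [4, 8] true: [4, 8]
edge F1: 1.0
phase 1 network: 8 edges, avg degree 1.600, ASPL 2.071/3.000, CC 0.000/0.286, sigma 0.000
```

The change points after periods 4 and 8 are found exactly and all 24 true
edges (8 per phase) are recovered with no false positives.  The phase-1
network is a sparse 8-edge graph: average degree 2q/n = 1.6, average
shortest-path length 2.071 against an Erdős–Rényi baseline of 3.000, and a
clustering coefficient of 0 (a forest — no triangles), hence small-world
coefficient σ = 0.

## Command-line pipeline

The `tgnet` console script wires the stages together
(`simulate` → `prep` → `fit` → `nets` → `report`, or `run-all`):

```sh
tgnet run-all --seed 2 --p 6 --periods 6 --phases 2 --out out/
tgnet prep --corpus reports.jsonl --stopwords stop.txt --merge-map merge.csv --out panel/
tgnet fit  --panel panel/ --out fit/       # AIC grid search over (λ1, λ2)
tgnet nets --fit-dir fit/ --out nets/      # indicators, hubs, modules, GraphML
```

Corpora are JSON-lines (`id`, `date`, `text`); panels, estimates,
indicators, hubs, modules and topic strengths are plain CSV plus JSON
manifests, so every run is reproducible from its outputs.

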