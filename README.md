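# emstem

Ensemble ODE simulation of the coupled epithelial–mesenchymal plasticity
(EMP) and stemness gene-regulatory circuit, for systems biologists studying
why hybrid epithelial/mesenchymal (E/M) cell states are so often the
stem-like ones.

The core EMP module is the mutually inhibitory miR-200 ⊣ ZEB toggle (with
ZEB self-activation and SNAIL input); the stemness module is the LIN28 ⊣
let-7 toggle (with self-activations and NF-kB input).  The two modules are
coupled by two microRNA repressions, miR-200 ⊣ LIN28 and let-7 ⊣ ZEB.
`emstem` asks what dynamical behavior is *encoded in this wiring itself*,
independent of any particular kinetic parameter choice, by simulating
thousands of random parameterizations of the circuit and analyzing the
pooled steady states.

## Model

Each node `i` follows a production–decay ODE in which every incoming link
contributes a shifted Hill factor:

    dp_i/dt = g_i · ∏_j HS(p_j; μ_ji, λ_ji, n_ji) − k_i p_i

    HS(p; μ, λ, n) = μⁿ/(μⁿ + pⁿ) + λ·pⁿ/(μⁿ + pⁿ)

`HS` equals 1 with no regulator and saturates at the fold change λ (λ > 1
activation, λ < 1 inhibition); μ is the regulation threshold and n the Hill
coefficient.  The maximal production rate `G = g·∏λ⁺` (over incoming
activations) is what is sampled; `g` is derived.  An ensemble draws `G`,
`k`, `λ`, `μ`, `n` uniformly from biologically motivated ranges (thresholds
calibrated by the half-functional rule so each link is active with roughly
even odds), integrates many log-uniform initial conditions per parameter
set to steady state, and keeps each distinct stable state once.

Downstream analysis mirrors the standard random-circuit-perturbation
workflow: gene-wise log2 normalization against the unperturbed reference
ensemble, k-means partition of the four core nodes into phenotypes e / he /
hm / m (named by ascending median ZEB), multistable *phase* labels such as
{e,m}, a LIN28 "stemness window" (middle 30% of median ± IQR), and the two
enrichment probabilities p1 = P(in window | phenotype) and
p2 = P(phenotype | in window).  Node over-/down-expression (e.g. oe10 =
10-fold) scales the node's `G` sampling range.  Six circuit variants are
bundled: `base`, `uncoupled`, and the phenotypic-stability-factor (PSF)
circuits `grhl2`, `grhl2_kd`, `ovol`, `nrf2`; arbitrary circuits load from
RACIPE-style `.topo` files.

## Worked example

```sh
emstem report --preset mini --circuit base --seed 7 --outdir demo_out --no-plots
```

prints (2 replicates × 600 random parameter sets × 30 initial conditions,
about one minute on a laptop core):

```
multistability (mean across replicates):
                mean        sd
monostable  0.308333  0.018856
bistable    0.378333  0.030641
tristable   0.237500  0.015321
>=4-stable  0.075833  0.003536

stemness enrichment (mean across replicates):
            p1_mean     p1_sd   p2_mean     p2_sd
phenotype
e          0.195646  0.013495  0.283121  0.035906
he         0.326876  0.019562  0.259962  0.006566
hm         0.505333  0.011364  0.328069  0.002585
m          0.086016  0.017511  0.128848  0.026755
```

Reading this: ~31% of random parameterizations are monostable, ~38%
bistable, ~24% tristable — the coupled circuit is robustly multistable.
The p1 column says a hybrid-mesenchymal (hm) solution has a ~51% chance of
lying in the stemness window versus ~9% for a fully mesenchymal (m) one;
summing hybrids vs non-hybrids (p1: 0.83 vs 0.28, p2: 0.59 vs 0.41) shows
the hybrid states are the stem-enriched ones, a property of the topology
rather than of any tuned parameter set.  Full tables (per-replicate
solutions, phase frequencies, enrichment, manifest) are written to
`demo_out/`.

The same analysis is available as a library:

```python
import emstem as es

cfg = es.RunConfig.preset("desk", circuit="grhl2", seed=1,
                          perturbation_node="GRHL2")
sweep = es.perturbation_sweep(cfg)           # de10 / ref / oe10 ensembles
sweep.by_fold[10.0].probs.hybrid_sums()      # hybrids stay stem-enriched
```

## Layout

| module | role |
| --- | --- |
| `emstem.topology` | `.topo` I/O, bundled circuits, validation |
| `emstem.sampler` | random kinetic parameterizations, fold-change perturbations, initial conditions |
| `emstem.dynamics` | ODE right-hand side, steady-state enumeration, multistability |
| `emstem.clustering` | normalization, k-means phenotypes, PCA, phases, Ward cross-check |
| `emstem.stemness` | stemness window, p1/p2, window-width sensitivity |
| `emstem.linkmetrics` | link strength, loop asymmetry, coupling strength |
| `emstem.pipeline` | replicates, sweeps, significance tests, persistence |
| `emstem.cli` | `emstem simulate / cluster / stemness / links / sweep / report` |

See `docs/methods.md` for the modeling assumptions, numerical choices, and
known limitations.
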