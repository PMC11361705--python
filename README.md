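# stavquant

Quantitative analysis of **streptavidin-vs-antibody fluorescence imaging**
and **proximity-labelling proteomics** for TurboID-HA tagged proteins.

When a protein of interest is fused to the biotin ligase TurboID plus an HA
epitope tag, it can be detected two ways in the same cell: with fluorescent
streptavidin (which binds the biotin deposited on the bait and its
neighbours) and with an anti-HA antibody. The two probes disagree in
informative ways. Streptavidin reaches targets inside dense, phase-separated
compartments — the FG-repeat channel of the nuclear pore, the nucleolus,
stress granules — where antibodies fail or only decorate the periphery, and
the multiply-biotinylated neighbourhood gives streptavidin a much stronger
signal. `stavquant` turns those qualitative observations into numbers:

- **Granule sizing at 50% fluorescence.** From a sum-slices z-projection, a
  line profile *I(x)* is drawn through a granule in both channels on the
  identical segment. With baseline *b* (mean of the lowest decile) and peak
  *I*max, the diameter is the distance between the outermost crossings of
  the level *b* + ½(*I*max − *b*). The per-granule **diameter quotient**
  *q* = *d*(anti-HA) / *d*(streptavidin) exceeds 1 when the antibody stains
  only a peripheral shell, and such shell profiles show a characteristic
  double peak. For a uniformly labelled sphere of radius *r* with no blur,
  the projected profile is ∝ √(r² − x²) and the measured diameter has the
  closed form √3·*r* — used as an exactness check of the whole chain.
- **Maximum-signal statistics.** Per cell, the maximum projected intensity
  inside the cell mask; groups (streptavidin-stained vs antibody-stained)
  are compared by fold change of means and an unpaired two-tailed Student
  t-test.
- **Antibody-accessibility score.** Within the streptavidin-defined mask
  *M* and background region *B*,
  `score = (med HA|M − med HA|B) / (med strep|M − med strep|B)`,
  aggregated as a median over cells and binned into increment classes to
  build an N-/C-terminus accessibility table across tagged proteins.
- **LFQ enrichment.** The standard label-free quantification contrast for
  BioID/TurboID pulldowns: keep protein groups with ≥1 valid bait value,
  log2-transform, impute missing values per sample from
  Normal(μ − 1.8σ, (0.3σ)²), Student's t-test of bait (n = 2–3) against the
  untagged control triplicate, report the *t*-test difference (Δ mean log2),
  bin it into enrichment increments and map onto a nuclear-pore parts list.

Everything is testable without any experimental data: `stavquant.scene`
generates ground-truthed two-channel 3D stacks (volume- or shell-labelled
spherical granules, nuclear-pore punctae, anisotropic Gaussian PSF, Poisson
shot noise + Gaussian read noise) and LFQ tables with intensity-dependent
missing-not-at-random dropout.

## Worked example

Simulate a replicated stress-granule experiment — anti-HA staining the
granule shell (`shell_fraction 0.25`), streptavidin filling the volume —
and quantify it:

```python
from stavquant.scene import simulate_granule_experiment
from stavquant.profiles import quantify_stack, summarise_replicates

cells = simulate_granule_experiment(n_replicates=3, cells_per_replicate=10, seed=7)
measurements = [
    m for c in cells
    if (m := quantify_stack(c.stack, granule_id=f"r{c.replicate}c{c.cell}",
                            replicate=c.replicate)) is not None
]
for s in summarise_replicates(measurements):
    print(f"replicate {s.replicate}: n={s.n_granules} "
          f"mean quotient={s.mean_quotient:.2f} (SD {s.sd_quotient:.2f}) "
          f"HA double-peak fraction={s.double_peak_fraction['HA']:.2f}")
```

```
replicate 0: n=10 mean quotient=1.24 (SD 0.02) HA double-peak fraction=0.90
replicate 1: n=10 mean quotient=1.26 (SD 0.04) HA double-peak fraction=1.00
replicate 2: n=10 mean quotient=1.24 (SD 0.02) HA double-peak fraction=1.00
```

Every replicate's mean quotient is above 1 — the antibody channel measures
wider than streptavidin on identical geometry — and the shell staining shows
up as double-peaked HA profiles. The LFQ side, on simulated intensities with
known log2 effects:

```python
from stavquant.scene import LfqSimSpec, simulate_lfq_table
from stavquant.lfq import run_enrichment, ImputeParams

table, effects, groups = simulate_lfq_table(
    LfqSimSpec(n_proteins=200, effects=(0.0, 5.0), seed=7))
res = run_enrichment(table, groups, "bait", "control",
                     impute_params=ImputeParams(seed=7))
print(res.join(effects).groupby("true_log2_effect")["t_test_difference"].mean().round(2))
```

```
true_log2_effect
0.0    0.07
5.0    5.12
Name: t_test_difference, dtype: float64
```

The stratum means of the *t*-test difference recover the simulated effects.

A CLI mirrors the library: `stavquant simulate`, `quantify-granules`,
`quantify-signal`, `accessibility` and `proteomics-map` (see `--help`).
Stacks travel as TIFF + JSON sidecar (calibration, channel labels, ground
truth); LFQ tables as TSV with a YAML sample→group map.

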