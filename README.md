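# radbio

Radiobiological evaluation of lung-SBRT treatment plans at the
dose-volume-histogram (DVH) level: linear-quadratic fractionation
correction (EQD2), Poisson-LQ tumor control probability (TCP),
Lyman-Kutcher-Burman (LKB) and relative-seriality normal-tissue
complication probability (NTCP), normal-tissue dose-constraint checking,
and paired-plan cohort statistics — plus a seeded synthetic-cohort
generator so the whole pipeline can be exercised without any patient data.

The package is aimed at medical-physics researchers who want to quantify
what a difference between two dose calculations of the *same* plan (for
example a convolution-superposition reference calculation and a
Boltzmann-solver recalculation) means in terms of predicted tumor control
and normal-tissue complications, rather than in raw dose metrics alone.

## Models

All responses are evaluated on the equivalent dose in 2-Gy fractions,

```
EQD2 = D · (1 + d/(α/β)) / (1 + 2/(α/β)),
```

with `D` the cumulative dose and `d` the dose per fraction (each DVH bin
is assumed delivered evenly over all fractions, so `d_i = D_i / n`).

**TCP** uses the Poisson-LQ (Källman) dose response

```
P(D) = 2^(−exp(e·γ·(1 − D/D₅₀)))
```

(`P(D₅₀) = ½` exactly; `γ` is the normalized dose-response gradient),
aggregated over the DVH by the voxel-independence product
`TCP = Π_i P(D_i)^{v_i}`.

**NTCP** is computed either with the LKB model,
`NTCP = Φ((EUD − D₅₀)/(m·D₅₀))` with the generalized equivalent uniform
dose `EUD = (Σ_i v_i·D_i^{1/n})^n`, or with the relative-seriality model
`NTCP = [1 − Π_i (1 − P(D_i)^s)^{v_i}]^{1/s}`.

Published parameter sets (three tumor dose-response fits; three lung
pneumonitis LKB fits at two α/β ratios; esophagus and heart LKB;
spinal-cord and esophagus relative-seriality) ship in a versioned YAML
registry addressed by citation label, e.g. `tcp.martel_30mo` or
`lung_lkb.seppenwoolde_ab1.3`.

## Worked example

Generate the default 28-patient paired cohort (19 peripheral / 9 central
tumors, 60 Gy in 5 fractions prescribed to D95% of the PTV, per-location
D95% degradations drawn from the published ranges), evaluate both plans of
every patient, and summarise the paired differences:

```python
from radbio import CohortSpec, generate_cohort, eqd2
from radbio.pipeline import default_parameter_selection, evaluate_patients, compare_cohort
from radbio.cohort import cohort_summary, delta_vs_covariate

spec = CohortSpec(seed=42)
patients = generate_cohort(spec)
tcp_sets, ntcp_sets = default_parameter_selection(
    tcp_labels=["martel_30mo"], ntcp_labels=["lung_lkb.seppenwoolde_ab1.3"])
records = evaluate_patients(patients, spec.scheme, tcp_sets, ntcp_sets)
comps = compare_cohort(records)
print(cohort_summary(comps))
trend = delta_vs_covariate(comps, "d_tcp:martel_30mo", "d_d95_gy",
                           n_permutations=2000, seed=42)
print(f"Spearman rho(dTCP, dD95) = {trend['rho']:.3f}  (perm. p = {trend['p_value']:.4g})")
print(f"EQD2(6.5 Gy @ 12 Gy/fx, a/b=10) = {eqd2(6.5, 12, 10):.2f} Gy")
```

which prints (abridged):

```
  location                             metric  n    median       min      max
peripheral                           d_d95_gy 19  3.464415  0.450612 6.418698
peripheral                  d_tcp:martel_30mo 19  0.079663  0.007621 0.168631
peripheral d_ntcp:lung_lkb.seppenwoolde_ab1.3 19 -0.000008 -0.001125 0.001739
   central                           d_d95_gy  9  3.039678  0.731706 4.266008
   central                  d_tcp:martel_30mo  9  0.063108  0.012410 0.091682
   central d_ntcp:lung_lkb.seppenwoolde_ab1.3  9  0.000494 -0.000407 0.000981
Spearman rho(dTCP, dD95) = 0.983  (perm. p = 0.0004998)
EQD2(6.5 Gy @ 12 Gy/fx, a/b=10) = 11.92 Gy
```

Reading the output: the recalculated plans cover the PTV less well (median
D95% difference of a few Gy, by construction drawn from the configured
ranges), which translates into a strictly positive median TCP loss under
the 30-month local-control parameter set and a strong positive rank
correlation between TCP loss and coverage loss — while the lung
pneumonitis NTCP barely moves (|ΔNTCP| well below 1 %), since the small
multiplicative perturbation of the lung DVH sits on the flat low-dose part
of the LKB response.

The same pipeline is available from the shell:

```sh
radbio simulate --n 28 --seed 42 --out cohort/
radbio compare --manifest cohort/manifest.csv --out results/
radbio report  --evaluations results/ --out results2/   # identical report
```

`compare` writes tidy `deltas.csv` / `summary.csv`, per-plan
`evaluations.csv`, the normal-tissue `constraints.csv` and a plain-text
`report.txt` with per-location medians, ranges and Kruskal-Wallis
p-values.

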