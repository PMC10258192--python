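# crowdscope

Ratiometric FRET crowding-sensor analysis for membraneless organelles.

Many nuclear bodies — heterochromatin foci, nuclear speckles — form by
phase separation, but "phase separation" hides two very different
assembly routes. A genetically encoded FRET crowding sensor
(CFP–linker–YFP; compression of the linker raises FRET, so the YFP/CFP
emission ratio reads out local macromolecular crowding) can tell them
apart when fused to a condensate protein:

* **aggregation** — small oligomers concentrate into the condensate and
  raise the local crowding: the *dense phase* (brightest YFP pixels) has
  a higher emission ratio than the *dilute phase* (dimmest pixels).
  Heterochromatin protein HP1α behaves this way.
* **consolidation** — pre-formed large polymers join up without raising
  local crowding: the dense phase is bright but *not* more crowded.
  Splicing factor SRSF2 (nuclear speckles) behaves this way.

`crowdscope` implements the full analysis as a tested pipeline for
people doing quantitative condensate imaging:

1. **synthetic_scenes** — ground-truth-labeled simulation of
   sensor-expressing cells (two-channel rendering with photon/read
   noise), FRAP traces and crowder-titration series, so every stage is
   testable without microscope data;
2. **ratiometric** — validity-masked YFP/CFP ratio images, control-group
   normalization, color-coded panels;
3. **phase_split** — the dense/dilute splitting procedure (intensity
   rank selection inside the cell), per-phase ratio measurement, line
   profiles;
4. **assembly_call** — mean ± SEM group summaries, the paired
   dense-vs-dilute test and the aggregation/consolidation verdict;
5. **frap_dynamics** — FRAP normalization, single-exponential recovery
   fits (mobile fraction F_m, time constant τ), mobility contrasts;
6. **calibration** — emission-spectrum band ratios, hyperbolic titration
   fits R(c) = R₀ + ΔR·c/(c + K_c), sensor-sensitivity ranking, linker
   screens, and assembly-mass → copy-number stoichiometry;
7. **pipeline_io** — TIFF/CSV formats, configs, the end-to-end runner
   and the seeded fixture generator, plus the `crowdscope` CLI.

## The model in brief

Per pixel with sensor concentration C and crowding c ∈ [0, 1]:

    E(c)     = E_min + (E_max − E_min) · c / (c + K_half)      (FRET efficiency)
    donor    = C · (1 − E)
    acceptor = γ · C · E + crosstalk · donor + background

so the background-subtracted emission ratio is R = γE/(1−E) + crosstalk,
strictly increasing in crowding. FRAP recovery is reaction-limited:
I(t) = I_post + F_m (1 − I_post)(1 − e^−(t−t_bleach)/τ) on a
pre-bleach-normalized trace. The verdict is *aggregation* iff the paired
one-sided Wilcoxon test (dense > dilute) is significant at α **and** the
mean paired normalized-ratio difference exceeds a minimal effect
(default 0.02); otherwise *consolidation*. See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

Classify two simulated 20-cell experiments (library API):

```python
from crowdscope import pipeline_io as pio
from crowdscope.assembly_call import classify_assembly_mode

for cond, name in ((pio.HP1A_LIKE, "HP1a-like"), (pio.SRSF2_LIKE, "SRSF2-like")):
    norm, _ = pio.simulate_experiment_measurements(cond, 20, seed=7)
    call = classify_assembly_mode(norm, seed=7)
    print(f"{name}: mode={call.mode} effect={call.effect_size:+.4f} "
          f"CI95=({call.ci_95[0]:+.4f}, {call.ci_95[1]:+.4f}) "
          f"p={call.p_value:.2e} n={call.n_cells}")
```

prints

```
HP1a-like: mode=aggregation effect=+0.0769 CI95=(+0.0688, +0.0850) p=9.54e-07 n=20
SRSF2-like: mode=consolidation effect=-0.0076 CI95=(-0.0148, -0.0001) p=9.59e-01 n=20
```

The HP1α-like condition (ground-truth crowding 0.38 inside condensates
vs 0.30 outside → ~0.10 normalized ratio contrast) is called
aggregation with a measured dense−dilute effect of +0.077 (boundary
pixels attenuate the 0.10 truth slightly); the SRSF2-like condition
(equal crowding) shows no positive contrast and stays consolidation.

From the shell:

```console
$ crowdscope simulate frap --mobile-fraction 0.5 --tau 30 --n-traces 3 --seed 1 --out traces.csv
$ crowdscope frap --in traces.csv
cell_id       Fm     tau_s  half_time_s     rmse
cell_00 0.495957 29.406428    20.382983 0.018764
cell_01 0.498394 30.382603    21.059616 0.020363
cell_02 0.501519 30.088617    20.855840 0.019849
$ crowdscope stoich --assembly-kda 2.9e5 --monomer-kda 58
copy number: 5000.00 (~5000)
```

The FRAP fits recover the generating mobile fraction (0.5) and time
constant (30 s) to within ~2%; the stoichiometry call turns a
2.9 × 10⁵ kDa polymer of 58 kDa fusion monomers into ~5000 copies per
assembly unit. Other subcommands: `simulate scene|titration`, `ratio`,
`split`, `titrate`, `linker-screen`, `classify`, `run`, `fixtures`.

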