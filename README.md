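# gctherm

Growth-temperature thermometry of archaeal communities from 16S rRNA clone
libraries.

## The problem

Deep anoxic aquifers (for example those hosted in accretionary-prism
sandstones) are sampled through wells, and the microbes recovered at the
outflow carry a thermal signature: the guanine-plus-cytosine content of
archaeal 16S rRNA genes (*P*<sub>G+C</sub>, in percent of unambiguous
bases) correlates tightly with growth temperature. Linear regressions
calibrated on cultured and uncultured archaea map *P*<sub>G+C</sub> to the
minimum, optimal and maximum growth temperature:

```
T_min = 3.91(±0.12)·P_G+C − 201.1(±7.34)
T_opt = 4.24(±0.13)·P_G+C − 202.5(±7.62)
T_max = 4.28(±0.12)·P_G+C − 195.3(±7.11)      (°C)
```

Given a clone library — 70–90 individually sequenced archaeal 16S
amplicons from one groundwater sample — the workflow is:

1. **trim** each clone to the region strictly between the archaeal primer
   sites (IUPAC-aware, substitution-only matching, orientation
   auto-detected);
2. **cluster** the trimmed sequences into OTUs at >97% global-alignment
   identity (greedy centroid, deterministic);
3. **thermometry**: per-OTU *P*<sub>G+C</sub> and temperatures, then
   community temperatures from the clone-count-weighted mean
   *P*<sub>G+C</sub>, `Σ count_i·P_i / Σ count_i`, with worst-case linear
   propagation of the coefficient half-widths;
4. **diversity**: coverage (1 − *n*/*N*), Chao1, ACE, Shannon, Simpson;
5. **geostats**: exact-permutation Spearman trend tests for the
   groundwater time series (n = 5 sampling dates), deuterium excess
   relative to the global meteoric water line, and conservative seawater
   mixing fractions.

Everything is testable offline: `gctherm.synthetic_data` generates clone
libraries with exactly planted *P*<sub>G+C</sub>, abundances and primer
sites, so the whole pipeline can be verified against known truth.

## Worked example

The per-OTU clone table of the groundwater study (five sampling dates,
0–26 months after pumping started) ships in `gctherm.datasets`. Math-only
"table mode" reproduces the published growth-temperature table:

```python
from gctherm import datasets, run_table_mode
from gctherm.thermometry import round_half_up

report = run_table_mode(datasets.clone_table("0 months"), label="0 months")
print(round_half_up(report.weighted_pgc))
for which, est in report.community.items():
    print(which, str(est))
```

prints

```
57.0
T_min 21.6(±14.2)
T_opt 39.0(±15.0)
T_max 48.5(±13.9)
```

i.e. the dominant-methanogen community sampled at month 0 has an
estimated optimal growth temperature of 39 °C, well below the ~51 °C
outflow water — while by 19 months the *Archaeoglobus*-dominated
community reaches T_opt 47.8(±15.1) °C, matching the measured groundwater
temperature, and T_max ≈ 57 °C, inside the 55–63 °C deep-aquifer window.

The full sequence pipeline is the same code fed FASTA:

```bash
gctherm simulate --out-dir scratch/demo --seed 7
gctherm run --fasta "0 months" scratch/demo/library_0_months.fasta --out-dir results/demo
```

## Analysis scripts

`analysis/01_simulate.py` … `05_geostats.py` are thin numbered drivers
that regenerate the synthetic study (five time points with planted
truth), trim/cluster it, recompute the published clone table cell by
cell, tabulate diversity, and run the groundwater trend statistics.
Bulky regenerable FASTAs go under `scratch/`; tables land in `results/`.

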