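# dnaakit

Tools for studying how the bacterial replication initiator **DnaA** is
distributed — on the chromosome and inside the cell.

DnaA triggers chromosome replication at *oriC*, and its activity is buffered
by *titration*: hundreds of 9-bp DnaA boxes scattered over the chromosome
sequester the protein. `dnaakit` implements, as a tested reusable pipeline,
the two computational pillars of that analysis:

1. **Chromosomal DnaA-box density** — scan a circular replicon for exact
   matches to degenerate box motifs (consensus `TTWTNCACA` plus the relaxed
   *datA*/*DARS* class `HHMTHCWVH`) on both strands, map them to centisome
   coordinates anchored at *oriC*, and test positional enrichment against a
   uniform-position null and a motif-permutation null (1000 replicates each,
   one-sided rank pseudo p-values), with a circular von Mises kernel density
   standardised to Z-scores for locating density maxima.
2. **MC-DDA diffusion kinetics** — estimate DnaA's chromosome-binding
   kinetics from single-particle tracks. Apparent diffusion coefficients
   D\* = ⟨‖Δr‖²⟩/(4 Δt) per track are collected into an 85-bin log histogram
   (0.04–10 µm²/s) and fitted by Monte-Carlo diffusion distribution analysis:
   particles switching between a free state (D\_free = 2.7 µm²/s) and an
   immobile bound state with rates k\_F→B, k\_B→F are forward-simulated in a
   spherocylindrical cell under stroboscopic observation (10 ms frames,
   0.1 ms sub-steps, σ\_loc = 0.035 µm), and the rates are adjusted by
   Levenberg–Marquardt least squares between measured and simulated bin
   fractions. The stationary bound fraction is k\_F→B/(k\_F→B + k\_B→F).

Supporting modules cover localisation ingestion and track linking
(`tracking`), per-cell mobility-vs-area profiles and spherocylinder
geometry (`cellcycle`), run-out flow-cytometry origin statistics
(`flowcyto`), and ground-truth synthetic data generators (`synth`).

## Worked example

Fit two-state kinetics to a diffusion histogram (here generated by the
simulator itself at k\_F→B = 186 s⁻¹, k\_B→F = 62 s⁻¹, i.e. a 75% bound
fraction):

```python
from dnaakit import TwoStateModel, DiffusionKineticsModel, render_histogram

data = render_histogram(TwoStateModel(k_fb=186.0, k_bf=62.0),
                        n_particles=250_000, seed=11)
res = DiffusionKineticsModel(data, n_particles_fit=50_000, seed=7).fit()
print(res.summary())
```

```
MC-DDA two-state kinetic fit
============================================================
data: 172991 tracks in 85 log bins [0.04, 10] um^2/s
fixed: D_free = 2.7 um^2/s, sigma = 0.035 um, t_frame = 10 ms, t_step = 0.1 ms
simulated particles per evaluation: 50000, seed 7
------------------------------------------------------------
k_free->bound :    178.55 +/-    3.92 1/s (95% CI)
k_bound->free :     60.15 +/-    0.98 1/s (95% CI)
bound fraction:   74.8 +/-  0.2 %
mean bound time:   16.6 ms
residual norm: 5.140e-03   (converged, 8 evaluations)
```

The fit recovers the generating bound fraction (74.8% vs 75%) and a mean
bound dwell time 1/k\_B→F of ~16 ms.

Box-density analysis of a synthetic 100-kb circular genome with 100 boxes
planted around the origin:

```python
from dnaakit import BoxDensityModel
from dnaakit.synth import gen_genome

genome, truth = gen_genome(seed=42)   # boxes concentrated at centisome 0
res = BoxDensityModel(genome, window_cs=10).fit(nulls=("uniform",),
                                                n_sims=1000, seed=1)
print(res.summary())
```

```
DnaA box density analysis
============================================================
replicon: synthetic_42  (L = 100,000 bp, ori @ 0)
motifs:   TTWTNCACA, HHMTHCWVH
matches:  845 unique (position,strand) sites
window:   10 cs, step 1 cs
uniform null (n=1000): significant regions (pseudo-p < 0.05): [94,6]
KDE global maximum: 99.9 cs (Z = 4.71, 0.1 cs from oriC)
```

The 845 sites are the 100 planted boxes plus accidental background matches;
the enrichment test flags the wrap-merged region from centisome 94 to 6 and
the kernel density peaks 0.1 cs from the origin. For real data, use
`BoxDensityModel.from_fasta(path, ori_position=...)` with a DoriC origin
coordinate.

A `dnaakit` command-line tool exposes the same pipelines
(`dnaakit boxscan|boxdensity|boxkde|track|histo|mcdda|cellcycle|flowcyto|synth`);
see `dnaakit --help`.

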