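# csmtsim

Quantitative MRI promises tissue parameters — the relaxation times T1 and
T2 — that are comparable across scanners and sites. In practice,
variable-flip-angle (VFA) relaxometry delivers systematically different
values depending on the scanner vendor and on the particular set of flip
angles acquired. A major culprit is magnetization transfer (MT): brain
tissue contains a semisolid proton pool that is partially saturated by RF
power, and because every VFA measurement uses a different pulse amplitude,
each one probes the two-pool system under different saturation. A fitted
single-pool model then absorbs the inconsistency as protocol- and
vendor-dependent T1/T2 biases.

`csmtsim` is a desk-scale simulation and analysis pipeline for this
problem, aimed at qMRI methods researchers. It provides:

* **Steady-state signal models** — single-pool SPGR (Ernst) and balanced
  SSFP closed forms, an isochromat simulator for quadratic RF spoiling
  (φₙ = φ₀·n(n+1)/2), and binary spin-bath two-pool MT versions of both
  sequences, with bound-pool saturation rate
  W = π γ² B₁ᵣₘₛ² G(Δ, T2b) under a super-Lorentzian lineshape.
* **Constant-power multiband pulse design (CSMT)** — a 3-band pulse
  (Gaussian base, symmetric ±6 kHz saturation bands) solved so that every
  flip angle is delivered at the same RMS B1 over TR (1.6 µT target),
  making the bound-pool saturation independent of the flip angle.
* **A digital phantom** — nested-ellipsoid WM/GM/CSF geometry on a 1-mm
  grid, two-pool tissue parameters, smooth B1/B0 field maps, three vendor
  RF profiles (hard 0.3 ms / hard 0.1 ms / shaped 1.6 ms excitation with
  native quadratic spoiling increments 150°/50°/115°), Rician noise, and
  test/retest replicates. Protocol: TR/TE 7.0/3.5 ms, SPGR at 3/7/11/15°,
  bSSFP at 5/25/45° (180° phase cycle) plus 45° (0° cycle).
* **Joint system relaxometry (JSR)** — simultaneous nonlinear fitting of
  all SPGR and bSSFP magnitudes of a flip-angle subset for (M0, T1, T2,
  Δf), with DESPOT1 initialization and off-resonance multistart; both a
  per-voxel scipy route and a vectorized batched solver for whole volumes.
* **Variability statistics** — WM-mask erosion, distribution medians,
  pairwise variability 100·(mᵢ−mⱼ)/(0.5·(mᵢ+mⱼ)), deviations from the
  grand mean, worst-case variability, and voxelwise cross-vendor and
  test/retest distributions, across the three acquisition conditions
  (native, harmonized 50° spoiling, CSMT).

## Worked example

```python
from csmtsim import StudyConfig, run_study

cfg = StudyConfig(seed=1, shape=(48, 48, 48), fit_subsample=600,
                  conditions=("native", "harmonized_spoiling", "csmt"))
report = run_study(cfg)
print(report.worst_case[report.worst_case.parameter == "t1"])
```

```
              condition parameter        grouping      value
0                  csmt        t1  cross_protocol   2.520245
1                  csmt        t1    cross_vendor   0.629542
2                  csmt        t1          global   2.681475
6   harmonized_spoiling        t1  cross_protocol  45.427142
7   harmonized_spoiling        t1    cross_vendor  35.624573
8   harmonized_spoiling        t1          global  45.427142
12               native        t1  cross_protocol  45.427142
13               native        t1    cross_vendor  35.776769
14               native        t1          global  45.427142
```

Reading the table: with native vendor pulses the WM-median T1 changes by up
to ~45% depending on which flip-angle subset is fitted (cross-protocol) and
by ~36% between vendors on the same subset (cross-vendor). Harmonizing the
RF-spoiling increment alone barely helps, because the MT saturation is
still uncontrolled. Under CSMT pulses — same saturation power at every flip
angle — the same statistics collapse to ~2.5% and ~0.6%: the single-pool
model has become self-consistent, so protocol and vendor choices no longer
move the estimate.

The same pipeline is scriptable from the shell:

```bash
csmtsim simulate --config study.yaml --out data/
csmtsim fit      --data data/ --subset S1 --out maps/
csmtsim analyze  --maps maps/ --out analysis/
csmtsim report   --analysis analysis/ --out figures/
```

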