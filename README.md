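# pcmassembly

Tools for quantifying how a coiled-coil heterotetramer (the Cep63•Cep152
"building block" of the pericentriolar material) self-assembles into
higher-order cylindrical structures. The package covers three linked
analyses, plus the synthetic-data generators needed to exercise them end to
end:

1. **`thermo`** — a square-lattice mass-action model of tetramer
   self-association and its classical-nucleation thermodynamics;
2. **`sedeq`** — forward simulation and global fitting of multi-speed,
   multi-loading sedimentation-equilibrium absorbance data under reversible
   self-association models, with F-statistic confidence limits and model
   comparison;
3. **`minflux`** — a MINFLUX single-molecule localization pipeline: trace
   filtering, photon-weighted collapse, precision estimation, least-squares
   circle fitting, cylindrical-shell statistics (Tukey-whisker outlier
   exclusion, 5th–95th percentile geometry, in-shell molar concentration),
   density rendering, and labeling/undercounting control arithmetic;
4. **`synthdata`** — seed-deterministic generators for molecules on a hollow
   cylinder, blinking localization traces with background, equilibrium
   absorbance datasets, and mass-photometry-style particle-mass samples;
5. **`cli`** — a `pcmassembly` console command orchestrating the stages with
   YAML configs and provenance-stamped outputs.

## The model at the core

The heterotetramer is treated as a square lattice unit whose faces bind
neighbours with contact free energy ε (kBT units). Two measured dissociation
constants anchor the model:

    k8  = c4²/c8  = c0·e^ε        (octamer ⇌ 2 tetramers, M)
    k16 = c4⁴/c16 = c0³·e^{4ε}    (hexadecamer ⇌ 4 tetramers, M³)

giving closed-form ε = ln(k8/c0) and c0 = k8⁴/k16. From these follow the
concentration of any assembly (e.g. the dodecamer, c12 = c4³/k8², which
carries two contacts), the saturation concentration for macroscopic lattice
growth c_sat = c0·e^{2ε}, and the free energy of square L×L assemblies

    G(L) = 2L(L−1)·ε − L²·ln(c4/c0)   [kBT],

whose maximum over integer L is the critical nucleus and nucleation barrier.

At sedimentation equilibrium each species obeys
c_i(r) = c_i(r0)·exp[M_i(1−v̄ρ)ω²(r²−r0²)/(2RT)]; the global fitter
estimates log₁₀ K's across speeds/loadings/wavelengths with per-cell
baselines and the 250 nm extinction profiled out linearly, and scans each K
against the F-statistic χ² threshold for 68 % confidence limits.

## Worked example

```bash
pcmassembly thermo --out thermo.json
```

prints

```
{"epsilon_kBT": -5.128971263276473, "c0_M": 0.06247203333333333,
 "c_sat_M": 2.1913805697589466e-06, "octamer_octamer_kd_M": 2.1913805697589483e-06}
```

i.e. from k8 = 370 μM and k16 = 3.0×10⁻¹³ M³ the contact energy is
ε ≈ −5.13 kBT and the reference concentration c0 ≈ 62.5 mM; the saturation
concentration c0·e^{2ε} ≈ 2.2 μM equals the stepwise octamer–octamer K_d
(k16/k8²) by algebraic identity. The full JSON report also contains, per
loading, the equilibrium tetramer/octamer/hexadecamer concentrations and the
trace-level dodecamer (0.011 μM at 12.6 μM total, 0.26 μM at 55 μM), and the
nucleation analysis at 55 μM: critical nucleus L = 2 (a hexadecamer) with a
barrier of ≈10 kBT.

A synthetic MINFLUX run:

```bash
pcmassembly simulate cylinder --n 300 --seed 1 --out mol.csv
pcmassembly simulate traces mol.csv --seed 2 --out loc.csv
pcmassembly minflux run loc.csv --out-dir mf/
```

prints

```
{"n_molecules": 323, "precision_nm": 12.67, "mean_diameter_nm": 392.8,
 "p5p95_width_nm": 99.3, "p5p95_height_nm": 235.5, "concentration_uM": 15.1}
```

— the pipeline filtered sub-5-localization background traces, collapsed the
rest to photon-weighted molecule positions (~13 nm trace precision),
fitted the x–y circle, and recovered the ground-truth hollow cylinder
(384 nm diameter; 5th–95th percentiles span 90 % of the 109 nm wall and
262 nm height) together with an in-shell concentration in the ~15 μM range
expected for ~300 molecules in that shell volume.

The labeling control:

```bash
pcmassembly minflux nup-control
# {"label_fraction": 0.2109, "single_trace_fraction": 0.9555,
#  "expected_traces": 85, "overcount_fraction": 0.0941}
```

81 labeled clusters over 24×16 labelable dimers gives a 21 % labeling
fraction, hence 95.5 % single-trace clusters, 85 expected traces, and a 9 %
overcount against the 93 observed.

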