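# archkit

Inter-module geometry, small-angle X-ray scattering (SAXS) modeling and
hybrid NOE + SAXS refinement for beads-on-a-string multidomain proteins.

Many extracellular regulators — the canonical example being complement
factor H, a chain of twenty ~60-residue complement control protein (CCP)
modules joined by 3–8-residue linkers — derive their function from how
consecutive modules are oriented: tilted back on themselves, twisted, rigid
or flexible. `archkit` implements the integrative toolkit used to
characterize such architectures from solution data:

- **Junction geometry.** Each module gets an orthonormal frame (long axis z
  from the inertia tensor, oriented N→C; x toward a reference atom). The
  junction between consecutive modules is reported as z–y–z Euler angles of
  the inter-frame rotation R = R_z(skew)·R_y(tilt)·R_z(twist−skew): tilt is
  the deviation from collinear extension, twist the net rotation about the
  long axes.
- **Interfaces.** Deterministic Shrake–Rupley solvent-accessible surface
  area; buried interface area BSA = SA(half_i) + SA(half_j) − SA(both) with
  an extended-boundary residue rule that splits the linker at its midpoint;
  inter-module contacts and salt bridges.
- **Fragment concatenation.** Overlapping bi-module NMR ensembles are joined
  over their shared module (backbone superposition), and their NOE lists are
  merged duplication-free by partitioning at the shared module's sequence
  midpoint.
- **SAXS.** Debye forward curves I(s) = Σ fᵢfⱼ sinc(s·rᵢⱼ) from coordinates;
  Guinier analysis (I(s) = I(0)·exp(−(sR_g)²/3) for s·R_g ≤ 1.3); p(r) by
  histogram and by regularized indirect Fourier transform with D_max;
  Porod volume V_p = 2π²I(0)/Q; molecular mass from I(0) against a 66-kDa
  reference; frame averaging with a radiation-damage screen.
- **Flexibility (EOM-style).** Pools of random conformers with rigid bodies
  and flexible dummy-residue linkers; genetic-algorithm selection of the
  sub-ensemble whose averaged curve fits a target; R_g-distribution
  comparison with a bimodality flag.
- **Hybrid refinement.** Metropolis Monte-Carlo annealing of flexible
  junctions against NOE upper bounds and/or a scattering curve (two-stage
  2000→600→100 cooling schedule with multiplicative weight ramping,
  optionally with N = 2 ensemble-averaged restraint energies), plus NOE
  violation reports with r⁻⁶ ensemble averaging.
- **Synthetic data.** Every input — prolate pseudo-modules, chains with
  prescribed junction angles, noisy curves, contact-derived NOE lists,
  jittered ensembles — can be generated deterministically, so the whole
  pipeline is testable without downloads.

Formats: multi-model PDB (via gemmi), whitespace 2–3-column scattering
curves with `#` comments, CYANA-style `.upl` restraint tables (plus a
generic TSV), and a YAML architecture file naming each module's boundary
cysteines and reference atom.

## Worked example

Build a two-module chain bent by 118° (the geometry of a strongly tilted
CCP pair), then analyse it:

```
$ archkit simulate chain --junction 118,57,89,6 --seed 1 -o chain.pdb
$ archkit angles --pdb chain.pdb --arch chain.pdb.arch.yaml
junction  n  tilt_mean  tilt_sd  twist_mean  twist_sd  skew_mean  skew_sd
M1/M2     1  118.00     0.00     57.00       0.00      89.00      0.00

$ archkit bsa --pdb chain.pdb --arch chain.pdb.arch.yaml
junction  bsa_A2
M1/M2     401.4

$ archkit simulate curve --pdb chain.pdb --rel-noise 0.01 --seed 2 -o exp.dat
$ archkit guinier --dat exp.dat
I0      254074
Rg_nm   1.8298
s_range 0.0500  0.7056
n_points 23

$ archkit pofr --dat exp.dat --dmax 9.0
Rg_nm  1.8334
I0     254389
chi    0.9410

$ archkit simulate noe --pdb chain.pdb --arch chain.pdb.arch.yaml -o noe.upl
$ archkit noe-count --noe noe.upl --arch chain.pdb.arch.yaml
intra             1996
n_module_to_linker   4
c_module_to_linker  11
inter_module         7
...
```

Reading the numbers: the measured junction angles reproduce the prescribed
(118°, 57°, 89°) exactly — chain construction and angle measurement are
mutually inverse. The compact junction buries ~400 Å² between the module
halves and yields a handful (7) of inter-module contacts within NOE range,
the signature of a strongly tilted, surface-burying junction. The Guinier
R_g of the simulated 1%-noise curve (1.830 nm) agrees with the indirect
Fourier transform estimate (1.833 nm) and the IFT's χ ≈ 0.94 shows the
inversion fits the data to within its errors.

The same operations run on deposited NMR ensembles: read a multi-model PDB
and restraint list with `archkit.core.read_structure_ensemble` /
`read_noe_table`, describe the module spans in an architecture YAML, and
apply `angles`, `bsa`, `ensemble-stats`, `noe-count`, `concat`, `noe-merge`,
`eom-pool`/`eom-select` or `refine` unchanged.

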