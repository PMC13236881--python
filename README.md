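# arsbind

Quantitative binding analytics for protein-functionalized particle
adsorbents.  `arsbind` is for experimentalists who immobilize a
metal-binding protein (e.g. an ArsR-family arsenite repressor) on biosilica
microspheres and want rigorous numbers out of the resulting solid-phase
assays: association constants and per-particle site counts from equilibrium
isotherms, rate constants from uptake time courses, immobilized-vs-free
affinity comparisons from competition experiments, and loading/stability/
selectivity metrics — plus a seeded simulator of all of these experiments
for validation and power analysis.

## The core model

Treating each sphere as a molecule (molarity = particle count / N_A), a
receptor with *n* identical independent sites per sphere at sphere molarity
[S] binds ligand M as a 1:1 Langmuir system.  With occupancy
μ = [M]_b/[S] carried in units of 10⁷ sites, the Scatchard linearization

&nbsp;&nbsp;&nbsp;&nbsp;[M]_f/μ = K_D/n + [M]_f/n

turns an isotherm into a straight line with

&nbsp;&nbsp;&nbsp;&nbsp;n = 10⁷/slope (sites per particle), K_A = slope/intercept (10⁶ M⁻¹).

Around this sit the pseudo-first/second-order kinetic linearizations
(ln(Q_e−Q_t) = lnQ_e − kt and t/Q_t = 1/(kQ_e²) + t/Q_e), and the
two-receptor competition identity
[R]_f/[R]_b = ([P]_f/[P]_b)·(K_D1/K_D2), whose slope converts an
immobilized reference affinity into the free protein's affinity.  See
`docs/methods.md` for assumptions, error propagation and numerical details.

## Worked example

Generate the synthetic demonstration bundle and analyse it (the bundle's
isotherm is simulated at K_A = 30.49 × 10⁶ M⁻¹ and n = 2.80 × 10⁷
sites/sphere with 3% multiplicative noise, triplicates):

```bash
arsbind simulate --fixtures --seed 42 -o fx
arsbind scatchard fx/isotherm.csv --suspensions fx/suspensions.csv --label S -o scatchard.csv
arsbind kinetics fx/kinetics.csv -o kinetics.csv
arsbind compete fx/competition.csv --ka-immobilized 30.49 -o competition.csv
arsbind selectivity --loading fx/loading.csv --interference fx/interference.csv -o .
arsbind annotate fx/synthetic_sequences.fasta -o cysteines.csv
```

which prints:

```
y = 0.3625x + 0.0126  K_A = 28.73 x1e6 M^-1, n = 2.759 x1e7 (R^2 0.9998)
selected PSO: t/Qt = 0.008992 + 0.01357 t (R^2 0.9987)
K_D1/K_D2 = 1.0182 (R^2 0.9992); K_A,free = 31.04 x1e6 M^-1 (1.79% deviation)
loading capacity: 2.733e+07 molecules/sphere (R^2 1.0000)
S/Cu: 78.7% (not retained)
conjugate-1/Cu: 99.2% (retained)
conjugate-2/Cu: 99.6% (retained)
conjugate-8/Cu: 94.5% (not retained)
synthetic_repressor_5C: 5 Cys at [91, 92, 99, 109, 110]
```

Reading the output: the noisy isotherm recovers the generating affinity to
within ~6% of its K_A (28.73 vs 30.49 × 10⁶ M⁻¹) and the site count to ~1.5%;
the uptake series is correctly classified pseudo-second-order; the
equal-affinity competition experiment reports a K_D ratio near 1, i.e. an
immobilized-vs-free affinity deviation under 2%; the loading regression
reads 2.733 × 10⁷ protein molecules per sphere off its slope; and an
adsorbent retaining only 78.7% of its control adsorption under a competing
metal falls below the 95% selectivity threshold.

The same analyses are available as library calls (`affinity_from_isotherm`,
`fit_pseudo_second_order`, `fit_affinity_ratio`, `fit_loading_capacity`,
`retention`, ...), and `arsbind report config.yaml` runs a configured
simulate-and-analyse pipeline with byte-reproducible outputs.

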