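# sopquant

Quantification of cortical polarity crescents and asymmetric cell division
outcomes in *Drosophila* sensory organ precursor (SOP) cells.

During the asymmetric division of an SOP (pI) cell, polarity proteins and
fate determinants (Bazooka/Par3, Pins, Partner of Numb) accumulate in
cortical *crescents* — asymmetric arcs along the cell perimeter — and the
mitotic spindle aligns with the anterior–posterior (A–P) body axis. Loss of
planar polarity regulators blurs the crescents, randomizes the division
angle, and mis-segregates determinants into both daughters. `sopquant`
provides the measurement layer for such experiments: it turns fluorescence
micrographs (or pre-extracted cortical intensity profiles) into harmonic
polarity statistics, division-angle and segregation summaries, and exact
group-comparison tests, with a seeded synthetic-data generator standing in
for microscopy inputs.

## The statistics

Let grey values I₁…I_N be sampled at N equally spaced positions along the
cell outline, each divided by their mean. The **polarization coefficient**

    P = √(a² + b²),   a = (1/N) Σₖ Iₖ cos(2πk/N),   b = (1/N) Σₖ Iₖ sin(2πk/N)

is the magnitude of the first circular harmonic: 0 for a uniform cortical
distribution, approaching 1 as the signal concentrates at a single point. It
detects unipolar crescents (Pon, Baz, Pins). The **nematic order parameter**

    S = √(c² + d²),   c = (1/N) Σₖ Iₖ cos(4πk/N),   d = (1/N) Σₖ Iₖ sin(4πk/N)

is the second-harmonic magnitude, 0 for uniform, sensitive to bipolar
(180°-periodic) patterns such as junctional Fz-GFP that P misses by symmetry.

Per division, the **segregation ratio** is min/max of the two daughter-cell
reporter intensities (1 = symmetric inheritance) and the **division angle**
is the signed angle between the A–P axis and the daughter–daughter axis
(clockwise positive in the viewer's frame, (−180°, 180°]). Genotypes are
compared with an exact Mann–Whitney test (full enumeration for small untied
samples) for continuous scores, and with the Freeman–Halton extension of
Fisher's exact test for r×c tables of bristle-defect categories.

## Worked example

Two synthetic genotypes of n = 60 divisions each: a control with tight
crescents (concentration κ = 4) and well-aligned divisions (angle SD 35°),
and a mutant with weak crescents (κ = 0.5) and dispersed angles (SD 68°).

```python
import numpy as np
from sopquant import (DivisionPopulationSpec, angle_dispersion, division_angle,
                      generate_division_population, generate_population_profiles,
                      mann_whitney, polarization_coefficient, segregation_ratio)

control = DivisionPopulationSpec(n_cells=60, angle_sd=35.0, polarization_kappa=4.0,
                                 segregation_shape=(2.0, 8.0), seed=1)
mutant = DivisionPopulationSpec(n_cells=60, angle_sd=68.0, polarization_kappa=0.5,
                                segregation_shape=(6.0, 4.0), seed=2)

for name, spec in [("control", control), ("mutant", mutant)]:
    records = generate_division_population(spec)
    P = [polarization_coefficient(p).P for p in generate_population_profiles(spec)]
    ratios = [segregation_ratio(r) for r in records]
    disp = angle_dispersion([division_angle(r) for r in records])
    print(f"{name}: mean P = {np.mean(P):.3f} +- {np.std(P, ddof=1):.3f}, "
          f"mean ratio = {np.mean(ratios):.3f}, angle SD = {disp.sd_arithmetic:.2f} deg")

p_ctrl = [polarization_coefficient(p).P for p in generate_population_profiles(control)]
p_mut = [polarization_coefficient(p).P for p in generate_population_profiles(mutant)]
res = mann_whitney(p_ctrl, p_mut)
print(f"Mann-Whitney on P: U = {res.statistic:.1f}, p = {res.p_value:.3g} ({res.method})")
```

prints

```
control: mean P = 0.583 +- 0.010, mean ratio = 0.192, angle SD = 30.47 deg
mutant: mean P = 0.210 +- 0.003, mean ratio = 0.622, angle SD = 68.38 deg
Mann-Whitney on P: U = 0.0, p = 3.56e-21 (normal-approximation)
```

The mutant population is far less polarized (mean P 0.21 vs 0.58),
segregates the reporter more symmetrically between daughters (ratio 0.62 vs
0.19 — ratios approach 1 for equal segregation), and divides at nearly
random angles (SD ≈ 68° vs ≈ 30°); the Mann–Whitney comparison of the
polarization coefficients separates the genotypes decisively.

The same workflow is available from the shell via the `sopquant` command
(`simulate-image`, `simulate-profiles`, `simulate-divisions`,
`simulate-table`, `extract`, `score`, `divisions`, `compare`), all honoring
`--seed` and writing CSV/JSON outputs.

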