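# colomech

Anisotropic hyperelastic modelling of colorectal tissue from uniaxial
tensile tests.

Colorectal anastomoses — surgical reconnections of the bowel — fail in part
because of how staples interact mechanically with the surrounding tissue.
Simulating that interaction needs a constitutive model of the colorectal
wall, which is strongly anisotropic: much stiffer circumferentially than
longitudinally, with fiber bundles near both axes. `colomech` implements
such a model together with everything needed to calibrate it from uniaxial
tensile experiments on rectangular tissue specimens, and a synthetic-data
generator so the whole chain can be exercised and validated without lab
data.

## The model

The strain energy combines a three-term Yeoh isotropic matrix with two
in-plane fiber families described by polynomials in their squared-stretch
pseudo-invariants:

```
Ψ = Σᵢ₌₁³ aᵢ (Ī₁ − 3)ⁱ  +  Σⱼ₌₂⁴ cⱼ (Ī₄ − 1)ʲ  +  Σₖ₌₂⁴ eₖ (Ī₆ − 1)ᵏ
```

with `Ī₁ = tr C̄`, `Ī₄ = a·C̄a`, `Ī₆ = g·C̄g`, and fiber directions
`a = (cos β₁, sin β₁, 0)`, `g = (cos β₂, sin β₂, 0)` measured from the
circumferential axis. Eleven coefficients in total: `a₁..a₃, c₂..c₄,
e₂..e₄` (Pa) and the angles `β₁, β₂` (degrees).

Under incompressible uniaxial tension (`λ` axial, `λ^(−1/2)` transverse)
the hydrostatic pressure is eliminated through the traction-free
out-of-plane condition, giving the closed-form axial second
Piola–Kirchhoff stress

```
S = S̃_axial − S̃₃₃ λ⁻³,     σ_true = λ² S,     P_eng = λ S
```

where `S̃ = 2 ∂Ψ/∂C̄`. Calibration minimizes the pair of normalized errors

```
E = Σ (σ_exp − σ_model)² / Σ σ_exp²
```

(circumferential `Ec`, longitudinal `Et`) with an NSGA-II genetic
algorithm; the "balanced" solution minimizes `max(Ec, Et)` on the Pareto
front. A published coefficient set for porcine colorectal tissue ships as
a packaged fixture.

The package also implements the two experimental reduction steps: raw
load-record processing (Savitzky–Golay smoothing, zero-phase Butterworth
slope filtering, detection of the post-conditioning onset, normalization
by post-conditioning geometry) and specimen width tracking from video
frames (Otsu binarization, four-edge boundary grouping, per-row minimum
width).

## Worked example

```python
import numpy as np
from colomech import (published_parameters, uniaxial_second_pk,
                      predict_curve, bounds_around, FitConfig,
                      run_moo, select_balanced)
from colomech.synthetic import generate_curves

params = published_parameters()
print(uniaxial_second_pk(params, 1.20, "circ").P_eng)   # 770076.6375...
print(uniaxial_second_pk(params, 1.18, "long").P_eng)   # 150835.5157...
```

The two numbers are engineering stresses in Pa at 20% circumferential and
18% longitudinal strain: the model is roughly five times stiffer around
the bowel than along it, which is why stapled side-to-side anastomoses
(loaded circumferentially) outperform end-to-end ones.

Recovering the coefficients from synthetic noisy data:

```python
circ = generate_curves(params, "circ", 20, noise_cv=0.05, seed=11)
long_ = generate_curves(params, "long", 20, noise_cv=0.05, seed=111)
cfg = FitConfig(population_size=80, generations=100,
                bounds=bounds_around(params), seed=11)
best = select_balanced(run_moo(circ, long_, cfg))
print(best.objectives)  # ObjectivePair(Ec=0.003705..., Et=0.004364...)
```

Both errors land near the 5%-noise floor (`Ec ≈ Et ≈ CV² = 0.0025`),
i.e. the fit recovers the generating curves to within the noise.

The same workflows are available from the shell:

```sh
colomech evaluate --direction circ --strain 0.2
colomech curve --direction long --strain-max 0.2 --n 100 --out long.csv
colomech synth load --direction circ --seed 1 --out load.csv
colomech process --load load.csv --out processed.csv
colomech fit --circ c1.csv --long l1.csv --out pareto.json
```

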