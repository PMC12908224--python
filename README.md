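# stentopt

Response-surface design optimization of a self-expanding nitinol stent for
the femoropopliteal artery (FPA).

## The problem

The FPA runs from thigh to knee and is severely deformed during limb
flexion — axial compression, bending, twisting and pinching are most
extreme at the adductor hiatus.  Stents placed there interact with the
artery wall: poor strut apposition predisposes to thrombosis and
restenosis, while high wall stress (above ~100 kPa in 60–70-year-old FPAs)
drives tissue damage.  A stent geometry must balance four competing
outcomes under flexion:

* mean intramural von Mises stress [kPa] — smaller the better,
* fraction of luminal area with stress > 100 kPa [%] — smaller the better,
* stent-artery apposition (strut area in contact with the wall) [%] — larger the better,
* lumen pinching (max/min diameter ratio, 1.0 = circular) — smaller the better.

The stent is parameterized by five factors: strut width *w* [µm], strut
thickness *t* [µm], number of struts NS (sine half-periods per ring
circumference), link amplitude LA [mm] and strut amplitude SA [mm], with a
fixed 8 mm outer diameter, 7 sine-wave rings, 6 link sets and π/2 mm link
length.  The finite-element simulations that evaluate a design are far too
expensive to embed in an optimizer, so the workflow is the classic RSM
(response surface methodology) loop:

1. **DOE** — a face-centered central composite design (2^k factorial core,
   2k face points, one center point) samples the design box at three
   levels per factor: 43 runs for k = 5, 15 runs for the refined k = 3
   space.
2. **Fit** — each response is fitted with a full second-order polynomial
   y = β₀ + Σβᵢxᵢ + Σβᵢᵢxᵢ² + Σβᵢⱼxᵢxⱼ + ε by OLS.
3. **Screen** — terms with |t| ≤ t_crit (two-tailed, α = 0.05) are dropped
   (weak heredity enforced) and the reduced model refitted.
4. **Optimize** — each predicted response is mapped to a desirability
   d_j ∈ [0, 1] (piecewise-linear, STB or LTB) and the composite
   D = Π d_j is maximized over the box (dense grid + local polish).
5. **Sensitivity** — midpoint partial derivatives, normalized by factor
   ranges, give each factor's percentage contribution per response.
6. **Fatigue** — per-element strain clouds (mean strain vs strain
   amplitude) are screened against nitinol limits (0.4 % amplitude for
   generation-I material, 2 % for generation III).

The two DOE response tables produced by the original finite-element study
are packaged as CSV fixtures; a quadratic surrogate with configurable
noise stands in for the FEA stage so every pipeline step can be exercised
end to end.  The FEA itself (artery constitutive model, crimp/deploy,
flexion boundary conditions) is out of scope — its outputs are consumed
as data.

## Worked example

```python
from stentopt import (RESPONSES, TABLE1_SPACE, StentDesign, fit,
                      load_table4, optimize_designs)
from stentopt.rsm import eq5_terms

table = load_table4()                       # 43-run DOE over 5 factors
models = {m.key: fit(table, m.key, eq5_terms()) for m in RESPONSES}
for key, m in models.items():
    print(key, round(m.r_squared, 4))

best = optimize_designs(models, TABLE1_SPACE, grid=21)
print(best.design.as_dict(), round(best.composite_d, 4))
```

prints

```
mean_stress 0.989
high_stress_area 0.9784
apposition 0.9686
pinching 0.9598
{'w': 100.0, 't': 100.0, 'NS': 16.0, 'LA': 0.0, 'SA': 0.5} 0.4598
```

i.e. the ten-term reduced models explain ≥ 96 % of the variance of every
response, and the equal-weight desirability optimum sits at the smallest
strut cross-section (w = t = 100 µm), the fewest struts (NS = 16) and the
lowest strut amplitude (SA = 0.5 mm).  The composite desirability carries
no LA term, so that coordinate is reported but uninformative
(`best.trace["flat_axes"] == ["LA"]`).  Evaluating the same models at the
optimum predicts ≈ 98.1 % apposition, ≈ 0.0 % high-stress area,
≈ 28.5 kPa mean stress and ≈ 1.19 pinching.

The numbered drivers under `analysis/` run the full story — DOE
generation and orthogonality (01), model fitting for both DOE tables
(02), optimization and sensitivity (03), fatigue screening of synthetic
strain clouds (04) and surrogate recovery checks (05) — writing their
tables under `results/`.  The same pipeline is scriptable via the
`stentopt` CLI (`stentopt run --config <yaml>`; shipped configs:
`doe1.yaml`, `doe2.yaml`).

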