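# killfrac

Mechanistic prediction of chemotherapy-induced tumor kill from measurable
physiology.

Whether a tumor responds to chemotherapy depends not only on how sensitive
its cells are to the drug, but on whether the drug physically reaches them.
`killfrac` implements a closed-form diffusion–uptake model that predicts the
fraction of tumor volume killed by a drug administration from four
parameters measurable in histology and cell culture, and provides the
surrounding analysis pipeline: extracting the parameters from tabulated
immunohistochemistry (IHC) measurements, calibrating the model to
per-section kill data from drug-sensitive and drug-resistant murine
lymphomas, and ranking the parameters by local sensitivity analysis. A
synthetic-data generator reproduces the statistical structure of the study
design so every stage is testable without any external data.

## The model

Each blood vessel is a straight cylinder of radius `r_b` feeding a
Krogh-type tissue cylinder of radius `r_t = r_b / √BVF`, where BVF is the
blood volume fraction. After extravasation the drug concentration σ obeys a
steady-state diffusion–uptake balance; with the radial coordinate scaled by
the penetration distance `L = √(D/λ)` (D drug diffusivity, λ cellular
uptake rate),

    σ(r)/σ₀ = K₀(r) / K₀(r̂_b),        r̂_b = r_b / L,

with K₀ the modified Bessel function of the second kind. Averaging this
profile over the tissue annulus and scaling by the in-vitro kill fraction
`f_kill^M` gives the fraction of tumor volume killed in closed form:

    f_kill = f_kill^M · BVF · [2·√BVF·K₁(r̂_b) − 2·K₁(r̂_b/√BVF)]
             ─────────────────────────────────────────────────────
                     √BVF · r̂_b · K₀(r̂_b) · (1 − BVF)

`f_kill` is bounded by `f_kill^M`, strictly increasing in BVF and L, and
strictly decreasing in `r_b`: vascularization and transport, not just
cell-intrinsic chemosensitivity, set the in-vivo response. An independent
adaptive-quadrature oracle verifies the closed form to ≤1e-6 relative error.

## Worked example

```python
from killfrac import ModelParams, kill_fraction, kill_fraction_oracle

params = ModelParams(bvf=0.038, rb_um=5.0, L_um=73.5, fkill_m=0.25)
print(kill_fraction(params))          # 0.146226
print(kill_fraction_oracle(params))   # 0.146226 (quadrature, agrees 6e-16)
```

With 3.8 % blood volume, 5 µm vessels and r_b/L = 0.068, the model predicts
15 % of the tumor killed even though the drug kills 25 % of these cells in
monolayer culture — the transport penalty of sparse vasculature.

Running `python examples/04_calibration.py` calibrates the model to a
synthetic 11-point per-section dataset (5 drug-sensitive + 6 drug-resistant
sections, resistant kill rescaled by the 3.5× in-vitro ratio):

```
noiseless check: fkill_m=0.250000, r_b/L=0.068000, R^2=1.000000
```

i.e. the bounded multistart least-squares fit recovers the generating
parameters exactly in the absence of measurement noise. The other examples
cover histology parameter extraction (`02`, reproducing the ~24× treated vs
untreated necrosis fold change), IC50 fitting (`03`, 46.2 vs 3.5 nM → ~13×
differential), sensitivity ranking (`05`) and the end-to-end pipeline
(`06`).

A thin CLI wraps the same library calls:

```
killfrac simulate --seed 1 --out inputs/
killfrac calibrate --data inputs/killdata.csv --rescale-factor 3.5
killfrac sensitivity --bvf 0.038
killfrac run --seed 1 --out results/
```

## Layout

- `src/killfrac/model.py` — concentration profile, closed-form kill
  fraction, quadrature oracle
- `src/killfrac/histology.py` — stain fractions, marker summaries, BVF /
  r_b / L estimation
- `src/killfrac/invitro.py` — 4-parameter-logistic IC50 fits, fold
  differences, kill ratio
- `src/killfrac/calibration.py` — rescaling and bounded multistart
  least-squares calibration
- `src/killfrac/sensitivity.py` — normalized local sensitivity
  coefficients and ranking
- `src/killfrac/synthetic.py` — study-structured synthetic data with
  ground truth
- `src/killfrac/pipeline.py`, `cli.py` — orchestration and command line

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
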