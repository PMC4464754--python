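"""Which parameter matters most for predicted tumor kill?

Computes normalized local sensitivity coefficients of f_kill at the pooled
treated-tumor reference and ranks the parameters.
"""

from killfrac import ModelParams, sensitivity_coefficient, sensitivity_ranking

reference = ModelParams(bvf=0.038, rb_um=5.0, L_um=40.0, fkill_m=0.25)
print("reference:", reference)

print("\ncoefficients at +10% perturbation:")
for p in ("bvf", "rb_um", "L_um", "fkill_m"):
    s = sensitivity_coefficient(reference, p, 0.1).S
    print(f"  S({p:7s}) = {s:+.4f}")

ranking = sensitivity_ranking(reference, ("bvf", "rb_um", "L_um", "fkill_m"))
print("\nranking by mean |S| over +1%, +10%, +25%:")
for p, s in ranking:
    print(f"  {p:7s}: {s:.4f}")

print("\nfkill_m has S = 1 exactly (the model is linear in it); among the")
print("physiological parameters, vascularization (BVF) dominates, then the")
print("vessel radius, then the penetration distance.")
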