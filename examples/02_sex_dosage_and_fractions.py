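"""Estimate sample sex and the three component fractions from ZFX/ZFY dosage.

A plasma sample mixing 72.64% male donor DNA, 18% maternal DNA and 9.36%
male placental DNA carries CN_Y = 0.82 and CN_X = 1.18, i.e. normalized
shares 0.59:0.41. The male fraction is m = 2*y_share; subtracting the
placental fraction gives the donor component.
"""

from cfmix import (
    component_fractions,
    generate_panel,
    infer_sex,
    male_fraction_from_xy,
    simulate_sex_dosage,
    xy_dosage,
)

panel = generate_panel(seed=0)
zfx = [r.region_id for r in panel.zfx]
zfy = [r.region_id for r in panel.zfy]

# a known 46,XX sample calibrates what "two copies of X" looks like in depth
ref = simulate_sex_dosage(panel, ["46,XX"], [1.0], depth=2500, seed=1)
female_ref = ref.loc[zfx, "depth"].mean()

mix = simulate_sex_dosage(
    panel, ["46,XY", "46,XX", "46,XY"], [0.7264, 0.18, 0.0936], depth=2500, seed=2
)
d = xy_dosage(mix.loc[zfx, "depth"], mix.loc[zfy, "depth"], female_ref)
m = male_fraction_from_xy(d)
print(f"X:Y copy numbers {d.cn_x:.3f}:{d.cn_y:.3f}  shares {d.x_share:.3f}:{d.y_share:.3f}")
print(f"male-DNA fraction m = {m:.4f}  sex call: {infer_sex(d).label}")

fr = component_fractions(m, f=0.0936, fetal_sex="XY")
print(f"components  A(donor)={fr.w_a:.4f}  B(maternal)={fr.w_b:.4f}  C(placental)={fr.w_c:.4f}")
# expect shares near 0.59:0.41, m near 0.82 and components near 0.7264/0.18/0.0936
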