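"""Field lure arithmetic: blend doses and solvent-balanced recipes.

The field lures pair a high-(Z)-3 mix against a low one on the same
plant.  Because (Z)-3-hexenal is supplied as a 50% solution in triacetin,
every mix carries solvent with it; the recipes add pure triacetin so both
sides of a comparison release the same solvent background.
"""

from glvchoice.quant import (check_recipe_balance, mixture_component_dose,
                             recipe_solvent_total)

for total, z_pct in [(250.0, 100.0), (250.0, 80.0), (250.0, 50.0),
                     (250.0, 20.0), (250.0, 0.0)]:
    z_ng, e_ng = mixture_component_dose(total, z_pct)
    print(f"{z_pct:5.0f}/{100 - z_pct:<3.0f} blend of {total:.0f} ng -> "
          f"(Z)-3 {z_ng:6.1f} ng, (E)-2 {e_ng:6.1f} ng")

print()
pairs = {
    "1:1 vs 9:1 mixes": [(51.25, 40.95), (92.2, 0.0)],
    "only-(Z)-3 vs only-(E)-2": [(102.5, 0.0), (0.0, 102.5)],
}
for label, recipes in pairs.items():
    totals = [recipe_solvent_total(d, a) for d, a in recipes]
    balanced = check_recipe_balance(totals)
    shown = " vs ".join(f"{t:.1f} ul" for t in totals)
    print(f"{label}: triacetin totals {shown} -> "
          f"{'balanced' if balanced else 'NOT balanced'}")
# Each paired comparison must show equal triacetin totals; an unbalanced
# pair would confound the isomer signal with a solvent-odor difference.
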