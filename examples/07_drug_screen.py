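"""Dose-response fitting and single-dose drug classification.

Each drug is screened alone (A) and after 24 h MEK-inhibitor pre-treatment
(T), both relative to matched controls (= 1), and classified as
growth-promoting / cytotoxic x MAPK-dependent / -independent or ineffective.
Full dose-response curves are fitted with a four-parameter logistic to
extract IC50s and pre-treatment fold shifts.
"""

import numpy as np

from oiswaves import drug_response as dr
from oiswaves.synthetic import DrugPlateSpec, generate_dose_response

data = generate_dose_response(DrugPlateSpec(seed=1))
calls = data["screen"].merge(data["truth"][["drug", "true_class"]], on="drug")
calls["called"] = [dr.classify_drug(a, t)
                   for a, t in zip(calls["A"], calls["T"])]
print(calls[["drug", "A", "T", "called"]].round(2).to_string(index=False))
acc = (calls["called"] == calls["true_class"]).mean()
print(f"\nclass recovery on this plate: {acc:.0%}")

# IC50 shift of the senolytic upon MEKi pre-treatment: releasing the cells
# from senescence makes the BCL-XL inhibitor less potent
folds = []
for seed in range(6):
    plate = generate_dose_response(DrugPlateSpec(seed=seed))["plate"]
    ic = {}
    for cond in ("single", "pretreat"):
        sub = plate.query("drug == 'navitoclax' and condition == @cond")
        ic[cond] = dr.fit_4pl(sub["dose"], sub["response"]).ic50
    folds.append(dr.ic50_fold(ic["single"], ic["pretreat"]))
print(f"\nnavitoclax IC50 fold (pretreat / single), mean of 6 plates: "
      f"{np.mean(folds):.2f}  (generative truth: 3.62)")
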