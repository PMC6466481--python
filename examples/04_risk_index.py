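"""Score subjects with the published nine-term synthetic value (SV).

The SV is the linear combination of a subject's raw clinical values with
the normalized feature weights of the reference stroke model (age carries
coefficient 1). Risk bands apply on the risk-index scale: <=1.5 none,
<=2 low, >2 high; the published high-risk SV interval is (1675, 2175).
"""

from wrhfs import RiskModel, risk_rank, synthetic_value

model = RiskModel.published()
print("SV terms:", " + ".join(f"{c:g} x {f}" for f, c in model.sv_terms))
print("published high-risk SV interval:", model.hri)

subject = {
    "Age": 72, "α-HBD": 160, "SCr": 88, "LDH": 210, "Height": 168,
    "TBIL": 14.0, "CK": 95, "Apo-B": 0.9, "CK-MB": 12,
}
sv = synthetic_value(subject, model)
print(f"\nexample subject SV = {sv:.1f}")
print("inside high-risk interval:", model.hri[0] < sv < model.hri[1])

for idx in (1.2, 1.8, 2.4):
    print(f"risk index {idx} -> band {risk_rank(idx)}")
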