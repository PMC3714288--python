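"""Framingham point scoring and mean arterial pressure for one profile.

Scores a typical recently-menopausal profile with the women's categorical
point table and shows the per-factor contributions.
"""

from cvprofiles import framingham_points, load_point_table, mean_arterial_pressure

table = load_point_table()
profile = dict(age=53, total_cholesterol=208, hdl=72, sbp=117, dbp=75, smoker=0)
pts = framingham_points(**profile, table=table)
print(f"profile: {profile}")
print(f"Framingham point score: {pts}")
print(f"mean arterial pressure: {mean_arterial_pressure(117, 75):.2f} mm Hg")
print(f"attainable score range: {table.attainable_range()}")
# Age 50-54 contributes +6, total cholesterol 200-239 +1, HDL >= 60 -2,
# optimal blood pressure -3: a low-ish score of 2 despite the age points,
# typical of the low-risk class (published class mean 2.16).
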