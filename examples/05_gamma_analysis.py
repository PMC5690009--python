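"""2D gamma analysis of the one-dwell vendor-vs-reference plane pair.

Sweeps local-dose-difference and distance-to-agreement criteria over
{1,2,3}% x {1,2,3} mm, the standard commissioning grid.  Despite table
discrepancies near 20% in the pole cones, pass rates stay high: the
affected region is a small fraction of the plane and the steep dose
gradient lets the DTA term rescue many points — exactly why a good gamma
result alone does not clear a planning system.
"""

import tg43qa as q

ref_eng, ven_eng = q.default_engines()
grid = q.GridSpec(half_width=2.0, spacing=0.05)
one = q.make_setup("one_dwell")
reference = q.compute_dose_plane(one, grid, ref_eng)
evaluated = q.compute_dose_plane(one, grid, ven_eng)

results, table = q.gamma_sweep(reference, evaluated)
cols = ["criteria", "evaluated_points", "passed_points", "pass_rate_pct",
        "gamma_mean", "gamma_max", "gamma_median"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))

print("\nPass rates rise as either criterion is relaxed; the gamma median")
print("scales as 1/d% because the dose term dominates where gradients are")
print("flat.  High pass rates coexist with ~20% local underestimates.")
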