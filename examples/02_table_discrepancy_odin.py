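"""Vendor-vs-reference anisotropy table comparison and ODIN detection.

Generates a dense reference table, subsamples it onto a sparse 17-angle
vendor grid (with large angular gaps next to the poles), resamples the
vendor table back onto the reference axes, and flags every cell whose
interpolation error exceeds the 2% investigation / 5% intervention
action levels.
"""

import tg43qa as q

dense = q.make_reference_anisotropy(q.SyntheticAnisotropySpec())
vendor = q.subsample_vendor(dense)
print(f"reference: {dense.radii.size} radii x {dense.angles.size} angles")
print(f"vendor:    {vendor.radii.size} radii x {vendor.angles.size} angles")

back = q.resample_table(vendor, dense.radii, dense.angles)
diff = q.compare_tables(dense, back, denominator="a")
report = q.odin_detect(diff)

s = report.summary
print(f"\npercent difference over {s['n_cells']} cells: "
      f"mean {s['mean']:.2f}%, SD {s['sd']:.2f}%, min {s['min']:.1f}%")
print(f"flagged (> 2%): {len(report.flagged)} cells, "
      f"intervention (> 5%): {len(report.intervention)} cells")
print(f"flagged angular bands (deg): {report.angular_bands}")
print(f"angular coverage: {100 * report.angular_coverage_fraction:.1f}% "
      f"of the [0, 180] deg domain")
print("\nAll flagged cells sit inside the vendor table's angular gaps:")
print("sparse sampling across the steep pole gradients makes linear")
print("interpolation underestimate the anisotropy function there.")
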