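"""Ventral contact stresses: septum pull versus proximal end pull.

Loads the pad block either dorsodistally through the septum's ventral
attachment line or with the same force magnitude on the proximal end face,
and compares the normal (pull-off) tractions on the bonded ventral surface.
Septum loading concentrates tension at the proximal edge and raises the mean
pull-off traction - peeling starts proximally, for less force.
"""

import frogpad as fp

domain = fp.build_design_domain(fp.PadGeometryParams(), (30, 20, 9))
report = fp.septum_loadcase_comparison(domain, fp.Material())

s, p = report.septum, report.proximal_pull
print("case             max pull-off (kPa)   at x (mm)   mean pull-off (kPa)")
print(f"septum pull          {1e3 * s.max_tensile_MPa:10.2f}      {s.max_tensile_location_mm[0]:7.3f}"
      f"       {1e3 * s.mean_tensile_MPa:8.3f}")
print(f"proximal pull        {1e3 * p.max_tensile_MPa:10.2f}      {p.max_tensile_location_mm[0]:7.3f}"
      f"       {1e3 * p.mean_tensile_MPa:8.3f}")
print(f"\nseptum / proximal mean pull-off ratio: {report.mean_tensile_ratio:.1f}")
print(f"septum-case maximum in proximal 10% of the pad: {report.septum_peaks_proximally}")
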