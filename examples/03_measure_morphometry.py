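"""Measure one oocyte's regions and compute the four shape descriptors.

Each region is measured on the area enclosed by its outer boundary (so the
ZP measurement covers the whole oocyte), from a sub-pixel iso-contour:
area A, perimeter Lp, best-fit-ellipse axes Lmaj/Lmin, convex-hull area.
Descriptors: aspect ratio RA = Lmaj/Lmin, circularity C = 4*pi*A/Lp^2,
roundness R = 4A/(pi*Lmaj^2), solidity S = A/Ahull.
"""

from oomorph import PhantomSpec, generate_phantom, shape_descriptors
from oomorph.morphometry import measure_regions, relative_features

_, labels, _ = generate_phantom(PhantomSpec(), seed=11)
geoms = measure_regions(labels)

print(f"{'region':8s} {'A (px^2)':>10s} {'Lp (px)':>8s} {'Lmaj':>7s} "
      f"{'Lmin':>7s} {'RA':>6s} {'C':>6s} {'R':>6s} {'S':>6s}")
for region in ("ooplasm", "pvs", "zp"):
    g = geoms[region]
    d = shape_descriptors(g)
    print(f"{region:8s} {g.area:10.0f} {g.perimeter:8.1f} {g.major_axis:7.1f} "
          f"{g.minor_axis:7.1f} {d.aspect_ratio:6.3f} {d.circularity:6.3f} "
          f"{d.roundness:6.3f} {d.solidity:6.3f}")

rel = relative_features(geoms)
print("\ninter-region ratios (inner/outer, all dimensionless):")
for k in sorted(rel):
    print(f"  {k:42s} {rel[k]:.3f}")
# Absolute pixel measurements never enter the downstream model: only the
# descriptors and these ratios do, because ratios transfer across
# magnifications and imaging systems.
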