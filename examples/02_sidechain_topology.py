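"""Sidechain rotation angles and the five-way arrangement taxonomy.

Computes the (theta1, theta2) order parameters for the two conformations
that dominate tripeptide fibril interiors and prints the full reference
map of all 48 codes.
"""

from trifil import (ConformationCode, RegionMap, build_from_code,
                    reference_theta_map, theta_pair, topology_group)

regions = RegionMap.default()

for text in ("b-b-b", "aR-aR-b"):
    frame = build_from_code("FFF", ConformationCode.parse(text), regions)
    t = theta_pair(frame, 0)
    group = topology_group(t)
    print(f"{text}: theta1 = {t.theta1:7.1f} deg, theta2 = {t.theta2:7.1f} deg"
          f"  ->  {group.value}")
# |theta| > 115 deg puts adjacent sidechains on opposite backbone sides
# (anti); |theta| < 60 deg puts them on the same side (syn).  The
# extended strand is all-anti; the helical-helical-extended turn is
# all-syn, with every sidechain on one convex face.

table = reference_theta_map(regions)
print("\ngroup census over all 48 codes:")
print(table["group"].value_counts().to_string())
# codes with any theta in the excluded 60-115 deg band fall in 'other';
# such conformations are geometrically unsuited to filament packing
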