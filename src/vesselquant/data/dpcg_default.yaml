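# Default resectability rule table (Dutch Pancreatic Cancer Group scheme).
#
# Degrees of circumferential tumor-vessel involvement are mapped per vessel
# class to a resectability stage.  Intervals are [lower, upper] in degrees
# and are interpreted right-closed ((lower, upper]); the first interval of
# a class additionally contains its lower bound, so a degenerate [0, 0]
# interval matches exactly 0.  Stages per class must be ordered from least
# to most severe and tile [0, 360] without gaps.
#
# Occlusion/stenosis qualifiers are not represented: the involvement input
# carries no such signal, so staging here is purely contact-geometric.
vessel_classes:
  CeTr: arterial
  HA: arterial
  SMA: arterial
  SMV: venous
  PV: venous
arterial_stages:
  resectable: [0, 0]
  borderline_resectable: [0, 90]
  locally_advanced: [90, 360]
venous_stages:
  resectable: [0, 90]
  borderline_resectable: [90, 270]
  locally_advanced: [270, 360]
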