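# Group taxonomy for working activities and materials.
#
# This file is data, not code: the full activity-code list of the source
# exposure database is not public, so the maps below are seeded with
# every activity string printed in the study and can be extended by
# users.  Activity codes are matched case-insensitively after whitespace
# normalisation.
#
# Working-activity groups:
#   1 surface treatment, 2 high temperature processing,
#   3 filling/transport/storage, 4 machining/abrasive techniques,
#   5 forming, 6 others (fallback for unknown codes).
# Material groups pool the printed subcategories:
#   A mineral-dominated, B metal-dominated, C fiber-dominated.
# Wood dust is deliberately NOT mapped into group A: wood dust consists
# predominantly of inhalable particles and is not comparable to
# mineral-dominated dust, so it stays "unclassified" and no conversion
# group resolves for it.

activity_groups:
  1:
    name: surface treatment
    activities:
      - glazing
      - spray painting
      - powder coating
      - galvanization
  2:
    name: high temperature processing
    activities:
      - thermal cutting
      - extrusion
      - soldering
      - welding
  3:
    name: filling/transport/storage
    activities:
      - filling
      - transport
      - storage
  4:
    name: machining/abrasive techniques
    activities:
      - machining
      - abrasive techniques
  5:
    name: forming
    activities:
      - roll forming
      - pressing
      - bending
  6:
    name: others
    activities: []

material_groups:
  A:
    name: mineral-dominated
    subcategories:
      - synthetic material/rubber/epoxy resin/powder coating
      - mineral material/glass/plaster/gypsum/concrete/carbon/graphite
      - others
  B:
    name: metal-dominated
    subcategories:
      - metal/metal ores/slag/metallic shot
      - lacquers/paint
      - electronic waste
  C:
    name: fiber-dominated
    subcategories:
      - textile
      - mineral fibers/ceramic fibers
      - paper
      - asphalt/bitumen

# Only these activity/material combinations have published combined
# conversion functions.
combined_groups:
  - 1-A
  - 2-B
  - 4-A
  - 6-B

# Heuristic groups: trial-and-error refined activity subsets with the
# best fit quality.  "material" restricts membership to one material
# group ("any" accepts all).  "originating" is the parent group whose
# activity group the member codes inherit.
# NOTE: the source table lists group zeta as originating from 4-A while
# the accompanying text calls it a subgroup of 5-A; the table value
# (4-A) is recorded here.
heuristic_groups:
  alpha:
    name: soldering
    originating: 2-B
    material: B
    activities:
      - soft soldering
      - flame soldering
      - hard soldering
      - arc soldering
      - MIG soldering
  beta:
    name: casting (metalworking)
    originating: 2-B
    material: B
    activities:
      - hot-chamber die-casting
      - cold-chamber die-casting
      - continuous casting
  gamma:
    name: welding
    originating: 2-B
    material: B
    activities:
      - manual arc welding
      - metal inert gas welding
      - metal active gas welding
      - tungsten inert gas welding
      - arc welding, mixed arc process
      - plasma welding
      - laser welding
      - resistance spot welding
      - metal welding, mixed welding processes
  delta:
    name: high temperature cutting
    originating: 2-B
    material: B
    activities:
      - flame cutting
      - plasma cutting
      - laser cutting
  epsilon:
    name: blasting
    originating: "1"
    material: any
    activities:
      - treatment and post-treatment blasting
      - fettling shop, abrasive blasting
      - silica sand abrasive, workpiece sand-coated, room
      - abrasive blasting systems, dry, open
      - sandblasting
  zeta:
    name: chiseling, embossing
    originating: 4-A
    material: A
    activities:
      - chiseling, manually
      - chiseling, mechanically
      - embossing, manually
      - embossing, mechanically
  eta:
    name: wire drawing
    originating: 2-B
    material: B
    activities:
      - wire drawing
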