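"""Counting water permeation events through a membrane slab.

The synthetic bundle plants nine scripted waters: four genuine crossings
near the protein (three upward, one downward), three crossings far from
the protein and two that teleport across the periodic z-boundary.  Only
the four near crossings qualify: a permeation event must traverse the
three equal-thickness slab regions in order while staying within 15 Å
of the protein, and periodic-boundary jumps reset the crossing.
"""

from carriermd import (
    BundleSpec,
    count_permeation_events,
    generate_bundle_trajectory,
    slab_from_phosphorus,
)

bundle = generate_bundle_trajectory(BundleSpec(seed=2))
top = bundle.topology
slab = slab_from_phosphorus(top, bundle.frames[0])
print(f"membrane slab from phosphorus planes: "
      f"z = [{slab.z_min:.1f}, {slab.z_max:.1f}] Å")

events = count_permeation_events(
    top, bundle.frames,
    water_oxygens=top.select("resname TIP3 and name OH2"),
    protein=top.select("segid PROT"), slab=slab)

print(f"\n{len(events)} permeation events "
      f"(generator planted {len(bundle.truth.countable_events)} countable "
      "crossings):")
for e in events:
    print(f"  water atom {e.molecule_id}: frames {e.entry_frame}-"
          f"{e.exit_frame}, direction {e.direction}")
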