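"""Build a normal atlas from a phantom cohort, then map a 'patient' with an
implanted reversed-flow patch against it.

The patch reverses the axial flow over a 9.55 mm arc-length window of the
proximal descending limb — analytic volume pi R^2 x extent = 3.0 cm^3 — so
the deviation map should flag ~3 cm^3 of >120-degree (red) volume in the
pDAo region and nothing in the ascending aorta.
"""

import math

from hemomap.phantom import (
    FlowProfileSpec,
    ReversedPatch,
    TubeGeometry,
    default_landmarks,
    make_tube_subject,
)
from hemomap.pipeline import RunConfig, analyze_subject, build_atlas

geom = TubeGeometry(30.0, 10.0, 100.0)
cfg = RunConfig(background_correction=False)
profile = FlowProfileSpec(v_peak=100.0, waveform=[1.0])

# healthy cohort (identical members here; see make_cohort for shape variation)
vel, mask, _ = make_tube_subject(profile=profile)
atlas = build_atlas([(vel, mask)] * 5, cfg)
print(f"atlas: shared lumen {atlas.shared_mask.volume_cm3():.1f} cm^3, "
      f"mesh {atlas.shared_mesh.n_vertices} vertices")

# patient with a reversed-flow patch of analytic volume 3.0 cm^3
extent = 3000.0 / (math.pi * geom.lumen_radius**2)
patch = ReversedPatch(center_arclen=geom.arch_length + 35.0, extent=extent)
p_vel, p_mask, _ = make_tube_subject(
    profile=FlowProfileSpec(v_peak=100.0, waveform=[1.0], reversed_patch=patch)
)
report = analyze_subject(p_vel, p_mask, default_landmarks(geom), atlas, cfg)

print(f"atlas coverage of patient lumen: {report.atlas_coverage:.1%}")
print("\nregional abnormal-direction quantification "
      "(volumes cm^3, surfaces cm^2):")
print(report.regional.round(2).to_string())
print("\nThe >120-degree velocity volume in pDAo should sit near the 3.0 cm^3 "
      "implanted; ascending regions stay at zero.")
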