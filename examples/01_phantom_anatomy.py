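"""Build the capsule-pouch phantom — the synthetic stand-in for a female
strepsipteran cephalothorax with its invaginated paragenital organ — and
inspect its ground truth."""

import numpy as np

import cuticlemap as cm

spec = cm.PhantomSpec(
    kind="capsule_pouch",
    grid_shape=(100, 64, 64),
    outer_radius=27,
    wall_thickness=5,          # dorsal pouch wall and capsule wall, voxels
    ventral_dorsal_factor=2.0,  # ventral pouch wall twice as thick
    pouch_depth_fraction=0.25,  # pouch depth as fraction of capsule length
    noise_sd=8.0,
    seed=0,
)
volume, mask, truth = cm.make_phantom(spec)

print(f"grid {spec.grid_shape}, foreground voxels: {mask.foreground_count()}")
print(f"true pouch depth DP = {truth.true_DP:.0f} voxels, "
      f"capsule length CL = {truth.true_CL:.0f} voxels")
print(f"pouch depth descriptor: {cm.pouch_depth_percent(truth.true_DP, truth.true_CL):.1f}% "
      "of capsule length")

labels = truth.region_labels
for lab, name in sorted(labels.legend.items()):
    sel = labels.data == lab
    if sel.any():
        t = np.unique(truth.true_thickness[sel])
        span = f"{t.min():.0f}" if len(t) == 1 else f"{t.min():.0f}..{t.max():.0f}"
        print(f"  region {lab} ({name}): {sel.sum():6d} voxels, true wall {span} voxels")

# The ventral pouch wall is exactly twice the dorsal wall by construction,
# and the brood-canal strip thins from ventral-wall to control thickness
# toward the posterior end — the geometry the thickness mappers must reveal.
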