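"""Render a synthetic Doppler flow-phantom acquisition.

Generates a 30-frame duplex video of a 5 mm vessel at 6 mL/s constant
flow with a 3 mm blind zone and color bleeding, plus the companion B-mode
still, and writes everything (PNG frames, layout metadata, ground truth)
as a reusable fixture directory.
"""

from cdqa.phantom import (
    ArtifactSpec,
    FlowSpec,
    PhantomSpec,
    simulate_bmode,
    simulate_cd_video,
    write_fixture,
)

spec = PhantomSpec(vessel_depth_mm=20.0, fov_cm=5.0)
flow = FlowSpec(Q=6.0)  # mean velocity Q/A = 30.6 cm/s, parabolic peak 61.1 cm/s
artifacts = ArtifactSpec(blind_zone_width_mm=3.0, bleed_rate=0.3, color_noise_sd=4.0)

stack, gt = simulate_cd_video(spec, flow, artifacts, n_fr=30, seed=7)
paths = write_fixture(stack, gt, "phantom_fixture")
bmode, _ = simulate_bmode(spec, seed=7)

print(f"Rendered {stack.n_fr} frames of {stack.shape[1]}x{stack.shape[0]} px")
print(f"Velocity scale (Nyquist): ±{gt.nyquist:.1f} cm/s, no aliasing by construction")
print(f"Ground truth: mean velocity {gt.v_mean:.1f} cm/s, peak {gt.v_peak:.1f} cm/s, "
      f"{int(gt.bleed_mask.sum())} bleed pixels")
print(f"Fixture written to {paths['frames']} (frames + meta.yaml + ground_truth.json)")
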