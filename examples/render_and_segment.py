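"""Full pipeline closure: simulate → render → segment → track → extract.

Generates a synthetic 30-hour bright-field movie of one growing
microcolony (with pixel-level ground truth), reconstructs the lineage
from the images alone, and compares the recovered per-cycle statistics
with the generating truth.
"""

import numpy as np

import cyanocycle as cc

params = cc.RenderParams(pixel_size=0.15, image_size=160, noise_sigma=0.01,
                         seed=3)
spec = cc.ModelSpec("adder", 2.7, trigger_cv=0.15, asym_sd=0.033,
                    growth_rate_mean=0.055, growth_rate_cv=0.15, seed=3)

movie = cc.generate_timelapse(spec, duration=30.0, params=params)
print(f"rendered {movie['stack'].shape[0]} frames "
      f"({movie['stack'].shape[1]}x{movie['stack'].shape[2]} px), "
      f"{len(movie['lineage_table'])} simulated cells")

model = cc.train_morphology_model(
    cc.RenderParams(image_size=96, noise_sigma=0.02, pixel_size=0.15,
                    seed=11))
tracked, lineage, _ = cc.process_stack(movie["stack"], params.pixel_size,
                                       model)
curves = cc.volumes_from_tracks(tracked, movie["frame_times"])
cycles = cc.extract_cycles(tracked, curves)

truth = movie["lineage_table"]
print(f"tracked {len(tracked)} cells, {len(cycles)} complete cycles")
for r in cycles:
    print(f"  cycle: V_b {r.V_b:.2f} µm³, V_d {r.V_d:.2f} µm³, "
          f"T {r.T:.2f} h, λ {r.lam:.4f} h⁻¹ (fit rmse {r.fit_rmse:.3f})")

det = [movie["frame_times"][c.division_frame] for c in tracked
       if c.division_frame is not None]
print(f"division times detected at "
      f"{[round(float(t), 2) for t in sorted(det)]} h")
print(f"true division times       "
      f"{[round(t, 2) for t in sorted(truth.division_time) if t < 30]} h")
print()
print("Recovered birth/division volumes, generation times and growth")
print("rates come from the images alone; agreement with the simulated")
print("truth validates the segmentation + tracking + extraction chain.")
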