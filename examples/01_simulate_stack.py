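"""Generate a small synthetic blockface stack and inspect its ground truth.

The simulator emulates the acquisition rig: a fixed camera over a paraffin
block with four dark corner fiducials, photographing every tenth 20 µm cut.
The camera-distance drift shrinks the specimen slightly on every photograph.
"""

import blockstack as bs

params = bs.AcquisitionParams()          # 1500x1000 px over 150x100 mm, 0.1 mm px
phantom = bs.PhantomSpec()               # three-territory ellipse + 4 markers
images, records = bs.generate_stack(params, phantom, n_slices=5,
                                    jitter=bs.JitterSpec(), seed=42)

bs.save_stack("scratch/example_stack", images, records)
print(f"wrote {len(images)} slices of {images[0].width}x{images[0].height} px "
      f"at {images[0].pixel_size_mm} mm/px (slice spacing "
      f"{params.slice_spacing_mm} mm)")
for rec in records:
    t = rec.true_transform
    print(f"slice {rec.slice_index}: scale {t.scale:.5f} "
          f"(camera drift), gain {rec.exposure_gain:.3f}, "
          f"first marker at ({rec.marker_centers_px[0][0]:.2f}, "
          f"{rec.marker_centers_px[0][1]:.2f}) px")

# scale < 1 and shrinking with slice index: the block surface recedes from
# the camera by 0.2 mm per photograph, so each image is slightly smaller.
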