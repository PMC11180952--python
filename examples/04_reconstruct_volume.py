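"""Full pipeline: synthetic stack -> aligned, normalized, isotropic NIfTI volume.

The in-plane resolution is Lanczos-downsampled to 0.2 mm to match the
0.2 mm spacing between photographed blockfaces, giving isotropic voxels.
"""

import nibabel as nib

import blockstack as bs
from blockstack.pipeline import PipelineConfig

params = bs.AcquisitionParams()
images, records = bs.generate_stack(params, bs.PhantomSpec(), n_slices=10,
                                    jitter=bs.JitterSpec(), seed=1)

result = bs.run_pipeline(PipelineConfig(), images=images,
                         output_volume="scratch/volume.nii.gz")

d, h, w = result.volume.voxels.shape[:3]
print(f"volume: {d} x {h} x {w} voxels at {result.volume.voxel_size_mm} mm isotropic")
hdr = nib.load(str(result.volume_path)).header
print(f"NIfTI pixdim: {hdr.get_zooms()[:3]}")
worst = max(a.rms_residual_px for a in result.alignments)
print(f"worst per-slice marker RMS residual: {worst:.4f} px")

# pixdim (0.2, 0.2, 0.2) confirms the isotropy contract; the residual shows
# how precisely the fiducial pillars are stacked through depth.
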