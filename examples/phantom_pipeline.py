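"""Render one synthetic whole mount and measure it end to end.

Builds a stage-1 phantom (a gland filling its fat pad), runs the full
analysis pipeline — grayscale, lymph-node excision, background flattening,
contrast enhancement, AOI rasterization, thresholding, measurement — and
compares the recovered epithelial area against the phantom's exact ground
truth.
"""

from wholemount import AnalysisConfig, PhantomSpec, analyze_whole_mount, render_phantom

cfg = AnalysisConfig()
rgb, truth = render_phantom(PhantomSpec(stage=1.0, seed=3))
m = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, cfg)

true_area = truth.true_epithelial_area_px * cfg.cm_per_pixel**2
print(f"epithelial area   {m.epithelial_area_cm2:.4f} cm^2 (ground truth {true_area:.4f})")
print(f"fat-pad area      {m.fat_area_cm2:.4f} cm^2")
print(f"total gland area  {m.total_area_cm2:.4f} cm^2")
print(f"epithelial volume {m.epithelial_sum_od:.1f} sum-OD")
print(f"density (area)    {m.density_area_pct:.1f} %")
print(f"density (volume)  {m.density_volume_pct:.1f} %")
print()
print("Density is the fraction of the traced gland occupied by stained")
print("epithelium - the rodent analogue of percent mammographic density.")
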