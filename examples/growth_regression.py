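"""Area-volume agreement across a developmental phantom series.

Generates a small growth series (3 stages, 4 phantoms each), measures every
phantom, and regresses log10(epithelial ΣOD) on log10(epithelial area).
A coefficient of determination near 1 means the cheap area measure carries
essentially the same information as the volumetric ΣOD measure.
"""

from wholemount import AnalysisConfig, analyze_whole_mount, growth_series
from wholemount.stats import loglog_area_volume_r2

cfg = AnalysisConfig()
areas, volumes = [], []
for spec, rgb, truth in growth_series(4, [0.2, 0.6, 1.0], base_seed=1):
    m = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, cfg)
    areas.append(m.epithelial_area_cm2)
    volumes.append(m.epithelial_sum_od)
    print(f"stage {spec.stage:.1f} seed {spec.seed:2d}: "
          f"area {m.epithelial_area_cm2:.4f} cm^2, volume {m.epithelial_sum_od:8.1f} sum-OD")

r2 = loglog_area_volume_r2(areas, volumes)
print(f"\nlog-log regression of volume on area: r^2 = {r2:.4f}")
print("(r^2 >= 0.95 means area and volume estimates agree across development)")
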