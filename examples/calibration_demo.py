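"""Spatial and optical-density calibration on their own.

Derives the pixel pitch from two stage-micrometer marks, then shows the
gray-level → optical-density curve at a few levels for both supported
models.
"""

from wholemount import ODCalibration, gray_to_od, spatial_calibration_from_points

cal = spatial_calibration_from_points((10, 20), (130, 70), known_distance_cm=0.26)
print(f"pixel pitch: {cal.cm_per_pixel:.6f} cm/px "
      f"({cal.cm_per_pixel * 1e4:.1f} um/px); 1 px = {cal.cm2_per_pixel:.2e} cm^2")

print("\ngray   OD(log)   OD(linear)")
log_cal, lin_cal = ODCalibration("log"), ODCalibration("linear")
for g in (0, 32, 64, 128, 192, 255):
    print(f"{g:4d}   {gray_to_od(g, log_cal):7.4f}   {gray_to_od(g, lin_cal):7.4f}")
print("\nOD 0 = fully transmitted light (white); 2.4 = opaque at 8-bit depth.")
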