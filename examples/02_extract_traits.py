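"""Render one plot and extract its traits back.

A plot with known biomass/cover/height is rendered as a 5-band stack plus
a DSM/DTM elevation pair; NDVI masking separates plant from soil pixels,
and the extraction chain recovers canopy cover (% of ROI), plant height
(mean DSM−DTM over plant pixels) and the mean band values.
"""

from uavbiomass import synthetic, traits

fb, ph, cc = synthetic.growth_curve(745.0)  # mid-season state
print(f"planted:  FB={fb:.2f} kg/m²  PH={ph:.2f} m  CC={100 * cc:.1f}%")

plot = synthetic.render_plot(fb, cc, ph, shape=(64, 64), seed=7)
roi = traits.ROI.full(plot.stack.shape)
mask = traits.mask_soil(plot.stack, traits.MaskRule("ndvi", 0.4))

cc_hat = traits.canopy_cover(mask, roi)
ph_hat = traits.plant_height(plot.elevation, mask, roi)
dns = traits.mean_dns(plot.stack, mask, roi)

agree = (mask == plot.plant_mask).mean()
print(f"recovered: CC={cc_hat:.1f}%  PH={ph_hat:.3f} m  "
      f"mask agreement={100 * agree:.1f}%")
print("mean plant DNs (B,G,R,RE,NIR):", [round(float(v), 3) for v in dns])
print()
print("CC deviates from the planted cover only by binomial sampling;")
print("PH by the 2 cm per-pixel elevation noise averaged over the canopy.")
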