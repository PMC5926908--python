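# Default configuration for blisterquant.
#
# Stain extinction vectors are the widely used Ruifrok & Johnston
# H-DAB deconvolution constants (per-channel relative absorbance,
# R/G/B order). The synthetic slide generator and the stain-detection
# reference hues both read these values, so forward synthesis and
# inversion share one definition.

stain_vectors:
  hematoxylin: [0.650, 0.704, 0.286]
  dab: [0.268, 0.570, 0.776]

tissue:
  filter_window_px: 25       # mean-filter window on the darkest-channel image
  init_centile: 99.0         # percentile of the filtered image
  init_offset: 15.0          # subtracted from the percentile (8-bit units)
  bg_centile: 10.0           # percentile of the background region
  bg_offset: 10.0            # subtracted (8-bit units)
  min_area_um2: 50.0         # tissue/background islands below this are flipped
  min_tissue_fraction: 0.01  # tissue components below this fraction are removed
  downsample: 2              # tissue stage runs at this integer downscaling
  connectivity: 2            # 8-connectivity for component labelling

stains:
  blue_small_window: 3
  blue_large_window: 101
  blue_floor: 0.05           # AU; strict > for normalized blue
  i0: 255                    # incident (glass) intensity per channel
  angle_full_deg: 15.0       # hue proximity weight = 1 within this angle
  angle_zero_deg: 60.0       # weight = 0 beyond this angle

cells:
  nb_threshold: 0.1              # AU, strict >
  min_nucleus_area_um2: 10.0     # strict >
  max_nucleus_area_um2: 150.0    # artifact ceiling, strict > discards
  body_depth_px: 7               # at the reference pixel size
  ref_pixel_size_um: 0.45
  dab_pixel_threshold: 0.1       # AU, strict >
  body_positive_fraction: 0.20   # strict >
  nucleus_positive_fraction: 0.40  # strict >
  split_h: 0.5                   # h-maxima depth for merged-nucleus splitting

mediators:
  rt_tolerance_min: 0.1
  mz_tolerance: 0.01
  min_ions: 6
  plsda_scaling: auto        # auto | pareto | none
  posthoc_correction: holm
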