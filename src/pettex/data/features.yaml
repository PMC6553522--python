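# Versioned roster of the 114 tumor features.
# categories: geometric (15), model_based (6), first_order (37),
#             second_order (21), higher_order (35)
version: 1
features:
  # ---- geometric (15) ----
  - {name: vol_met, category: geometric, unit: mm^3}
  - {name: surface_area, category: geometric, unit: mm^2}
  - {name: surface_to_volume_ratio, category: geometric, unit: mm^-1}
  - {name: sphericity, category: geometric, unit: ""}
  - {name: compactness1, category: geometric, unit: ""}
  - {name: compactness2, category: geometric, unit: ""}
  - {name: spherical_disproportion, category: geometric, unit: ""}
  - {name: max_3d_diameter, category: geometric, unit: mm}
  - {name: equivalent_spherical_diameter, category: geometric, unit: mm}
  - {name: major_axis_length, category: geometric, unit: mm}
  - {name: minor_axis_length, category: geometric, unit: mm}
  - {name: least_axis_length, category: geometric, unit: mm}
  - {name: elongation, category: geometric, unit: ""}
  - {name: flatness, category: geometric, unit: ""}
  - {name: centroid_surface_distance_mean, category: geometric, unit: mm}
  # ---- model_based (6) ----
  - {name: fd_mask, category: model_based, unit: ""}
  - {name: fd_intensity, category: model_based, unit: ""}
  - {name: fd_mean, category: model_based, unit: ""}
  - {name: fd_max, category: model_based, unit: ""}
  - {name: fd_std, category: model_based, unit: ""}
  - {name: lacunarity, category: model_based, unit: ""}
  # ---- first_order (37) ----
  - {name: met_mean, category: first_order, unit: "%ID/g"}
  - {name: met_max, category: first_order, unit: "%ID/g"}
  - {name: met_min, category: first_order, unit: "%ID/g"}
  - {name: met_median, category: first_order, unit: "%ID/g"}
  - {name: percentile_05, category: first_order, unit: "%ID/g"}
  - {name: percentile_10, category: first_order, unit: "%ID/g"}
  - {name: percentile_25, category: first_order, unit: "%ID/g"}
  - {name: percentile_75, category: first_order, unit: "%ID/g"}
  - {name: percentile_90, category: first_order, unit: "%ID/g"}
  - {name: percentile_95, category: first_order, unit: "%ID/g"}
  - {name: interquartile_range, category: first_order, unit: "%ID/g"}
  - {name: interdecile_range, category: first_order, unit: "%ID/g"}
  - {name: range, category: first_order, unit: "%ID/g"}
  - {name: standard_deviation, category: first_order, unit: "%ID/g"}
  - {name: variance, category: first_order, unit: "(%ID/g)^2"}
  - {name: mean_absolute_deviation, category: first_order, unit: "%ID/g"}
  - {name: median_absolute_deviation, category: first_order, unit: "%ID/g"}
  - {name: robust_mean_absolute_deviation, category: first_order, unit: "%ID/g"}
  - {name: root_mean_square, category: first_order, unit: "%ID/g"}
  - {name: energy, category: first_order, unit: "(%ID/g)^2"}
  - {name: total_energy, category: first_order, unit: "(%ID/g)^2.mm^3"}
  - {name: entropy, category: first_order, unit: bits}
  - {name: uniformity, category: first_order, unit: ""}
  - {name: skewness, category: first_order, unit: ""}
  - {name: kurtosis_excess, category: first_order, unit: ""}
  - {name: coefficient_of_variation, category: first_order, unit: ""}
  - {name: quartile_coefficient_of_dispersion, category: first_order, unit: ""}
  - {name: histogram_mode, category: first_order, unit: "%ID/g"}
  - {name: histogram_max_probability, category: first_order, unit: ""}
  - {name: trimmed_mean_10_90, category: first_order, unit: "%ID/g"}
  - {name: mean_median_difference, category: first_order, unit: "%ID/g"}
  - {name: entropy_normalized, category: first_order, unit: ""}
  - {name: histogram_gradient_max, category: first_order, unit: ""}
  - {name: histogram_gradient_max_level, category: first_order, unit: ""}
  - {name: histogram_gradient_min, category: first_order, unit: ""}
  - {name: histogram_gradient_min_level, category: first_order, unit: ""}
  - {name: total_lesion_metabolism, category: first_order, unit: "%ID/g.mm^3"}
  # ---- second_order / GLCM (21) ----
  - {name: glcm_contrast, category: second_order, unit: ""}
  - {name: glcm_dissimilarity, category: second_order, unit: ""}
  - {name: glcm_homogeneity, category: second_order, unit: ""}
  - {name: glcm_inverse_difference_moment, category: second_order, unit: ""}
  - {name: glcm_energy, category: second_order, unit: ""}
  - {name: glcm_entropy, category: second_order, unit: bits}
  - {name: glcm_correlation, category: second_order, unit: ""}
  - {name: glcm_autocorrelation, category: second_order, unit: ""}
  - {name: glcm_cluster_shade, category: second_order, unit: ""}
  - {name: glcm_cluster_prominence, category: second_order, unit: ""}
  - {name: glcm_cluster_tendency, category: second_order, unit: ""}
  - {name: glcm_imc1, category: second_order, unit: ""}
  - {name: glcm_imc2, category: second_order, unit: ""}
  - {name: glcm_maximum_probability, category: second_order, unit: ""}
  - {name: glcm_sum_average, category: second_order, unit: ""}
  - {name: glcm_sum_entropy, category: second_order, unit: bits}
  - {name: glcm_sum_variance, category: second_order, unit: ""}
  - {name: glcm_difference_entropy, category: second_order, unit: bits}
  - {name: glcm_difference_variance, category: second_order, unit: ""}
  - {name: glcm_joint_average, category: second_order, unit: ""}
  - {name: glcm_inverse_variance, category: second_order, unit: ""}
  # ---- higher_order / GLRLM (16) ----
  - {name: glrlm_sre, category: higher_order, unit: ""}
  - {name: glrlm_lre, category: higher_order, unit: ""}
  - {name: glrlm_gln, category: higher_order, unit: ""}
  - {name: glrlm_rln, category: higher_order, unit: ""}
  - {name: glrlm_run_percentage, category: higher_order, unit: ""}
  - {name: glrlm_lgre, category: higher_order, unit: ""}
  - {name: glrlm_hgre, category: higher_order, unit: ""}
  - {name: glrlm_srlge, category: higher_order, unit: ""}
  - {name: glrlm_srhge, category: higher_order, unit: ""}
  - {name: glrlm_lrlge, category: higher_order, unit: ""}
  - {name: glrlm_lrhge, category: higher_order, unit: ""}
  - {name: glrlm_run_length_variance, category: higher_order, unit: ""}
  - {name: glrlm_run_entropy, category: higher_order, unit: bits}
  - {name: glrlm_gray_level_variance, category: higher_order, unit: ""}
  - {name: glrlm_run_mean_length, category: higher_order, unit: ""}
  - {name: glrlm_gray_level_mean, category: higher_order, unit: ""}
  # ---- higher_order / GLSZM (14) ----
  - {name: glszm_sze, category: higher_order, unit: ""}
  - {name: glszm_lze, category: higher_order, unit: ""}
  - {name: glszm_intensity_variability, category: higher_order, unit: ""}
  - {name: glszm_szv_nu, category: higher_order, unit: ""}
  - {name: glszm_szv_var, category: higher_order, unit: ""}
  - {name: glszm_zone_percentage, category: higher_order, unit: ""}
  - {name: glszm_lize, category: higher_order, unit: ""}
  - {name: glszm_hize, category: higher_order, unit: ""}
  - {name: glszm_szlie, category: higher_order, unit: ""}
  - {name: glszm_szhie, category: higher_order, unit: ""}
  - {name: glszm_lzlie, category: higher_order, unit: ""}
  - {name: glszm_lzhie, category: higher_order, unit: ""}
  - {name: glszm_zone_size_entropy, category: higher_order, unit: bits}
  - {name: glszm_gray_level_variance, category: higher_order, unit: ""}
  # ---- higher_order / NGTDM (5) ----
  - {name: ngtdm_coarseness, category: higher_order, unit: ""}
  - {name: ngtdm_contrast, category: higher_order, unit: ""}
  - {name: ngtdm_busyness, category: higher_order, unit: ""}
  - {name: ngtdm_complexity, category: higher_order, unit: ""}
  - {name: ngtdm_strength, category: higher_order, unit: ""}
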