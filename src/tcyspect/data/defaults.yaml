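# Packaged defaults: acquisition physics, phantom configuration, dead-time model.
#
# Energy windows are keV bounds of the five acquisition windows plus the open
# ("full") window.  Collimator geometry is the printed hole geometry of the
# three collimator sets; k_factor is the measured ratio of 90Y counts in the
# 140 keV window to counts in the 226 keV window for that collimator.

energy_windows_kev:
  "125": [119.7, 129.5]
  "140": [129.5, 150.5]
  "155": [150.5, 160.3]
  "181": [161.1, 200.9]
  "226": [201.1, 250.9]
  "full": [0.0, 690.0]

collimators:
  LEHR: {hole_length_mm: 24.04, septal_thickness_mm: 0.16, hole_diameter_mm: 1.11, penetration_scale: 0.10, k_factor: 0.478}
  ME:   {hole_length_mm: 40.64, septal_thickness_mm: 1.14, hole_diameter_mm: 2.94, penetration_scale: 0.05, k_factor: 0.632}
  HE:   {hole_length_mm: 59.7,  septal_thickness_mm: 2.0,  hole_diameter_mm: 4.0,  penetration_scale: 0.05, k_factor: 0.745}

# Per (isotope, collimator, window) detection model.  Each window entry is
# [primary, diffuse] sensitivity in cps/MBq for a source in air: "primary"
# counts get the distance-dependent geometric collimator PSF only, "diffuse"
# counts (scatter, septal penetration, bremsstrahlung haze) are additionally
# blurred by a broad stationary Gaussian of diffuse_fwhm_mm.
#
# 99mTc: photopeak in the 140 keV window (80% primary / 20% scatter); the
# flanking 125/155 scatter windows carry pure scatter whose average equals the
# 140 keV scatter component (TEW-consistent); nothing above 161 keV.
spectrum:
  Tc:
    diffuse_fwhm_mm: {LEHR: 40.0, ME: 40.0, HE: 40.0}
    windows:
      LEHR: {"125": [0.0, 5.675], "140": [18.16, 4.54],  "155": [0.0, 3.405], "181": [0.0, 0.0], "226": [0.0, 0.0], "full": [18.16, 27.24]}
      ME:   {"125": [0.0, 7.775], "140": [24.88, 6.22],  "155": [0.0, 4.665], "181": [0.0, 0.0], "226": [0.0, 0.0], "full": [24.88, 37.32]}
      HE:   {"125": [0.0, 5.725], "140": [18.32, 4.58],  "155": [0.0, 3.435], "181": [0.0, 0.0], "226": [0.0, 0.0], "full": [18.32, 27.48]}
  # 90Y bremsstrahlung: no photopeak; a per-collimator primary/diffuse split
  # shared by every window (the continuum is spectrally smooth), so the
  # 140/226 count ratio of any extended source equals the k-factor exactly.
  # The 140 keV sensitivity is derived at load time as k_factor * s226.
  Y:
    diffuse_fwhm_mm: {LEHR: 60.0, ME: 30.0, HE: 30.0}
    primary_fraction: {LEHR: 0.30, ME: 0.60, HE: 0.60}
    s226_cps_per_mbq: {LEHR: 11.80, ME: 1.566, HE: 0.685}
    window_rel_140: {"125": 0.50, "155": 0.45, "181": 1.80, "full": 8.0}

geometry:
  n_angles: 120
  rotation_radius_mm: 250.0
  duration_s: 20.0

# Phantom configuration: compartment volumes of the torso phantom and the
# per-isotope activity configuration (tumor-to-normal ratios, lung shunt
# fraction, extrahepatic-deposition-to-liver activity ratios, total activity).
phantom:
  volumes_ml: {liver: 1172.0, tumor1: 24.5, tumor2: 16.0, lungs: 690.0, ehd1: 8.1, ehd2: 4.1, ehd3: 2.0}
  isotopes:
    Tc: {tn_ratio_tumor1: 4.0, tn_ratio_tumor2: 4.0, lsf_pct: 15.0,
         ehd1_liver_pct: 3.28, ehd2_liver_pct: 0.00, ehd3_liver_pct: 0.81, total_mbq: 98.0}
    Y:  {tn_ratio_tumor1: 1.0, tn_ratio_tumor2: 4.0, lsf_pct: 10.0,
         ehd1_liver_pct: 3.13, ehd2_liver_pct: 1.58, ehd3_liver_pct: 0.00, total_mbq: 1969.0}
  grid: {shape: 128, voxel_mm: 4.8}
  # World coordinates (mm), origin at the volume centre; ellipsoid semi-axes.
  # Positions approximate the torso phantom layout: liver right, two tumors
  # inside it, lungs superior, three EHD spheres in the background volume.
  placement_mm:
    body:   {center: [0.0, 0.0, 0.0],     semi_axes: [170.0, 120.0, 250.0]}
    liver:  {center: [45.0, 20.0, -60.0], semi_axes: [95.0, 75.0, 39.3]}
    tumor1: {center: [85.0, 20.0, -60.0]}
    tumor2: {center: [5.0, 20.0, -60.0]}
    lung_left:  {center: [-60.0, 0.0, 120.0], semi_axes: [28.0, 40.0, 73.6]}
    lung_right: {center: [60.0, 0.0, 120.0],  semi_axes: [28.0, 40.0, 73.6]}
    ehd1: {center: [0.0, -80.0, -140.0]}
    ehd2: {center: [90.0, -70.0, 20.0]}
    ehd3: {center: [-90.0, -40.0, -20.0]}

attenuation_per_cm: {soft_tissue: 0.154, lung: 0.040}

# Paralyzable dead-time model: R_obs = R_true * exp(-R_true * tau).
# Intrinsic slopes are full-spectrum, no-collimator count rates per MBq;
# extrinsic/intrinsic ratios convert them to collimated rates.
deadtime:
  tau_s: 5.0e-7
  intrinsic_slope_cps_per_mbq: {Tc: 9.0e+4, Y: 4.5e+3}
  extrinsic_intrinsic_ratio: {LEHR: 2.5e-4, ME: 3.4e-4, HE: 2.5e-4}

reconstruction:
  iterations: 50
  subsets: 8
  floor: 1.0e-12
  postfilter_fwhm_mm: 5.0
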