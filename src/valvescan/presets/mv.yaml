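# Mitral-valve strip preset.
#
# Per-region ultimate stresses are the measured values for porcine mitral
# valve strips (MPa).  Cross-sectional areas are strength-consistent with a
# single series pull (A_i = F0 / sigma_ult_i; see the phantom module
# docstring): the tear force F0 is fixed by giving the reference region (PM)
# a realistic 10 mm^2 cross section, and the PM-CT transition is made 0.5%
# thinner so failure initiates there, as observed in failure pulls.
# Moduli, toe parameters, thicknesses and spreads are plausible choices for
# these tissue types (compliant muscle, stiff chordae, intermediate leaflet);
# see docs/methods.md.
name: MV
reference_region: PM
reference_area_mm2: 10.0
weak_region: PM-CT
weak_area_deficit: 0.005
d_period_nm: 67.0
d11_nm: 21.5
d11_strain_gain: 0.3
alignment_rate: 1.5
marker_inset_mm: 0.5
coupling:
  baseline: 0.10
  bumps:
    - {region: PM-CT, amplitude: 0.30, sigma_mm: 1.2}
    - {region: CT-LL, amplitude: 0.05, sigma_mm: 0.8}
rotated_population:
  region: CT-LL
  amplitude: 0.70
  sigma_mm: 0.8
regions:
  - name: PM
    length_mm: 8.0
    thickness_mm: 3.0
    muscle_fraction: 0.95
    sigma_chi_deg: 16.0
    toe_stiffness_mpa: 0.005
    toe_exponent: 29.0
    linear_modulus_mpa: 0.05
    ultimate_stress_mpa: 0.011
    residual_fraction: 0.05
  - name: PM-CT
    length_mm: 3.0
    thickness_mm: 1.6
    muscle_fraction: null
    sigma_chi_deg: 12.0
    transition: true
    toe_stiffness_mpa: 0.1
    toe_exponent: 46.0
    linear_modulus_mpa: 1.0
    ultimate_stress_mpa: 0.144
    residual_fraction: 0.05
  - name: CT
    length_mm: 10.0
    thickness_mm: 0.8
    muscle_fraction: 0.0
    sigma_chi_deg: 7.0
    toe_stiffness_mpa: 4.0
    toe_exponent: 115.0
    linear_modulus_mpa: 40.0
    ultimate_stress_mpa: 1.491
    residual_fraction: 0.05
  - name: CT-LL
    length_mm: 2.0
    thickness_mm: 1.1
    muscle_fraction: null
    sigma_chi_deg: 14.0
    transition: true
    toe_stiffness_mpa: 0.03
    toe_exponent: 77.0
    linear_modulus_mpa: 0.3
    ultimate_stress_mpa: 0.024
    residual_fraction: 0.05
  - name: LL
    length_mm: 7.0
    thickness_mm: 1.5
    muscle_fraction: 0.0
    sigma_chi_deg: 24.0
    toe_stiffness_mpa: 0.02
    toe_exponent: 38.0
    linear_modulus_mpa: 0.2
    ultimate_stress_mpa: 0.025
    residual_fraction: 0.05
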