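# Tricuspid-valve strip preset.  Same construction as the MV preset with
# the tricuspid per-region ultimate stresses (MPa).
name: TV
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
    - {region: CT-LL, amplitude: 0.04, sigma_mm: 0.8}
rotated_population:
  region: CT-LL
  amplitude: 0.70
  sigma_mm: 0.8
regions:
  - name: PM
    length_mm: 8.0
    thickness_mm: 3.2
    muscle_fraction: 0.95
    sigma_chi_deg: 16.0
    toe_stiffness_mpa: 0.05
    toe_exponent: 29.0
    linear_modulus_mpa: 0.5
    ultimate_stress_mpa: 0.119
    residual_fraction: 0.05
  - name: PM-CT
    length_mm: 3.0
    thickness_mm: 1.7
    muscle_fraction: null
    sigma_chi_deg: 12.0
    transition: true
    toe_stiffness_mpa: 0.12
    toe_exponent: 46.0
    linear_modulus_mpa: 1.2
    ultimate_stress_mpa: 0.159
    residual_fraction: 0.05
  - name: CT
    length_mm: 10.0
    thickness_mm: 0.9
    muscle_fraction: 0.0
    sigma_chi_deg: 7.0
    toe_stiffness_mpa: 12.0
    toe_exponent: 115.0
    linear_modulus_mpa: 120.0
    ultimate_stress_mpa: 4.503
    residual_fraction: 0.05
  - name: CT-LL
    length_mm: 2.0
    thickness_mm: 1.2
    muscle_fraction: null
    sigma_chi_deg: 14.0
    transition: true
    toe_stiffness_mpa: 0.1
    toe_exponent: 77.0
    linear_modulus_mpa: 1.0
    ultimate_stress_mpa: 0.097
    residual_fraction: 0.05
  - name: LL
    length_mm: 7.0
    thickness_mm: 1.6
    muscle_fraction: 0.0
    sigma_chi_deg: 24.0
    toe_stiffness_mpa: 0.045
    toe_exponent: 38.0
    linear_modulus_mpa: 0.45
    ultimate_stress_mpa: 0.059
    residual_fraction: 0.05
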