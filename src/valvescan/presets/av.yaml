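# Aortic-valve cusp preset.  The aortic valve has no papillary muscle or
# chordae: the strip runs from the aortic wall (AO) through a diffuse
# attachment into the cusp (LL).  All values here are plausible synthetic
# stand-ins: no per-region reference measurements exist for this geometry,
# so this preset carries no recovery targets.
name: AV
reference_region: AO
reference_area_mm2: 6.0
weak_region: AO-LL
weak_area_deficit: 0.005
d_period_nm: 67.0
d11_nm: 21.5
d11_strain_gain: 0.3
alignment_rate: 1.5
marker_inset_mm: 0.5
coupling:
  baseline: 0.10
  bumps:
    - {region: AO-LL, amplitude: 0.20, sigma_mm: 1.0}
regions:
  - name: AO
    length_mm: 6.0
    thickness_mm: 2.2
    muscle_fraction: 0.35
    sigma_chi_deg: 18.0
    toe_stiffness_mpa: 0.05
    toe_exponent: 35.0
    linear_modulus_mpa: 0.6
    ultimate_stress_mpa: 0.35
    residual_fraction: 0.05
  - name: AO-LL
    length_mm: 2.5
    thickness_mm: 1.4
    muscle_fraction: null
    sigma_chi_deg: 15.0
    transition: true
    toe_stiffness_mpa: 0.04
    toe_exponent: 45.0
    linear_modulus_mpa: 0.5
    ultimate_stress_mpa: 0.12
    residual_fraction: 0.05
  - name: LL
    length_mm: 6.0
    thickness_mm: 1.0
    muscle_fraction: 0.0
    sigma_chi_deg: 26.0
    toe_stiffness_mpa: 0.03
    toe_exponent: 40.0
    linear_modulus_mpa: 0.4
    ultimate_stress_mpa: 0.2
    residual_fraction: 0.05
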