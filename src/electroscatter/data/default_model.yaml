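# Default electro-optic model parameters.
#
# The oscillator values are literature-informed defaults for electrodeposited
# PEDOT:PSS (doped state: weak free-carrier metal, near index-matched to
# water at 640 nm; dedoped state: dielectric with the neutral-polymer
# absorption band in the red/near-IR edge region). They are defaults, not
# measured for any particular device, and are meant to be edited when
# ellipsometry data for a specific film are available.
format_version: 1

permittivity:
  doped_drude:
    eps_inf: 2.2
    plasma_energy_ev: 1.36
    damping_energy_ev: 0.8
  dedoped_oscillators:
    eps_inf: 1.8
    lorentz:                    # (dimensionless amplitude, center eV, width eV)
      - {amplitude: 0.6, center_ev: 4.5, width_ev: 0.5}
    tauc_lorentz:               # (amplitude eV, center eV, width eV, gap eV)
      - {amplitude_ev: 3.0, center_ev: 2.4, width_ev: 1.0, gap_ev: 1.55}
  doping_calibration:
    v_half: -0.35               # V vs Ag/AgCl, bias of half doping
    v_width: 0.12               # V, logistic transition width

geometry:
  cap_diameter_nm: 1000.0
  stem_diameter_nm: 250.0
  stem_height_nm: 50.0

medium:
  eps: 1.77                     # water, visible range

# Interface circuit defaults per cap diameter (um). c_p scales with polymer
# volume; r_p is then fixed by the measured charging time constants
# (6.0 / 34.7 / 233.9 ms for 0.7 / 1.4 / 1.8 um caps at optimal bias).
circuit:
  default: {r_s_ohm: 1.0e+4, r_p_ohm: 9.9e+5, c_p_farad: 6.0e-9}
  per_cap_um:
    0.7: {r_s_ohm: 1.0e+4, r_p_ohm: 7.49e+6, c_p_farad: 8.0e-10}
    1.4: {r_s_ohm: 1.0e+4, r_p_ohm: 5.41e+6, c_p_farad: 6.4e-9}
    1.8: {r_s_ohm: 1.0e+4, r_p_ohm: 1.719e+7, c_p_farad: 1.36e-8}
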