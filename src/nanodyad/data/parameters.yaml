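# nanodyad default parameters, version 1.
# Internal units: length nm, time ms, concentration mM, potential mV,
# conductance zS, capacitance yF/nm^2.  This file mirrors the in-code
# defaults; it is loaded and cross-checked at import time of the scenario
# registry and may be copied and edited as a base for custom runs.
version: 1

constants:
  F: 96485.3365          # Faraday constant, C/mol
  eps0: 8854.0           # vacuum permittivity, fF/m
  e: 1.60217662e-19      # elementary charge, C
  kB: 1.380649e-20       # Boltzmann constant, mJ/K
  T: 310.0               # temperature, K

permittivity:
  bulk: 80.0             # relative permittivity in the intra/extracellular space
  membrane: 2.0          # relative permittivity in the membrane

species:                 # valence, diffusivities (nm^2/ms), initial conc. (mM)
  Na: {z: 1,  De: 1.33e+6, Di: 0.37e+6, c0e: 100.0,  c0i: 12.0}
  K:  {z: 1,  De: 1.96e+6, Di: 0.55e+6, c0e: 5.0,    c0i: 125.0}
  Ca: {z: 2,  De: 0.71e+6, Di: 0.20e+6, c0e: 1.4,    c0i: 1.0e-4}
  Cl: {z: -1, De: 2.03e+6, Di: 0.57e+6, c0e: 107.8,  c0i: 15.0}

buffers:                 # stationary intracellular Ca2+ buffers
  high_affinity: {target: Ca, Btot: 0.20, kon: 100.0, koff: 0.03}
  low_affinity:  {target: Ca, Btot: 0.56, kon: 100.0, koff: 1.3}

geometry:                # nm
  Le: 100.0              # extracellular (T-tubule) depth along x
  Lm: 5.0                # membrane thickness
  Li: 7.0                # intracellular (dyad) width, membrane to SR
  Ly: 1000.0
  Lz: 1000.0
  wc: 4.0                # channel/exchanger patch edge length

channels:                # single-channel conductances, zS
  K: 5.0e+9
  Na: 20.0e+9
  Ca: 8.0e+9

ncx:
  Ibar: 4.9              # scaling current density, A/F
  delta: 4.0e-4          # NCX surface density, 1/nm^2
  Cm: 10000.0            # specific membrane capacitance, yF/nm^2
  nu: 0.3                # energy-barrier position
  ksat: 0.3              # saturation factor
  Kact: 0.00015          # allosteric Ca activation constant, mM
  KCai: 0.0036           # half-saturation constants, mM
  KCae: 1.3
  KNai: 12.3
  KNae: 87.5
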