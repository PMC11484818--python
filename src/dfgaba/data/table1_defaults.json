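{
  "constants": {
    "F": {"value": 96485.33, "unit": "C/mol", "description": "Faraday constant"},
    "R": {"value": 8.31446, "unit": "J/(K.mol)", "description": "Universal gas constant"},
    "T": {"value": 310.15, "unit": "K", "description": "Absolute temperature (37 C)"}
  },
  "parameters": {
    "radius": {"value": 5, "unit": "um", "description": "Radius of the compartment"},
    "length": {"value": 25, "unit": "um", "description": "Length of the compartment"},
    "Cm": {"value": 2e-06, "unit": "F/cm^2", "description": "Unit membrane capacitance"},
    "g_Na": {"value": 25, "unit": "uS/cm^2", "description": "Na+ leak conductance"},
    "g_K": {"value": 70, "unit": "uS/cm^2", "description": "K+ leak conductance"},
    "g_Cl": {"value": 20, "unit": "uS/cm^2", "description": "Cl- leak conductance"},
    "g_HCO3": {"value": 4, "unit": "uS/cm^2", "description": "HCO3- leak conductance"},
    "g_KCC2": {"value": 20, "unit": "uS/cm^2", "description": "KCC2 conductance"},
    "vw": {"value": 0.018, "unit": "dm^3/mol", "description": "Partial molar volume of water"},
    "pw": {"value": 0.0015, "unit": "dm/s", "description": "Osmotic permeability"},
    "P": {"value": 0.1, "unit": "C/(dm^2.s)", "description": "ATPase pump rate constant"},
    "PCO2": {"value": 0.05, "unit": "atm", "description": "Partial pressure of CO2"},
    "kH": {"value": 0.031, "unit": "M/atm", "description": "Henry's law constant for CO2 in water"},
    "Kf": {"value": 1000.0, "unit": "1/s", "description": "Forward rate constant"},
    "Kr": {"value": 2539000000.0, "unit": "1/(s.M)", "description": "Reverse rate constant"},
    "g_GABAA_max": {"value": 10, "unit": "nS", "description": "Maximum conductance of GABA-A receptors"},
    "tau": {"value": 250, "unit": "ms", "description": "Alpha-function time constant"},
    "pKa": {"value": 6.1, "unit": "", "description": "Dissociation constant of H2CO3"},
    "pH_o": {"value": 7.4, "unit": "", "description": "Extracellular pH"},
    "pH_i": {"value": 7.2, "unit": "", "description": "Intracellular pH"},
    "K_o": {"value": 3.5, "unit": "mM", "description": "Extracellular K+ concentration"},
    "Na_o": {"value": 145, "unit": "mM", "description": "Extracellular Na+ concentration"},
    "Cl_o": {"value": 110, "unit": "mM", "description": "Extracellular Cl- concentration"},
    "HCO3_o": {"value": 31, "unit": "mM", "description": "Extracellular HCO3- concentration"},
    "H2CO3_o": {"value": 1.55, "unit": "mM", "description": "Extracellular H2CO3 concentration"},
    "H2CO3_i": {"value": 1.55, "unit": "mM", "description": "Intracellular H2CO3 concentration"},
    "X_o": {"value": 7.5, "unit": "mM", "description": "Extracellular impermeant anion concentration"},
    "z_o": {"value": -1, "unit": "", "description": "Extracellular impermeant anion average charge"},
    "z_i": {"value": -0.85, "unit": "", "description": "Intracellular impermeant anion average charge"}
  },
  "initial_state": {
    "K_i": {"value": 122.6, "unit": "mM", "description": "Initial intracellular K+ concentration"},
    "Na_i": {"value": 15, "unit": "mM", "description": "Initial intracellular Na+ concentration"},
    "Cl_i": {"value": 5.3, "unit": "mM", "description": "Initial intracellular Cl- concentration"},
    "HCO3_i": {"value": 9.7, "unit": "mM", "description": "Initial intracellular HCO3- concentration"},
    "X_i": {"value": 144.4, "unit": "mM", "description": "Initial intracellular impermeant anion concentration"},
    "Vm": {"value": -67.2, "unit": "mV", "description": "Initial membrane potential"},
    "w": {"value": 19, "unit": "pL", "description": "Compartment volume as printed; inconsistent with the cylinder geometry, retained as metadata only"}
  }
}
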