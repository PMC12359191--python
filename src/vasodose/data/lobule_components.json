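{
  "comment": "Microscale lobule components: target mass fractions (percent of lobule mass), reference per-component masses (g), densities (g/cm^3) and composition assignment. 'composition_printed' follows the printed per-component table; 'composition_text' follows the narrative rule (blood-containing regions get blood, bile/interstitial get plasma_lymph, cells get the fitted cell material).",
  "percent": true,
  "total_mass_g": 8.22e-05,
  "components": {
    "central_vein":    {"mass_g": 1.23e-06, "mass_fraction": 1.50,  "density": 1.060, "composition_printed": "blood",        "composition_text": "blood",        "class": "blood"},
    "portal_arteries": {"mass_g": 5.04e-08, "mass_fraction": 0.06,  "density": 1.060, "composition_printed": "blood",        "composition_text": "blood",        "class": "blood"},
    "portal_veins":    {"mass_g": 4.50e-07, "mass_fraction": 0.55,  "density": 1.060, "composition_printed": "blood",        "composition_text": "blood",        "class": "blood"},
    "bile_ducts":      {"mass_g": 7.12e-08, "mass_fraction": 0.09,  "density": 1.000, "composition_printed": "plasma_lymph", "composition_text": "plasma_lymph", "class": "parenchyma"},
    "bile_canaliculi": {"mass_g": 4.36e-06, "mass_fraction": 5.30,  "density": 1.000, "composition_printed": "blood",        "composition_text": "plasma_lymph", "class": "parenchyma"},
    "sinusoids":       {"mass_g": 1.26e-05, "mass_fraction": 15.38, "density": 1.060, "composition_printed": "plasma_lymph", "composition_text": "blood",        "class": "blood"},
    "space_of_disse":  {"mass_g": 2.77e-06, "mass_fraction": 3.37,  "density": 1.000, "composition_printed": "plasma_lymph", "composition_text": "plasma_lymph", "class": "parenchyma"},
    "kupffer_cells":   {"mass_g": 1.05e-07, "mass_fraction": 0.13,  "density": 1.068, "composition_printed": "cell",         "composition_text": "cell",         "class": "parenchyma"},
    "hepatocytes":     {"mass_g": 6.05e-05, "mass_fraction": 73.63, "density": 1.068, "composition_printed": "cell",         "composition_text": "cell",         "class": "parenchyma"}
  }
}
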