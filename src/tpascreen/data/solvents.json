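{
  "comment": "Solvent polarity constants: ET(30) in kcal/mol (Reichardt's betaine-30 scale), static dielectric constant at 20-25 C, gas-phase dipole moment in Debye. Sources: Reichardt, Chem. Rev. 1994, 94, 2319; CRC Handbook of Chemistry and Physics, 97th ed.",
  "solvents": {
    "toluene":              {"et30": 33.9, "dielectric": 2.38,  "dipole": 0.36},
    "benzene":              {"et30": 34.3, "dielectric": 2.27,  "dipole": 0.0},
    "chloroform":           {"et30": 39.1, "dielectric": 4.81,  "dipole": 1.04},
    "dichloromethane":      {"et30": 40.7, "dielectric": 8.93,  "dipole": 1.60},
    "1,2-dichloroethane":   {"et30": 41.3, "dielectric": 10.36, "dipole": 1.83},
    "carbon tetrachloride": {"et30": 32.4, "dielectric": 2.24,  "dipole": 0.0},
    "tetrahydrofuran":      {"et30": 37.4, "dielectric": 7.58,  "dipole": 1.63},
    "1,4-dioxane":          {"et30": 36.0, "dielectric": 2.25,  "dipole": 0.45},
    "dimethyl sulfoxide":   {"et30": 45.1, "dielectric": 46.7,  "dipole": 3.96},
    "n,n-dimethylformamide":{"et30": 43.2, "dielectric": 36.7,  "dipole": 3.82},
    "n,n-dimethylacetamide":{"et30": 42.9, "dielectric": 37.8,  "dipole": 3.72},
    "acetonitrile":         {"et30": 45.6, "dielectric": 37.5,  "dipole": 3.92},
    "acetone":              {"et30": 42.2, "dielectric": 20.7,  "dipole": 2.88},
    "ethyl acetate":        {"et30": 38.1, "dielectric": 6.02,  "dipole": 1.78},
    "methanol":             {"et30": 55.4, "dielectric": 32.7,  "dipole": 1.70},
    "ethanol":              {"et30": 51.9, "dielectric": 24.5,  "dipole": 1.69},
    "2-propanol":           {"et30": 48.4, "dielectric": 19.9,  "dipole": 1.66},
    "water":                {"et30": 63.1, "dielectric": 78.36, "dipole": 1.85},
    "hexane":               {"et30": 31.0, "dielectric": 1.88,  "dipole": 0.0},
    "cyclohexane":          {"et30": 30.9, "dielectric": 2.02,  "dipole": 0.0},
    "pyridine":             {"et30": 40.5, "dielectric": 12.4,  "dipole": 2.19},
    "chlorobenzene":        {"et30": 36.8, "dielectric": 5.62,  "dipole": 1.69}
  },
  "aliases": {
    "dcm": "dichloromethane",
    "methylene chloride": "dichloromethane",
    "ch2cl2": "dichloromethane",
    "chcl3": "chloroform",
    "thf": "tetrahydrofuran",
    "dmso": "dimethyl sulfoxide",
    "dmf": "n,n-dimethylformamide",
    "dimethylformamide": "n,n-dimethylformamide",
    "dmac": "n,n-dimethylacetamide",
    "dma": "n,n-dimethylacetamide",
    "mecn": "acetonitrile",
    "acn": "acetonitrile",
    "ch3cn": "acetonitrile",
    "meoh": "methanol",
    "etoh": "ethanol",
    "ipa": "2-propanol",
    "isopropanol": "2-propanol",
    "h2o": "water",
    "ccl4": "carbon tetrachloride",
    "dioxane": "1,4-dioxane",
    "dce": "1,2-dichloroethane",
    "phcl": "chlorobenzene",
    "n-hexane": "hexane",
    "etoac": "ethyl acetate",
    "ethylacetate": "ethyl acetate"
  }
}
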