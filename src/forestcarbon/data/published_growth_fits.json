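{
  "description": "Published climate-augmented biomass-age growth model fits for the 15 primary forest types of China (national field-survey compilation, 1978-2020). family: MM = Michaelis-Menten, MO = monomolecular, L = logistic. mu in Mg/ha; k in years; alpha in 1/yr; a in Mg/ha per degC; b in Mg/ha per mm; d in Mg/ha.",
  "fits": [
    {"label": "DBF in north subtropical humid region", "n": 66, "family": "L", "rmse": 36.9, "r2": 0.58, "aic": 488.3, "mu": 86.59, "c": 840000.0, "alpha": 0.88, "a": -6.14, "b": 0.04, "d": 91.63},
    {"label": "DBF in plateau temperate semi-arid region", "n": 24, "family": "MM", "rmse": 26.3, "r2": 0.89, "aic": 168.9, "mu": 59.98, "k": 357.71, "a": 0.093, "b": -170.86, "d": 206.63},
    {"label": "DBF in tropical humid region", "n": 21, "family": "MO", "rmse": 12.2, "r2": 0.74, "aic": 115.2, "mu": 205.882, "c": 1.0, "alpha": 0.30, "a": -31.61, "b": -0.055, "d": 74.91},
    {"label": "DBF in warm/mid-temperate region", "n": 132, "family": "MM", "rmse": 30.1, "r2": 0.52, "aic": 909.1, "mu": 79.98, "k": 228.93, "a": -1.897, "b": 0.45, "d": 106.18},
    {"label": "DNF", "n": 159, "family": "MM", "rmse": 22.2, "r2": 0.40, "aic": 995.3, "mu": 58.70, "k": 167.44, "a": -0.98, "b": 0.04, "d": -27.41},
    {"label": "EBF in plateau semi-arid region", "n": 19, "family": "MM", "rmse": 18.0, "r2": 0.67, "aic": 118.0, "mu": 7.27, "k": 193.04, "a": -4.51, "b": -0.02, "d": 36.09},
    {"label": "EBF in tropical humid region", "n": 154, "family": "MM", "rmse": 26.7, "r2": 0.57, "aic": 1021.8, "mu": 21.43, "k": 218.53, "a": 0.54, "b": -0.01, "d": 10.34},
    {"label": "EBF in temperate/subtropical humid/sub-humid region", "n": 112, "family": "MM", "rmse": 59.1, "r2": 0.34, "aic": 923.36, "mu": 84.95, "k": 343.12, "a": 2.01, "b": 0.04, "d": -54.96},
    {"label": "ENF in mid-temperate arid/semi-arid region", "n": 68, "family": "MM", "rmse": 19.9, "r2": 0.81, "aic": 416.7, "mu": 47.51, "k": 406.95, "a": 6.36, "b": 0.20, "d": -223.52},
    {"label": "ENF in mid-temperate sub-humid region", "n": 68, "family": "MM", "rmse": 32.9, "r2": 0.71, "aic": 485.3, "mu": 3.33, "k": 1000.00, "a": 2.80, "b": 0.19, "d": -941.05},
    {"label": "ENF in north subtropical humid region", "n": 595, "family": "MM", "rmse": 37.9, "r2": 0.59, "aic": 4335.4, "mu": 49.91, "k": 442.58, "a": 3.38, "b": 0.02, "d": -113.53},
    {"label": "ENF in plateau temperate semi-arid region", "n": 36, "family": "MM", "rmse": 29.2, "r2": 0.84, "aic": 252.9, "mu": 44.43, "k": 288.43, "a": 3.70, "b": 0.06, "d": -91.78},
    {"label": "ENF in tropical humid region", "n": 59, "family": "MM", "rmse": 19.1, "r2": 0.71, "aic": 357.8, "mu": 40.63, "k": 273.84, "a": 6.12, "b": -0.02, "d": -106.07},
    {"label": "ENF in warm temperate sub-humid region", "n": 109, "family": "L", "rmse": 15.3, "r2": 0.42, "aic": 607.1, "mu": 49.54, "c": 210000.0, "alpha": 0.72, "a": 0.72, "b": -0.81, "d": -0.01},
    {"label": "MF", "n": 72, "family": "MM", "rmse": 13.0, "r2": 0.74, "aic": 348.9, "mu": 9.48, "k": 176.50, "a": 1.99, "b": 0.01, "d": -90.84}
  ]
}
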