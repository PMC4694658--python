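# Percentage of damaging flood/landslide events for each region and weather
# type (WT), 1948-2003. Values are stored verbatim from the source table with
# one correction: the Veneto/WT7 entry is printed there as "041", an obvious
# typographic slip for 0.41, and is stored as 0.41.
# Note: columns do not sum to 100; the normalization basis of these
# percentages is not stated by the source. The risk_index module treats them
# as proportional per-region event weights, where min-max rescaling makes any
# global scale factor irrelevant.
region,wt1,wt2,wt3,wt4,wt5,wt6,wt7,wt8
Abruzzo,0.24,0.16,0.17,0.08,0.14,5.56,0.46,0.32
Basilicata,0.29,0.48,0.56,0.36,0.39,0,0.60,0.21
Calabria,0.39,0.34,0.65,0.24,0.45,5.56,0.64,0.16
Campania,0.92,1.79,1.68,1.15,1.44,0,1.20,2.31
Emilia Romagna,0.15,0.27,0.30,0.28,0.18,0,0.32,0.86
Friuli Venezia Giulia,0.15,0.32,0.39,0.12,0.10,0,0.18,0.97
Lazio,0.44,0.77,0.43,0.84,0.45,0,0.60,1.77
Liguria,0.29,0.23,0.60,0.84,0.26,0,0.09,1.23
Lombardy,0.05,0.48,0.65,1.07,0.49,0,0.23,2.68
Marche,0.24,0.20,0.17,0.08,0.20,0,0.51,0.38
Molise,0.05,0.07,0.04,0.04,0.06,0,0.05,0.11
Piedmont,0.10,0.27,0.60,0.64,0.47,0,0.37,2.47
Puglia,0.63,0.36,0.43,0.24,0.53,0,0.78,0.59
Sardinia,0.44,0.64,1.12,0.56,0.79,0,0.78,1.39
Sicily,0.73,0.36,0.39,0.44,0.49,0,1.01,0.64
Toscany,0.34,0.61,0.69,0.52,0.28,0,0.37,1.34
Trentino Alto Adige,0.24,0.55,0.47,0.32,0.28,0,0.32,1.45
Umbria,0.44,0.45,0.13,0.12,0.12,0,0.18,0.54
Veneto,0.34,0.59,0.43,0.28,0.28,0,0.41,1.45
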