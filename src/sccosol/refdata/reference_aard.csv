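# Published per-drug AARD% of eleven density-based solubility correlations
# fitted to the twelve anti-cancer drug / supercritical CO2 datasets.
# The "overall" row is the published pooled value over all 316 measurements.
drug_id,modified_arrhenius,chrastil,jouyban,kumar_johnston,garlapati_madras,bian,bartle,mendez_santiago_teja,sodeifian,tan,gordillo
sorafenib-tosylate,7.91,13.90,14.40,12.70,11.00,10.30,13.70,15.30,10.10,52.21,95.85
sunitinib-malate,3.89,21.26,14.20,38.85,17.16,21.07,26.11,24.68,12.16,54.69,91.67
azathioprine,4.29,9.88,10.21,16.26,8.62,8.40,12.22,10.70,8.04,13.72,84.91
busulfan,7.41,11.20,88.70,7.57,11.20,6.55,11.70,10.70,25.99,32.48,96.87
tamoxifen,12.02,16.50,96.87,11.10,16.40,8.84,16.10,16.00,58.03,45.91,96.87
letrozole,13.21,22.16,21.50,39.42,7.14,10.42,46.61,15.40,26.66,39.20,95.00
tamsulosin,9.27,22.11,82.70,15.20,24.91,14.24,17.08,16.98,13.64,29.07,95.83
capecitabine,11.42,12.20,11.90,10.30,43.48,33.00,12.80,9.90,41.47,9.10,20.50
paclitaxel,9.69,28.90,80.95,38.89,11.79,15.96,50.09,55.31,9.26,18.44,95.23
5-fluorouracil,8.39,19.48,69.90,19.48,22.77,15.59,35.34,31.98,13.86,25.52,82.99
thymidine,16.64,25.10,91.77,29.86,32.48,19.68,46.90,40.32,22.31,32.78,96.00
decitabine,9.11,15.30,88.88,9.04,15.30,8.82,15.30,13.30,80.01,49.18,96.88
overall,9.54,17.42,56.51,18.97,19.64,14.90,23.24,20.01,30.05,33.19,84.66
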