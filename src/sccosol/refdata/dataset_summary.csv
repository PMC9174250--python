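# Published operating envelopes and measurement counts for the solubility of
# twelve anti-cancer drugs in supercritical CO2 (316 measurements in total).
# Solubility columns carry the mole fraction scaled by 1e6.
drug_id,T_min_K,T_max_K,P_min_MPa,P_max_MPa,rho_min_kg_m3,rho_max_kg_m3,y2e6_min,y2e6_max,n_data
sorafenib-tosylate,308,338,12,27,388,914,0.68,12.57,24
sunitinib-malate,308,338,12,27,388,914,5,85.6,24
azathioprine,308,338,12,27,388,914,2.7,18.3,24
busulfan,308,338,12,40,383,971,32.7,865,32
tamoxifen,308,338,12,40,383,971,18.8,989,32
letrozole,318,348,12,36,319,922,1.6,85.1,20
tamsulosin,308,338,12,27,384,914,0.18,10.13,24
capecitabine,308,348,15.2,35.4,477,955,2.7,158.8,40
paclitaxel,308,328,10,27.5,654,915,1.2,6.22,21
5-fluorouracil,308,328,12.5,25,541,901,3.8,14.6,18
thymidine,308,328,10,30,325,928,1.2,82,25
decitabine,308,338,12,40,383,971,28.4,1070,32
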