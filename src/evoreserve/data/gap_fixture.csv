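feature,kind,status,total,target,cat0,cat1,cat2,cat3,modelled
CHmo,species,NT,292535,10.3,2947,73689,210830,5069,1
DIvi,species,LC,136499,15.9,1434,22567,109478,3020,1
DIvi_1,lineage,,89221,19.5,1372,13703,71175,2971,1
DIvi_2,lineage,,104923,18.1,1434,17771,83747,1971,1
HAri,species,LC,276256,10.7,2834,60715,207751,4956,1
HAri_1,lineage,,201130,12.9,2834,54848,139228,4220,1
HAri_2,lineage,,209015,12.6,2445,50538,152498,3534,1
HAtr,species,LC,235772,11.8,3134,76541,152539,3558,1
HAtr_1,lineage,,224772,12.1,3134,76541,141539,3558,1
HAtr_2,lineage,,70733,21.7,0,14725,53721,2287,1
HEdr,species,CR,2275,100.0,0,0,1833,442,1
HEgr,species,NT,4623,90.4,0,0,2908,1715,1
HEHo,species,NE,276100,10.7,2915,66317,201666,5202,1
HEHo_1,lineage,,64989,22.5,2529,21287,38387,2786,1
HEHo_2,lineage,,128216,16.4,2262,19242,103189,3523,1
HEHo_3,lineage,,191269,13.3,538,46114,141186,3431,1
HEin,species,LC,187232,13.4,1756,33352,148103,4021,1
HEin_1,lineage,,60720,23.2,1630,18974,38799,1317,1
HEin_2,lineage,,146717,15.3,1630,28482,113327,3278,1
HEin_3,lineage,,45783,26.3,0,11396,33195,1192,1
HEin_4,lineage,,84544,20.0,304,20665,62774,801,1
HEin_5,lineage,,41857,27.4,1630,12144,26813,1270,1
HEpu,species,LC,184829,13.5,2849,57635,121274,3071,1
HEpu_1,lineage,,151231,15.1,2849,46171,99848,2363,1
HEpu_2,lineage,,74310,21.2,2816,22010,47913,1571,1
HEpu_3,lineage,,36042,29.2,2474,9602,22992,974,1
HEpu_4,lineage,,28345,32.4,612,10755,16334,644,1
HEpu_5,lineage,,22302,36.0,375,4835,16348,744,1
HEpu_6,lineage,,31227,31.0,0,5315,25910,2,1
HKsi,species,NT,57770,23.8,1228,6738,48045,1759,1
HKsi_1,lineage,,57526,23.8,1226,6721,47820,1759,1
HKsi_2,lineage,,24716,34.4,864,5683,18071,98,1
HMso,species,NT,99927,18.5,2597,62166,33695,1469,1
MEba,species,LC,305669,10.0,3150,82315,214514,5690,1
MEba_1,lineage,,302942,10.1,3150,82124,211978,5690,1
MEba_2,lineage,,90147,19.4,455,14125,74563,1004,1
MYfi,species,DD,1,100.0,0,1,0,0,0
MYma,species,DD,150436,15.1,2024,49215,98343,854,1
MYma_1,lineage,,147860,15.2,2024,49214,95822,800,1
MYma_2,lineage,,136390,15.9,1634,39785,94117,854,1
MYwi,species,DD,5,100.0,0,0,5,0,0
PAbr,species,DD,9626,83.6,924,5847,2833,22,1
PRgu,species,LC,86085,19.8,955,9394,73432,2304,1
PRid,species,LC,4329,97.8,0,0,2647,1682,1
PRin,species,LC,250861,11.3,1992,50522,193202,5145,1
PRin_1,lineage,,220379,12.2,1992,50245,163958,4184,1
PRin_2,lineage,,75194,21.1,224,15328,57633,2009,1
PRin_3,lineage,,132040,16.1,219,31207,98746,1868,1
PRob,species,LC,140257,15.7,2704,60278,75177,2098,1
PRso,species,LC,268762,10.9,2800,65578,194858,5526,1
PRso_1,lineage,,86988,19.7,2470,21573,59679,3266,1
PRso_2,lineage,,160917,14.6,2266,35332,119640,3679,1
PRso_3,lineage,,159275,14.7,330,47553,109545,1847,1
TRso,species,LC,248971,11.4,2865,67633,173417,5056,1
TRso_1,lineage,,236304,11.8,1733,67301,163445,3825,1
TRso_2,lineage,,180283,13.7,2621,36674,136050,4938,1
XEso,species,DD,5,100.0,0,1,4,0,0
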