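drug,class,severity_grade,incidence,cmax_uM,route,model,assay,ic15_uM,ic50_uM,pct_reduction
Paclitaxel,cell-cycle inhibitor,2,very common,5.1,intravenous,hIEC,TEER,2.71,15.33,89.51
Paclitaxel,cell-cycle inhibitor,2,very common,5.1,intravenous,Caco-2,TEER,7.04,39.91,76.32
Paclitaxel,cell-cycle inhibitor,2,very common,5.1,intravenous,hIEC,ATP,8.01,45.41,60.91
Paclitaxel,cell-cycle inhibitor,2,very common,5.1,intravenous,Caco-2,ATP,69.00,391.00,19.38
Docetaxel,cell-cycle inhibitor,3,very common,5.1,intravenous,hIEC,TEER,4.36,24.69,91.28
Docetaxel,cell-cycle inhibitor,3,very common,5.1,intravenous,Caco-2,TEER,19.25,109.10,50.38
Docetaxel,cell-cycle inhibitor,3,very common,5.1,intravenous,hIEC,ATP,88.94,504.00,10.69
Docetaxel,cell-cycle inhibitor,3,very common,5.1,intravenous,Caco-2,ATP,291.18,1650.00,1.71
Capecitabine,cell-cycle inhibitor,3,very common,13.7,oral,hIEC,TEER,5.74,32.52,79.92
Capecitabine,cell-cycle inhibitor,3,very common,13.7,oral,Caco-2,TEER,10.27,58.21,70.45
Capecitabine,cell-cycle inhibitor,3,very common,13.7,oral,hIEC,ATP,62.59,354.70,18.49
Capecitabine,cell-cycle inhibitor,3,very common,13.7,oral,Caco-2,ATP,>100,>100,-10.35
Cyclophosphamide,cell-cycle inhibitor,2,common,122.0,oral,hIEC,TEER,7.40,41.91,67.94
Cyclophosphamide,cell-cycle inhibitor,2,common,122.0,oral,Caco-2,TEER,22.84,129.40,44.51
Cyclophosphamide,cell-cycle inhibitor,2,common,122.0,oral,hIEC,ATP,40.50,229.50,29.32
Cyclophosphamide,cell-cycle inhibitor,2,common,122.0,oral,Caco-2,ATP,>100,>100,-15.13
Cisplatin,cell-cycle inhibitor,1,very common,14.8,intravenous,hIEC,TEER,30.49,172.80,36.84
Cisplatin,cell-cycle inhibitor,1,very common,14.8,intravenous,Caco-2,TEER,44.45,251.90,31.31
Cisplatin,cell-cycle inhibitor,1,very common,14.8,intravenous,hIEC,ATP,2.62,14.84,78.90
Cisplatin,cell-cycle inhibitor,1,very common,14.8,intravenous,Caco-2,ATP,7.10,40.26,84.85
5-FU,cell-cycle inhibitor,3,very common,34.1,intravenous,hIEC,TEER,19.31,109.40,65.48
5-FU,cell-cycle inhibitor,3,very common,34.1,intravenous,Caco-2,TEER,17.60,99.74,78.64
5-FU,cell-cycle inhibitor,3,very common,34.1,intravenous,hIEC,ATP,87.78,497.40,22.64
5-FU,cell-cycle inhibitor,3,very common,34.1,intravenous,Caco-2,ATP,74.47,422.00,24.14
Doxorubicin,cell-cycle inhibitor,2,common,7.6,intravenous,hIEC,TEER,1.99,11.28,95.35
Doxorubicin,cell-cycle inhibitor,2,common,7.6,intravenous,Caco-2,TEER,3.08,17.48,94.75
Doxorubicin,cell-cycle inhibitor,2,common,7.6,intravenous,hIEC,ATP,0.28,1.61,76.28
Doxorubicin,cell-cycle inhibitor,2,common,7.6,intravenous,Caco-2,ATP,7.42,42.04,58.92
Gefitinib,TKI,2,very common,0.5,oral,hIEC,TEER,3.80,21.51,90.44
Gefitinib,TKI,2,very common,0.5,oral,Caco-2,TEER,2.41,13.68,98.16
Gefitinib,TKI,2,very common,0.5,oral,hIEC,ATP,5.81,32.95,75.25
Gefitinib,TKI,2,very common,0.5,oral,Caco-2,ATP,2.24,12.72,82.42
Crizotinib,TKI,2,very common,1.0,oral,hIEC,TEER,4.81,27.25,88.04
Crizotinib,TKI,2,very common,1.0,oral,Caco-2,TEER,4.64,26.31,98.27
Crizotinib,TKI,2,very common,1.0,oral,hIEC,ATP,5.70,32.32,82.94
Crizotinib,TKI,2,very common,1.0,oral,Caco-2,ATP,3.78,21.41,86.50
Sunitinib,TKI,2,very common,0.3,oral,hIEC,TEER,3.68,20.87,96.79
Sunitinib,TKI,2,very common,0.3,oral,Caco-2,TEER,7.70,43.61,91.17
Sunitinib,TKI,2,very common,0.3,oral,hIEC,ATP,2.25,12.77,80.96
Sunitinib,TKI,2,very common,0.3,oral,Caco-2,ATP,6.24,35.35,80.57
Sorafenib,TKI,2,very common,6.5,oral,hIEC,TEER,3.36,19.05,87.72
Sorafenib,TKI,2,very common,6.5,oral,Caco-2,TEER,3.77,21.38,93.32
Sorafenib,TKI,2,very common,6.5,oral,hIEC,ATP,3.26,19.32,75.98
Sorafenib,TKI,2,very common,6.5,oral,Caco-2,ATP,19.82,112.30,43.81
Lapatinib,TKI,3,very common,4.2,oral,hIEC,TEER,5.44,30.82,80.26
Lapatinib,TKI,3,very common,4.2,oral,Caco-2,TEER,2.98,16.89,93.56
Lapatinib,TKI,3,very common,4.2,oral,hIEC,ATP,3.48,19.73,79.81
Lapatinib,TKI,3,very common,4.2,oral,Caco-2,ATP,3.64,20.63,79.31
Ibuprofen,NSAID,1,common,145.0,oral,hIEC,TEER,>100,>100,-8.14
Ibuprofen,NSAID,1,common,145.0,oral,Caco-2,TEER,>100,>100,-23.28
Ibuprofen,NSAID,1,common,145.0,oral,hIEC,ATP,>100,>100,1.75
Ibuprofen,NSAID,1,common,145.0,oral,Caco-2,ATP,59.49,337.10,24.28
Diclofenac,NSAID,1,common,5.0,oral,hIEC,TEER,43.52,246.60,23.83
Diclofenac,NSAID,1,common,5.0,oral,Caco-2,TEER,1018.24,5770.00,0.99
Diclofenac,NSAID,1,common,5.0,oral,hIEC,ATP,>100,>100,3.31
Diclofenac,NSAID,1,common,5.0,oral,Caco-2,ATP,110.47,626.00,16.63
Naproxen,NSAID,1,common,313.0,oral,hIEC,TEER,7.90,44.75,47.84
Naproxen,NSAID,1,common,313.0,oral,Caco-2,TEER,37.01,209.70,54.68
Naproxen,NSAID,1,common,313.0,oral,hIEC,ATP,177.71,1007.00,14.01
Naproxen,NSAID,1,common,313.0,oral,Caco-2,ATP,42.25,239.40,34.81
Ketoprofen,NSAID,1,common,10.8,oral,hIEC,TEER,14.11,79.98,49.84
Ketoprofen,NSAID,1,common,10.8,oral,Caco-2,TEER,25.50,144.50,59.11
Ketoprofen,NSAID,1,common,10.8,oral,hIEC,ATP,150.74,854.20,17.00
Ketoprofen,NSAID,1,common,10.8,oral,Caco-2,ATP,30.46,172.60,38.82
Ketorolac,NSAID,4,uncommon,11.0,oral,hIEC,TEER,134.29,761.00,10.60
Ketorolac,NSAID,4,uncommon,11.0,oral,Caco-2,TEER,156.05,884.30,14.63
Ketorolac,NSAID,4,uncommon,11.0,oral,hIEC,ATP,150.74,854.20,17.00
Ketorolac,NSAID,4,uncommon,11.0,oral,Caco-2,ATP,34.82,197.30,30.03
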