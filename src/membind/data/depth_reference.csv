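site,composition,phi,phi_err,distance_A
173,20% PtdSer,1.20,0.10,8.8
173,5% PtdIns(4:5)P2,-0.01,0.20,5.5
173,10% PtdSer + 2.5% PtdIns(4:5)P2,0.66,0.10,7.4
234,20% PtdSer,-0.10,0.10,5.2
234,5% PtdIns(4:5)P2,-1.50,0.03,-0.6
234,10% PtdSer + 2.5% PtdIns(4:5)P2,0.00,0.10,5.5
304,20% PtdSer,-0.39,0.20,4.3
304,5% PtdIns(4:5)P2,-1.30,0.10,0.6
304,10% PtdSer + 2.5% PtdIns(4:5)P2,-0.23,0.10,4.8
329,20% PtdSer,-2.00,0.14,-5.4
329,5% PtdIns(4:5)P2,-0.80,0.14,2.8
329,10% PtdSer + 2.5% PtdIns(4:5)P2,-2.10,0.12,-7.3
368,20% PtdSer,0.60,0.10,7.2
368,5% PtdIns(4:5)P2,-0.64,0.05,3.6
368,10% PtdSer + 2.5% PtdIns(4:5)P2,0.18,0.10,6.0
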