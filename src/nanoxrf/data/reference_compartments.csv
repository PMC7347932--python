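condition,neuron,compartment,element,am_ng_cm2,c_ppm,eps_pct
CTRL,1,nucleus,Fe,10,200.9,14.0
CTRL,1,nucleolus,Fe,14.3,286.3,13.3
CTRL,1,cytoplasm,Fe,7.7,154.6,13.5
CTRL,1,granules,Fe,11,,13.6
CTRL,1,nucleus,Ca,1.2,24.5,16.7
CTRL,1,nucleolus,Ca,1.5,29.4,13.3
CTRL,1,cytoplasm,Ca,2.5,50.3,13.7
CTRL,1,granules,Ca,2.8,,14.3
CTRL,1,nucleus,S,59.2,1183.8,16.9
CTRL,1,nucleolus,S,61.8,1235.7,16.8
CTRL,1,cytoplasm,S,66.6,1332.7,16.9
CTRL,1,granules,S,98.2,,16.9
CTRL,1,nucleus,P,79,1579.4,20.6
CTRL,1,nucleolus,P,97.9,1958.9,20.7
CTRL,1,cytoplasm,P,112.8,2256.3,20.7
CTRL,1,granules,P,86,,20.7
CTRL,2,nucleus,Fe,9.8,196.9,13.3
CTRL,2,nucleolus,Fe,19.6,391.8,13.3
CTRL,2,cytoplasm,Fe,7.6,152.5,13.5
CTRL,2,granules,Fe,10.6,,13.2
CTRL,2,nucleus,Ca,1.2,24.6,16.7
CTRL,2,nucleolus,Ca,1.9,38.3,15.8
CTRL,2,cytoplasm,Ca,2.5,49.2,13.6
CTRL,2,granules,Ca,2.7,,14.8
CTRL,2,nucleus,S,60.7,1213.1,16.8
CTRL,2,nucleolus,S,78.9,1577.1,16.9
CTRL,2,cytoplasm,S,72.3,1447,16.9
CTRL,2,granules,S,107.3,,16.9
CTRL,2,nucleus,P,78,1559.5,20.6
CTRL,2,nucleolus,P,155.1,3102.4,20.7
CTRL,2,cytoplasm,P,100.9,2018.7,20.7
CTRL,2,granules,P,78.3,,20.7
ASYN,1,nucleus,Fe,8.9,178.6,13.5
ASYN,1,nucleolus,Fe,14.3,285.6,13.3
ASYN,1,cytoplasm,Fe,8.5,169.1,13.5
ASYN,1,granules,Fe,22.9,,13.5
ASYN,1,nucleus,Ca,1.1,22,18.2
ASYN,1,nucleolus,Ca,1.9,37.6,15.8
ASYN,1,cytoplasm,Ca,2.2,43.2,13.7
ASYN,1,granules,Ca,2.6,,15.4
ASYN,1,nucleus,S,47.9,957.3,16.9
ASYN,1,nucleolus,S,58.2,1164,16.8
ASYN,1,cytoplasm,S,60.7,1214.7,16.9
ASYN,1,granules,S,66.1,,16.9
ASYN,1,nucleus,P,72.8,1455.7,20.7
ASYN,1,nucleolus,P,106.6,2131.8,20.7
ASYN,1,cytoplasm,P,97.4,1948.9,20.7
ASYN,1,granules,P,85.5,,20.7
ASYN,2,nucleus,Fe,8.7,173.4,13.8
ASYN,2,nucleolus,Fe,13.6,272.5,13.2
ASYN,2,cytoplasm,Fe,8.8,175.4,13.5
ASYN,2,granules,Fe,23.3,,13.3
ASYN,2,nucleus,Ca,1.1,21.2,9.1
ASYN,2,nucleolus,Ca,1.7,34.4,11.8
ASYN,2,cytoplasm,Ca,1.9,38.9,13.6
ASYN,2,granules,Ca,2.4,,12.5
ASYN,2,nucleus,S,52.9,1058,16.8
ASYN,2,nucleolus,S,69,1380.7,17.0
ASYN,2,cytoplasm,S,62.7,1254.1,16.9
ASYN,2,granules,S,72.9,,16.9
ASYN,2,nucleus,P,74.6,1492.1,20.6
ASYN,2,nucleolus,P,141.6,2831.9,20.7
ASYN,2,cytoplasm,P,117.4,2347.6,20.7
ASYN,2,granules,P,96.2,,20.7
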