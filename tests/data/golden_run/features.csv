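patient_id,tlnv,tlnd,node_count,volume_mode,no_nodes
sim-00000,62.085451093513896,151.59120189454686,6,accumulated,False
sim-00001,23.795375128118806,130.67696934491056,3,accumulated,False
sim-00002,35.49982848394668,128.86929702579832,5,accumulated,False
sim-00003,23.130676991757454,47.42615036945516,2,accumulated,False
sim-00004,7.875263538498945,16.226704019359552,1,accumulated,False
sim-00005,64.196955276127,104.22450903688568,5,accumulated,False
sim-00006,67.78838121662642,134.54567606581668,5,accumulated,False
sim-00007,28.86761267298541,70.70320116698723,3,accumulated,False
sim-00008,60.07932559717929,123.5700782971446,5,accumulated,False
sim-00009,38.82655109083784,90.81033357138739,3,accumulated,False
sim-00010,31.91553699251929,55.2305746206295,3,accumulated,False
sim-00011,38.03843388446273,91.99502654276587,4,accumulated,False
sim-00012,61.62698378407344,137.00643730860594,5,accumulated,False
sim-00013,80.52840110888219,90.95369175600862,4,accumulated,False
sim-00014,35.10459032045655,85.23818754673613,3,accumulated,False
sim-00015,32.760030562187374,121.07401451043694,3,accumulated,False
sim-00016,9.048647843257942,27.962529624962556,1,accumulated,False
sim-00017,36.589829595580525,59.33697644099537,3,accumulated,False
sim-00018,7.10465942862808,34.95326751747222,1,accumulated,False
sim-00019,39.796928512206804,77.9682400983542,3,accumulated,False
sim-00020,48.27594409671411,140.72791181309313,5,accumulated,False
sim-00021,21.5769263504229,59.36115833719924,3,accumulated,False
sim-00022,54.11326478447568,105.52736330057272,6,accumulated,False
sim-00023,22.638579428148603,54.956832480250526,3,accumulated,False
sim-00024,59.54119731320645,85.81863615890812,3,accumulated,False
sim-00025,48.650025327508295,111.70461488739751,5,accumulated,False
sim-00026,68.94872512540546,79.14039868822887,4,accumulated,False
sim-00027,75.26405606926083,105.84221407010557,5,accumulated,False
sim-00028,65.91236641618197,130.65098622695695,6,accumulated,False
sim-00029,15.028452503935753,35.41380055470172,2,accumulated,False
sim-00030,75.72761664480514,118.86379677486907,5,accumulated,False
sim-00031,31.34493081509628,20.371500794745394,1,accumulated,False
sim-00032,19.050835156690972,17.84947850077665,1,accumulated,False
sim-00033,39.03595909995237,167.38804094402494,5,accumulated,False
sim-00034,61.708057379978484,146.777272001125,5,accumulated,False
sim-00035,49.76546520509727,91.68874862964931,5,accumulated,False
sim-00036,87.4919167272538,64.61909734590967,5,accumulated,False
sim-00037,27.396759225973398,74.52681074135245,2,accumulated,False
sim-00038,69.23398656164203,93.05638663278373,6,accumulated,False
sim-00039,63.955536350020644,183.8436522079018,5,accumulated,False
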