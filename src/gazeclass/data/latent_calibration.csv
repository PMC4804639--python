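group,stimulus,aoi,mu,sigma
ASD,A,eyes,73.882801,33.120597
ASD,A,mouth,10.850051,13.932179
TD,A,eyes,110.264063,43.187615
TD,A,mouth,5.145880,14.220245
ASD,B,eyes,58.602342,61.902132
ASD,B,mouth,22.541568,28.797079
TD,B,eyes,101.098660,43.019075
TD,B,mouth,-73.865941,95.255426
ASD,C,eyes,43.208306,48.935062
ASD,C,mouth,42.671471,40.922936
TD,C,eyes,55.859733,28.358447
TD,C,mouth,29.736895,30.495659
ASD,D,eyes,-250.555494,1376.293936
ASD,D,mouth,46.280011,81.111776
TD,D,eyes,84.740996,60.364993
TD,D,mouth,4.014492,58.502870
ASD,E,eyes,59.103633,169.955904
ASD,E,mouth,49.994010,85.578075
TD,E,eyes,63.028655,46.237670
TD,E,mouth,31.999538,34.836803
ASD,F,upright,266.177167,145.986034
ASD,F,inverted,267.287128,130.311958
TD,F,upright,262.217189,116.748973
TD,F,inverted,255.725351,177.805421
ASD,G,people,199.057288,153.713309
ASD,G,geometry,123.316887,89.698349
TD,G,people,126.216934,6.012605
TD,G,geometry,52.959275,43.417847
ASD,H,geometry,31.541542,26.889868
TD,H,geometry,21.029011,16.759443
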