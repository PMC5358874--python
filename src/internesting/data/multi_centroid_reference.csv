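turtle_id,site,n_centroids,d_1_2,d_2_3,d_3_4
7689,PAIS,2,156.4,,
70700,PAIS,2,71.9,,
82215,PAIS,2,54.5,,
101136,PAIS,2,131.8,,
101137,PAIS,3,99.3,14.3,
101139,PAIS,4,27.1,14.5,8.0
106341,PAIS,2,23.2,,
100391,RNMX,2,29.4,,
100394,RNMX,2,93.1,,
100395,RNMX,2,73.9,,
100403,RNMX,2,369.3,,
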