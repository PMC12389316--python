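gene_a	gene_b	ka	ks	kaks	date_mya	selection	dup_type
Glyma.02G261800	Glyma.18G023900	0.223722	0.618747	0.361573	47.60	Purification or Stabilization selection	WGD or Segmental
Glyma.02G261800	Glyma.U027200	0.0281611	0.117351	0.239974	9.03	Purification or Stabilization selection	WGD or Segmental
Glyma.U027200	Glyma.18G023900	0.223407	0.614387	0.363626	47.26	Purification or Stabilization selection	WGD or Segmental
Glyma.08G339900	Glyma.08G339800	0.219666	0.373098	0.58876	28.70	Purification or Stabilization selection	Tandem
Glyma.08G339900	Glyma.09G229400	0.166574	0.407391	0.40888	31.34	Purification or Stabilization selection	WGD or Segmental
Glyma.08G339900	Glyma.12G006900	0.225172	0.396627	0.567	30.51	Purification or Stabilization selection	WGD or Segmental
Glyma.12G006900	Glyma.09G229400	0.131003	0.173655	0.754383	13.36	Purification or Stabilization selection	WGD or Segmental
Glyma.12G006900	Glyma.08G339800	0.14434	0.301214	0.47919	23.17	Purification or Stabilization selection	WGD or Segmental
Glyma.09G229400	Glyma.08G339800	0.14488	0.309337	0.468356	23.80	Purification or Stabilization selection	WGD or Segmental
Glyma.12G236100	Glyma.13G201800	0.09762	0.31009	0.3148	23.85	Purification or Stabilization selection	WGD or Segmental
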