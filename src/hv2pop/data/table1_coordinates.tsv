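population	longitude_deg	latitude_deg
Armenian	44.51	40.18
Azeri	49.86	40.43
Georgian	41.63	41.63
Kurds-Iraq	44.42	33.32
Russ-Caucasus	39.26	44.17
Turkey	32.85	39.92
Afghan	67.89	38.27
Kazakh	70.15	41.73
Kirgiz	71.66	41.00
Russ-Central-Asia	69.21	41.26
Tajik	67.26	39.18
Turkmen	66.78	38.06
Esfahan	51.67	32.65
Khuzestan	48.68	31.31
Mashhad	59.60	36.30
Shiraz	52.53	29.61
Tehran	51.42	35.69
Yazd	54.36	31.89
Baloch	66.69	30.70
Brahui	66.57	30.60
Burusho	73.84	36.44
Hazara	70.02	33.53
Kalash	71.53	35.98
Makrani	66.00	25.99
Pathan	70.31	33.52
Sindhi	69.04	25.30
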