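# Best-effort grouping assignments for the 26 survey populations.
# geo1_group: west/central/east three-way split; geo2_group: four-way split
# separating Central Asia from Pakistan; linguistic_group: seven language
# families.  Population-to-family membership is not fully documented for
# every sample set; entries here are editable assumptions.
population	geo1_group	geo2_group	linguistic_group
Armenian	western	western	Armenian
Azeri	western	western	Altaic
Georgian	western	western	Karto-Zan
Kurds-Iraq	western	western	Iranian
Russ-Caucasus	western	western	Abkhazo-Adyghean
Turkey	western	western	Altaic
Afghan	eastern	northeastern	Iranian
Kazakh	eastern	northeastern	Altaic
Kirgiz	eastern	northeastern	Altaic
Russ-Central-Asia	eastern	northeastern	Indo-Aryan
Tajik	eastern	northeastern	Iranian
Turkmen	eastern	northeastern	Altaic
Esfahan	central	central	Iranian
Khuzestan	central	central	Semitic
Mashhad	central	central	Iranian
Shiraz	central	central	Iranian
Tehran	central	central	Iranian
Yazd	central	central	Iranian
Baloch	eastern	southeastern	Iranian
Brahui	eastern	southeastern	Iranian
Burusho	eastern	southeastern	Indo-Aryan
Hazara	eastern	southeastern	Iranian
Kalash	eastern	southeastern	Indo-Aryan
Makrani	eastern	southeastern	Iranian
Pathan	eastern	southeastern	Iranian
Sindhi	eastern	southeastern	Indo-Aryan
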