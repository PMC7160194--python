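species	autosomes	sex_system	y_present	exx	nuc	notes
Attinella_concolor	14m	Xm0	no	1	6	all metacentric; Robertsonian fusion series
Attinella_dorsata	26a?	XaXa0?	?	3	11	faded 1980s slides; at least 13 acrocentric bivalents
Jollas_cupreus	26a	XaXa0	no	1	2
Sittisax_ranieri	24a	XmXaYm	yes	6	21	quadruple-junction sex trivalent
Sittisax_saxicola	24a	XaXaXaYm|XmYaYaYa	yes	3	14	ears/head orientation; system ambiguous
Tomis_manabita	26a	XaXa0	no	1	3
Attulus_ammophilus	26a	XaXa0	no	5	20
Attulus_burjaticus	28a?	XaXa0	no	1	1	autosome count uncertain; XX0 reasonably secure
Attulus_caricis	26a	XaXa0	no	0	0	literature record
Attulus_cutleri	26a	XaXaYa	yes	1	3
Attulus_floricola	28a	XaXa0	no	2	9	one autosome much smaller
Attulus_rupicola_floricola	24a?	XaXaXaYm?	yes	1	3	Y secure; details of system uncertain
Attulus_inexpectus	26a	XaXa0	no	2	13
Attulus_striatus	24a	XaXaXaYm	yes	1	5	scored from 1985 notes
Attulus_fasciger	26a	XaXa0	no	3	16
Attulus_finschi	28a	XaXa0	no	3	13	one autosome much smaller
Attulus_pubescens	26a	XaXmYa	yes	4	10
Attulus_terebratus	26a	XaXa0	no	1	9
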