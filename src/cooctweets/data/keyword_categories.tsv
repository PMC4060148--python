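# Per-cancer keyword category assignments (disease <TAB> keyword <TAB> category).
# Categories: diagnosis, symptoms, treatments, others.
# Some keywords are legitimately listed under two columns for one disease
# (a drug can be both a treatment and a source of symptoms); both rows are kept.
stomach cancer	ct	diagnosis
stomach cancer	mri	diagnosis
stomach cancer	tumor marker	diagnosis
stomach cancer	lumbago	symptoms
stomach cancer	ts-1	symptoms
stomach cancer	side effects	symptoms
stomach cancer	anti-cancer drug	treatments
stomach cancer	ts-1	treatments
stomach cancer	administration of iron	treatments
colon and colorectal cancer	ct	diagnosis
colon and colorectal cancer	pet	diagnosis
colon and colorectal cancer	elplat	symptoms
colon and colorectal cancer	side effects	symptoms
colon and colorectal cancer	chemotherapy	treatments
colon and colorectal cancer	diet	treatments
colon and colorectal cancer	nursing care	others
uterine and cervical cancer	lymphedema	symptoms
uterine and cervical cancer	educational activity	others
uterine and cervical cancer	screening	others
uterine and cervical cancer	not covered by health insurance	others
uterine and cervical cancer	health insurance	others
uterine and cervical cancer	vaccination	others
uterine and cervical cancer	official support	others
lung cancer	ct	diagnosis
lung cancer	metastasis	symptoms
lung cancer	shoulder pain	symptoms
lung cancer	back pain	symptoms
lung cancer	iressa	symptoms
lung cancer	side effects	symptoms
lung cancer	anti-cancer drug	treatments
lung cancer	iressa	treatments
lung cancer	tarceva	treatments
lung cancer	palliative care	others
breast cancer	self-diagnosis	diagnosis
breast cancer	metastasis	symptoms
breast cancer	lymphedema	symptoms
breast cancer	chemotherapy	treatments
breast cancer	hormonal treatment	treatments
breast cancer	palliative care	others
breast cancer	the pink ribbon	others
breast cancer	pink ribbon	others
leukemia	liver function test	diagnosis
leukemia	liver function test	symptoms
leukemia	foot pain	symptoms
leukemia	immunosuppression	symptoms
leukemia	gvhd	symptoms
leukemia	chemotherapy	treatments
leukemia	steroid treatment	treatments
leukemia	transfusion of red blood cells	treatments
leukemia	transfusion	treatments
leukemia	platelet transfusion	treatments
leukemia	aml	others
leukemia	hematopoietic stem cell transplantation	others
leukemia	stem cell transplantation	others
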