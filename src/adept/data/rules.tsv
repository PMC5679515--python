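rule_id	kind	category	pattern_type	pattern	must_contain_mention	description
RET-01	retention	B	tokens	NEG GAP<=1 LIT:relief|respite GAP<=2 LIT:from|of GAP<=1 ADE	false	Negated relief: the event persists ("no relief from headache")
RET-02	retention	A	tokens	NEG GAP<=2 HELP:administration GAP<=3 DRUG	false	Negation of drug administration, not of the event ("not taking his medication")
RET-03	retention	A	tokens	LIT:non GAP<=1 LIT:compliant|adherent|concordant GAP<=2 DRUG	false	Non-compliance with medication ("non-compliant with meds")
RET-04	retention	B	tokens	NEG GAP<=1 LIT:increase|increased|increasing|escalation|worsening GAP<=2 ADE	false	Negated increase: event present but stable ("no increase in headache")
RET-05	retention	B	tokens	NEG GAP<=1 LIT:change|changes GAP<=2 ADE	false	Negated change: event present but unchanged ("no change in restlessness")
RET-06	retention	A	tokens	NEG GAP<=2 HELP:administration	false	Negation of administration without explicit drug ("not taking")
RET-07	retention	B	tokens	NEG GAP<=1 LIT:worsened|worsening|worse|deteriorated|deteriorating|progressed|progressing	false	Negated worsening: event present but not worse ("has not worsened")
RET-08	retention	B	tokens	NEG GAP<=1 LIT:improved|improving|improvement|settled|resolved|subsided|eased|abated	false	Negated improvement: event still present ("not improved")
RET-09	retention	A	tokens	NEG GAP<=2 DRUG	false	Negation of the drug itself ("not on olanzapine")
REM-01	removal	a	tokens	DRUG GAP<=4 HELP:drug_link GAP<=3 ADE	false	Drug-to-event explanation ("olanzapine as it can cause weight gain")
REM-02	removal	a	tokens	HELP:drug_link GAP<=3 ADE	false	Causal explanation of a potential event ("as it can cause weight gain")
REM-03	removal	a	tokens	HELP:monitoring GAP<=4 ADE	false	Warning or monitoring instruction ("warned ZZZZ of dizziness", "signs of myocarditis")
REM-04	removal	a	tokens	ADE GAP<=1 LIT:screen|screening|surveillance|workup|bloods|monitoring	false	Event named as an investigation ("myocarditis screen")
REM-05	removal	a	tokens	LIT:risk|risks GAP<=1 LIT:of GAP<=2 ADE	false	Risk statement ("risk of seizures")
REM-06	removal	a	tokens	LIT:discussed|explained|discussing|explaining|educated|education|counselled|counseled GAP<=3 HELP:negative_effect	false	Side-effect education ("discussed side effects")
REM-07	removal	a	tokens	LIT:potential|possible GAP<=1 HELP:negative_effect	false	Potential side effects mentioned generically
REM-08	removal	a	tokens	LIT:ongoing|going GAP<=1 LIT:investigation|investigations	false	Ongoing investigation of a suspected event
REM-09	removal	a	tokens	LIT:ecg|echo|echocardiogram|bloods|test|tests|investigation|investigations GAP<=3 LIT:arranged|ordered|requested|pending|booked|awaited	false	Investigation arranged or pending
REM-10	removal	a	tokens	LIT:leaflet|information GAP<=2 LIT:given|provided|offered	false	Patient information material supplied
REM-11	removal	a	tokens	LIT:warn|warning|warnings GAP<=2 LIT:about|of|regarding GAP<=3 ADE	false	Explicit warning phrasing ("warning about dizziness")
REM-12	removal	a	tokens	LIT:precaution|precautions|prophylaxis|prophylactic|precautionary	false	Precautionary discussion
REM-13	removal	b	tokens	LIT:unstable|unclear|uncertain|equivocal|borderline|inconclusive GAP<=3 ADE	false	Uncertainty marker before the event ("unstable partial complex seizures")
REM-14	removal	b	tokens	ADE GAP<=3 LIT:unstable|unclear|uncertain|equivocal|inconclusive	false	Uncertainty marker after the event
REM-15	removal	b	tokens	LIT:query|queried GAP<=2 ADE	false	Clinical query ("query seizures")
REM-16	removal	b	tokens	LIT:? GAP<=1 ADE	false	Question mark before the event ("?seizures")
REM-17	removal	b	tokens	ADE GAP<=1 LIT:?	false	Question mark after the event ("seizures?")
REM-18	removal	b	tokens	LIT:cannot|can't GAP<=1 LIT:exclude|rule	false	Inability to exclude the event
REM-19	removal	c	regex	\*\s*no\s*\*?\s*yes|\*\s*yes\s*\*?\s*no	false	Questionnaire checkbox pair ("*No * Yes")
REM-20	removal	c	regex	\byes\s*/\s*no\b|\bno\s*/\s*yes\b	false	Yes/No answer slot
REM-21	removal	c	regex	\bx\s*\d+\s*[.!?]?\s*$	false	Trailing questionnaire score ("x 5")
REM-22	removal	c	regex	\[\s*\]|\(\s*\)	false	Empty checkbox bracket
REM-23	removal	c	builtin	slash_menu	false	Slash-separated symptom menu ("Fainting/ dizziness")
REM-24	removal	d	regex	[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}	true	Event string inside an e-mail address
REM-25	removal	d	regex	(?:https?://|www\.)\S+	true	Event string inside a URL
REM-26	removal	d	builtin	allcaps_run	true	Event string inside an all-capitals organisation name
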