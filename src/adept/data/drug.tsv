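surface	canonical	subcategory	direction	dimension	case_sensitive
medication	medication				
medications	medications				
meds	meds				
tablets	tablets				
tablet	tablet				
drugs	drugs				
antipsychotic	antipsychotic				
antipsychotics	antipsychotics				
antidepressant	antidepressant				
antidepressants	antidepressants				
depot	depot				
depot injection	depot injection				
mood stabiliser	mood stabiliser				
mood stabilizer	mood stabilizer				
beta-blocker	beta-blocker				
beta blocker	beta blocker				
olanzapine	olanzapine				
clozapine	clozapine				
risperidone	risperidone				
quetiapine	quetiapine				
aripiprazole	aripiprazole				
haloperidol	haloperidol				
chlorpromazine	chlorpromazine				
flupentixol	flupentixol				
zuclopenthixol	zuclopenthixol				
amisulpride	amisulpride				
sulpiride	sulpiride				
paliperidone	paliperidone				
lurasidone	lurasidone				
sertraline	sertraline				
fluoxetine	fluoxetine				
citalopram	citalopram				
escitalopram	escitalopram				
paroxetine	paroxetine				
venlafaxine	venlafaxine				
mirtazapine	mirtazapine				
duloxetine	duloxetine				
amitriptyline	amitriptyline				
clomipramine	clomipramine				
trazodone	trazodone				
lofepramine	lofepramine				
lithium	lithium				
sodium valproate	sodium valproate				
valproate	valproate				
carbamazepine	carbamazepine				
lamotrigine	lamotrigine				
diazepam	diazepam				
lorazepam	lorazepam				
clonazepam	clonazepam				
zopiclone	zopiclone				
zolpidem	zolpidem				
promethazine	promethazine				
procyclidine	procyclidine				
propranolol	propranolol				
pregabalin	pregabalin				
gabapentin	gabapentin				
methadone	methadone				
buprenorphine	buprenorphine				
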