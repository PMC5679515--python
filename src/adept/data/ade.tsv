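surface	canonical	subcategory	direction	dimension	case_sensitive
agitation	agitation				
agitated	agitation				
akathisia	akathisia				
akathesia	akathisia				
acathisia	akathisia				
anxiety	anxiety				
anxious	anxiety				
anxiousness	anxiety				
arrhythmia	arrhythmia				
arrhythmias	arrhythmia				
arrythmia	arrhythmia				
irregular heartbeat	arrhythmia				
irregular heart rhythm	arrhythmia				
cardiomyopathy	cardiomyopathy				
cardiomyopathies	cardiomyopathy				
constipation	constipation				
constipated	constipation				
convulsion	convulsions				
convulsions	convulsions				
convulsing	convulsions				
diarrhoea	diarrhoea				
diarrhea	diarrhoea				
loose stools	diarrhoea				
disorientation	disorientation				
disorientated	disorientation				
disoriented	disorientation				
dizziness	dizziness				
dizzy	dizziness				
light-headed	dizziness				
lightheaded	dizziness				
light-headedness	dizziness				
lightheadedness	dizziness				
dry mouth	dry mouth				
xerostomia	dry mouth				
mouth dryness	dry mouth				
fainting	fainting				
fainted	fainting				
faints	fainting				
syncope	fainting				
syncopal episode	fainting				
galactorrhoea	galactorrhoea				
galactorrhea	galactorrhoea				
lactation	galactorrhoea				
headache	headache				
headaches	headache				
head ache	headache				
hypersalivation	hypersalivation				
excessive salivation	hypersalivation				
drooling	hypersalivation				
sialorrhoea	hypersalivation				
sialorrhea	hypersalivation				
insomnia	insomnia				
sleeplessness	insomnia				
unable to sleep	insomnia				
poor sleep	insomnia				
myocarditis	myocarditis				
nausea	nausea				
nauseous	nausea				
nauseated	nausea				
feeling sick	nausea				
pneumonia	pneumonia				
chest infection	pneumonia				
restlessness	restlessness				
restless	restlessness				
sedation	sedation				
sedated	sedation				
drowsy	sedation				
drowsiness	sedation				
sleepy	sedation				
sleepiness	sedation				
somnolence	sedation				
somnolent	sedation				
seizure	seizures				
seizures	seizures				
fit	seizures				
fits	seizures				
sjs	sjs				
stevens johnson syndrome	sjs				
steven johnson syndrome	sjs				
stevens-johnson syndrome	sjs				
stephen johnson's syndrome	sjs				
tachycardia	tachycardia				
tachycardic	tachycardia				
racing heart	tachycardia				
heart racing	tachycardia				
vomiting	vomiting				
vomited	vomiting				
emesis	vomiting				
being sick	vomiting				
weight gain	weight gain				
gained weight	weight gain				
gaining weight	weight gain				
weightgain	weight gain				
put on weight	weight gain				
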