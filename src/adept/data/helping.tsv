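surface	canonical	subcategory	direction	dimension	case_sensitive
does have	does have	occurrence			
developed	developed	occurrence			
develops	develops	occurrence			
developing	developing	occurrence			
complaining of	complaining of	occurrence			
complains of	complains of	occurrence			
complained of	complained of	occurrence			
suffering from	suffering from	occurrence			
suffers from	suffers from	occurrence			
suffered from	suffered from	occurrence			
experiencing	experiencing	occurrence			
experienced	experienced	occurrence			
experiences	experiences	occurrence			
reports	reports	occurrence			
reported	reported	occurrence			
reporting	reporting	occurrence			
has had	has had	occurrence			
have had	have had	occurrence			
presented with	presented with	occurrence			
presenting with	presenting with	occurrence			
presents with	presents with	occurrence			
feeling	feeling	occurrence			
felt	felt	occurrence			
feels	feels	occurrence			
appears	appears	occurrence			
appeared to be	appeared to be	occurrence			
noted to be	noted to be	occurrence			
observed to be	observed to be	occurrence			
has been	has been	occurrence			
became	became	occurrence			
become	become	occurrence			
becoming	becoming	occurrence			
describes	describes	occurrence			
described	described	occurrence			
states	states	occurrence			
stated	stated	occurrence			
mentions	mentions	occurrence			
mentioned	mentioned	occurrence			
troubled by	troubled by	occurrence			
bothered by	bothered by	occurrence			
struggling with	struggling with	occurrence			
taking	taking	administration			
taken	taken	administration			
takes	takes	administration			
took	took	administration			
applying	applying	administration			
applied	applied	administration			
using	using	administration			
used	used	administration			
administering	administering	administration			
administered	administered	administration			
started	started	administration			
starting	starting	administration			
commenced	commenced	administration			
commencing	commencing	administration			
prescribed	prescribed	administration			
restarted	restarted	administration			
titrated	titrated	administration			
adherent to	adherent to	administration			
compliant with	compliant with	administration			
concordant with	concordant with	administration			
tolerating	tolerating	administration			
continued on	continued on	administration			
maintained on	maintained on	administration			
switched to	switched to	administration			
changed to	changed to	administration			
assess for	assess for	monitoring			
assessing for	assessing for	monitoring			
monitor	monitor	monitoring			
monitor for	monitor for	monitoring			
monitoring	monitoring	monitoring			
monitoring for	monitoring for	monitoring			
screen for	screen for	monitoring			
screening for	screening for	monitoring			
signs of	signs of	monitoring			
sign of	sign of	monitoring			
watch for	watch for	monitoring			
watch out for	watch out for	monitoring			
look out for	look out for	monitoring			
observe for	observe for	monitoring			
observing for	observing for	monitoring			
warned	warned	monitoring			
warned of	warned of	monitoring			
warned about	warned about	monitoring			
warn	warn	monitoring			
warn of	warn of	monitoring			
advised about	advised about	monitoring			
advised of	advised of	monitoring			
advised regarding	advised regarding	monitoring			
counselled about	counselled about	monitoring			
counselled regarding	counselled regarding	monitoring			
counseled about	counseled about	monitoring			
alert for	alert for	monitoring			
check for	check for	monitoring			
checking for	checking for	monitoring			
review for	review for	monitoring			
be aware of	be aware of	monitoring			
risk of	risk of	monitoring			
at risk of	at risk of	monitoring			
potential for	potential for	monitoring			
vigilant for	vigilant for	monitoring			
side effect	side effect	negative_effect			
side effects	side effects	negative_effect			
side-effect	side-effect	negative_effect			
side-effects	side-effects	negative_effect			
adverse effect	adverse effect	negative_effect			
adverse effects	adverse effects	negative_effect			
adverse reaction	adverse reaction	negative_effect			
adverse reactions	adverse reactions	negative_effect			
adverse event	adverse event	negative_effect			
adverse events	adverse events	negative_effect			
undesirable effect	undesirable effect	negative_effect			
undesirable effects	undesirable effects	negative_effect			
SE	se	negative_effect			true
EPSE	epse	negative_effect			true
untoward effect	untoward effect	negative_effect			
untoward effects	untoward effects	negative_effect			
drug reaction	drug reaction	negative_effect			
as it can be	as it can be	drug_link			
as it may	as it may	drug_link			
if it cause	if it cause	drug_link			
if it causes	if it causes	drug_link			
known for	known for	drug_link			
may lead	may lead	drug_link			
may lead to	may lead to	drug_link			
as it can cause	as it can cause	drug_link			
can cause	can cause	drug_link			
as it may cause	as it may cause	drug_link			
known to cause	known to cause	drug_link			
can lead to	can lead to	drug_link			
which can cause	which can cause	drug_link			
which may cause	which may cause	drug_link			
may cause	may cause	drug_link			
commonly causes	commonly causes	drug_link			
a recognised side effect of	a recognised side effect of	drug_link			
a known side effect of	a known side effect of	drug_link			
attributed to	attributed to	drug_link			
secondary to the	secondary to the	drug_link			
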