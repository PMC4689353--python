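stem_id	spelling	affix_class	parent	definition	position_sense_key	position_sense_text
ast	ast	suffix		antiasthmatics or antiallergics, not acting primarily as antihistaminics
lukast	lukast	suffix	ast	leukotriene receptor antagonists
milast	milast	suffix	ast	phosphodiesterase type IV (PDE IV) inhibitors
trodast	trodast	suffix	ast	thromboxane A-2 receptor antagonists, antiasthmatics
zolast	zolast	suffix	ast	leukotriene biosynthesis inhibitors
vir	vir	freefix		antivirals
amivir	amivir	suffix	vir	neuraminidase inhibitors
asvir	asvir	suffix	vir	antivirals, hepatitis C virus (HCV) NS5A inhibitors
buvir	buvir	suffix	vir	RNA polymerase (NS5B) inhibitors
cavir	cavir	suffix	vir	carbocyclic nucleosides
ciclovir	ciclovir	suffix	vir	bicyclic heterocycle compounds
fovir	fovir	suffix	vir	phosphonic acid derivatives
gosivir	gosivir	suffix	vir	glucoside inhibitors
navir	navir	suffix	vir	HIV protease inhibitors
previr	previr	suffix	vir	hepatitis C virus (HCV) protease inhibitors
virine	virine	suffix	vir	non-nucleoside reverse transcriptase inhibitors (NNRTI)
viroc	viroc	suffix	vir	CCR5 (chemokine CC motif receptor 5) receptor antagonists
mab	mab	suffix		monoclonal antibodies
axo	axo	infix	mab	rat/mouse source
xi	xi	infix	mab	chimeric source
xizu	xizu	infix	mab	chimeric/humanized source
zu	zu	infix	mab	humanised source
ba	ba	infix	mab	bacterial target
ci	ci	infix	mab	cardiovascular target
fu	fu	infix	mab	fungal target
ki	ki	infix	mab	interleukin target
li	li	infix	mab	immunomodulating target
ne	ne	infix	mab	neural target
so	so	infix	mab	bone target
tox	tox	infix	mab	toxin target
tox	toxa	infix	mab
tu	tu	infix	mab	tumour target
astine	astine	suffix		antihistaminics (histamine-H1 receptor antagonists)
azepide	azepide	suffix		cholecystokinin receptor antagonists
cromil	cromil	suffix		antiallergics, cromoglicic acid derivatives
fenin	fenin	suffix		diagnostic aids; (phenylcarbamoyl)methyl iminodiacetic acid derivatives
fenine	fenine	suffix		analgesics, glafenine derivatives
profen	profen	suffix		anti-inflammatory agents, ibuprofen derivatives
profen	profene	suffix
iptiline	iptiline	suffix		antidepressants, tricyclic (dibenzazepine) compounds
dipine	dipine	suffix		calcium channel blockers, 1,4-dihydropyridine derivatives
pine	pine	suffix		tricyclic compounds
micin	micin	suffix		antibiotics, derived from Micromonospora strains
mycin	mycin	suffix		antibiotics, derived from Streptomyces strains
nico	nico	infix		nicotinic acid derivatives
nico	nic	infix
gli	gli	freefix		antihyperglycaemics
grel	grel	infix		platelet aggregation inhibitors
grel	grel	suffix
fos	fos	suffix		insecticides, anthelminthics, pesticides etc., phosphorus derivatives	suffix	insecticides, anthelminthics, pesticides etc., phosphorus derivatives
fos	fos	infix			infix	various pharmacological categories belonging to fos, other than insecticides and pesticides
fos	fos	prefix			prefix	various pharmacological categories belonging to fos, other than insecticides and pesticides
tide	tide	suffix		peptides and glycopeptides
actide	actide	suffix		synthetic polypeptides with a corticotrophin-like action
orex	orex	suffix		anorexics
arte	arte	prefix		antimalarial agents, artemisinin related compounds
sal	sal	prefix		analgesic anti-inflammatories, salicylic acid derivatives
salazo	salazo	prefix	sal	phenylazosalicylic acid derivatives, antibacterial
sulfa	sulfa	prefix		anti-infectives, sulfonamides
kacin	kacin	suffix		antibiotics obtained from Streptomyces kanamyceticus
metasone	metasone	suffix		corticosteroids, prednisolone derivatives
metasone	methasone	suffix
setron	setron	suffix		serotonin (5-HT3) receptor antagonists
pristone	pristone	suffix		steroids, antiprogestogens
pristone	pristal	infix
nab	nab	freefix		cannabinoid receptor agonists
orphinol	orphinol	suffix		morphinan derivatives, opioid analgesics
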