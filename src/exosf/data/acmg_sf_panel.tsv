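symbol	transcript	inheritance	mim	disease	category	onset
BRCA1	NM_007300.3	AD	604370	Hereditary breast and ovarian cancer	oncogenetic	adult
BRCA2	NM_000059.3	AD	612555	Hereditary breast and ovarian cancer	oncogenetic	unknown
TP53	NM_001126112.2	AD	151623	Li-Fraumeni syndrome	oncogenetic	child_or_adult
STK11	NM_000455.4	AD	175200	Peutz-Jeghers syndrome	oncogenetic	child_or_adult
MLH1	NM_001258271.1	AD	120435	Lynch syndrome	oncogenetic	adult
MSH2	NM_000251.2	AD		Lynch syndrome	oncogenetic	unknown
MSH6	NM_001281493.1	AD		Lynch syndrome	oncogenetic	unknown
PMS2	NM_000535.6	AD		Lynch syndrome	oncogenetic	unknown
APC	NM_001127511.2	AD	175100	Familial adenomatous polyposis	oncogenetic	child_or_adult
MUTYH	NM_001128425.1	AR	608456,132600	MYH-associated polyposis, Adenomas, multiple colorectal, FAP type 2, Colorectal adenomatous polyposis with pilomatricomas	oncogenetic	adult
BMPR1A	NM_004329.2	AD	174900	Juvenile polyposis syndrome	oncogenetic	child_or_adult
SMAD4	NM_005359.5	AD		Juvenile polyposis syndrome	oncogenetic	unknown
VHL	NM_198156.2	AD	193300	Von Hippel-Lindau syndrome	oncogenetic	child_or_adult
MEN1	NM_130801.2	AD	131100	Multiple endocrine neoplasia type 1	oncogenetic	child_or_adult
RET	NM_020975.4	AD	171400,162300,1552401	Multiple endocrine neoplasia type 2, familial medullary thyroid carcinoma	oncogenetic	child_or_adult
PTEN	NM_000314.6	AD	158350	PTEN hamartoma tumor syndrome	oncogenetic	child_or_adult
RB1	NM_000321.2	AD	180200	Retinoblastoma	oncogenetic	child
SDHD	NM_003002.3	AD	168000	Hereditary paraganglioma-pheochromocytoma syndrome	oncogenetic	child_or_adult
SDHAF2	NM_017841.2	AD	601650	Hereditary paraganglioma-pheochromocytoma syndrome	oncogenetic	unknown
SDHC	NM_003001.3	AD	605373	Hereditary paraganglioma-pheochromocytoma syndrome	oncogenetic	unknown
SDHB	NM_003000.2	AD	115310	Hereditary paraganglioma-pheochromocytoma syndrome	oncogenetic	unknown
TSC1	NM_000368.4	AD	191100	Tuberous sclerosis complex	oncogenetic	child
TSC2	NM_000548.4	AD	613254	Tuberous sclerosis complex	oncogenetic	unknown
WT1	NM_001198551.1	AD	194070	WT1-related Wilms tumor	oncogenetic	child
NF2	NM_000268.3	AD	101000	Neurofibromatosis type 2	oncogenetic	child_or_adult
COL3A1	NM_000090.3	AD	130050	Vascular Ehlers-Danlos syndrome	connective_tissue	child_or_adult
FBN1	NM_000138.4	AD	154700	Marfan's syndrome	connective_tissue	child_or_adult
TGFBR1	NM_001130916.2	AD	609192	Loeys-Dietz syndrome	connective_tissue	unknown
TGFBR2	NM_003242.5	AD	190182	Loeys-Dietz syndrome	connective_tissue	unknown
SMAD3	NM_001145103.1	AD	613795	Loeys-Dietz syndrome	connective_tissue	unknown
ACTA2	NM_001613.2	AD	611788	Familial thoracic aortic aneurysm and dissection	connective_tissue	unknown
MYH11	NM_001040114.1	AD	160745	Familial thoracic aortic aneurysm and dissection	connective_tissue	unknown
MYBPC3	NM_000256.3	AD	115197	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	child_or_adult
MYH7	NM_000257.3	AD	192600	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	unknown
TNNT2	NM_001276346.1	AD	601494	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	child_or_adult
TNNI3	NM_000363.4	AD	613690	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	unknown
TPM1	NM_001018008.1	AD	115196	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	unknown
MYL3	NM_000258.2	AD	608751	Hypertrophic cardiomyopathy	cardiogenetic	unknown
ACTC1	NM_005159.4	AD	612098	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	unknown
PRKAG2	NM_016203.3	AD	600858	Hypertrophic cardiomyopathy	cardiogenetic	unknown
GLA	NM_000169.2	XLD	301500	Fabry disease	cardiogenetic	unknown
MYL2	NM_000432.3	AD	608758	Hypertrophic cardiomyopathy	cardiogenetic	unknown
LMNA	NM_170707.3	AD	115200	Hypertrophic cardiomyopathy, dilated cardiomyopathy	cardiogenetic	unknown
RYR2	NM_001035.2	AD	604772	Catecholaminergic polymorphic ventricular tachycardia	cardiogenetic	child_or_adult
PKP2	NM_004572.3	AD	609040	Arrhythmogenic right ventricular cardiomyopathy	cardiogenetic	child_or_adult
DSP	NM_001008844.2	AD	607450	Arrhythmogenic right ventricular cardiomyopathy	cardiogenetic	unknown
DSC2	NM_024422.4	AD	610476	Arrhythmogenic right ventricular cardiomyopathy	cardiogenetic	unknown
TMEM43	NM_024334.2	AD	604400	Arrhythmogenic right ventricular cardiomyopathy	cardiogenetic	unknown
DSG2	NM_001943.4	AD	610193	Arrhythmogenic right ventricular cardiomyopathy	cardiogenetic	unknown
KCNQ1	NM_181798.1	AD	192500	Romano-Ward long QT syndromes 1, 2, and 3, Brugada syndrome	cardiogenetic	child_or_adult
KCNH2	NM_000238.3	AD	613688	Romano-Ward long QT syndromes 1, 2, and 3, Brugada syndrome	cardiogenetic	unknown
SCN5A	NM_198056.2	AD	601144,603830	Romano-Ward long QT syndromes 1, 2, and 3, Brugada syndrome	cardiogenetic	unknown
LDLR	NM_000527.4	AD	143890	Familial hypercholesterolemia	other	child_or_adult
APOB	NM_000384.2	AD		Familial hypercholesterolemia	other	unknown
PCSK9	NM_174936.3	AD	603776	Familial hypercholesterolemia	other	unknown
ATP7B	NM_000053.2	AR	277900	Wilson disease	other	child
CACNA1S	NM_000069.2	AD	114208	Malignant hyperthermia susceptibility	other	child_or_adult
RYR1	NM_000540.2	AD	145600	Malignant hyperthermia susceptibility	other	unknown
OTC	NM_000531.5	XLR	311250	Ornithine transcarbamylase deficiency	other	unknown
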