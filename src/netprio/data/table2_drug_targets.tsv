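gene	drug_id	drug_name	action	groups
ABL1	DB00619	Imatinib	inhibitor	approved
ABL1	DB01254	Dasatinib	multitarget	approved,investigational
ABL1	DB04868	Nilotinib	inhibitor	approved,investigational
ABL1	DB12010	Fostamatinib	inhibitor	approved,investigational
ERBB2	DB01259	Lapatinib	inhibitor	approved,investigational
ERBB2	DB12010	Fostamatinib	inhibitor	approved,investigational
MYC	DB08813	Nadroparin	inhibitor	approved,investigational
FN1	DB08888	Ocriplasmin	cleavage	approved
CFTR	DB01016	Glyburide	antagonist	approved
CFTR	DB00887	Bumetanide	antagonist	approved
CFTR	DB08820	Ivacaftor	potentiator	approved
CFTR	DB09280	Lumacaftor	modulator	approved
CFTR	DB02587	Colforsin- Forskolin	inhibitor	experimental,investigational
IKBKE	DB12010	Fostamatinib	inhibitor	approved,investigational
NFKB1	DB08814	Triflusal	antagonist	approved,investigational
NFKB2	DB01296	Glucosamine	antagonist	approved,investigational
PIK3R1	DB01064	Isoprenaline	agonist	approved,investigational
RAC1	DB00993	Azathioprine	-	approved
RELA	DB08908	Dimethyl fumarate	-	approved,investigational
SRC	DB01254	Dasatinib	multitarget	approved,investigational
SRC	DB12010	Fostamatinib	inhibitor	approved,investigational
HSP90AB1	DB02424	Geldanamycin	-	experimental,investigational
ESR1	DB09086	Eugenol	-	approved
ESR1	DB02709	Resveratrol	-	approved,experimental,investigational
ESR1	DB01065	Melatonin	antagonist	approved
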