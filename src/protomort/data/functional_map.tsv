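protein	name	category
A2M	Alpha-2-macroglobulin	hemostasis
F2	Prothrombin	hemostasis
F10	Coagulation factor X	hemostasis
F12	Coagulation factor XII	hemostasis
PDGFB	Platelet-derived growth factor subunit B	hemostasis
PLG	Plasminogen	hemostasis
PLGLA	Plasminogen-like protein A	hemostasis
PLGB1	Plasminogen-like protein B1	hemostasis
PROZ	Vitamin K-dependent protein Z	hemostasis
PTPN11	Tyrosine-protein phosphatase non-receptor type 11	hemostasis
TLN1	Talin-1	hemostasis
KNG1	Kininogen-1	hemostasis
PF4	Platelet factor 4	hemostasis
THBS1	Thrombospondin-1	hemostasis
FGB	Fibrinogen beta chain	hemostasis
ORM1	Alpha-1-acid glycoprotein 1	hemostasis
C1QA	Complement C1q subcomponent subunit A	complement
C1QC	Complement C1q subcomponent subunit C	complement
CFH	Complement factor H	complement
CFP	Properdin	complement
CCL17	C-C motif chemokine 17	cytokine
CCL25	C-C motif chemokine 25	cytokine
CXCL5	C-X-C motif chemokine 5	cytokine
CXCL9	C-X-C motif chemokine 9	cytokine
CSF2	Granulocyte-macrophage colony-stimulating factor	cytokine
IL1B	Interleukin-1 beta	cytokine
IGLV3-10	Immunoglobulin lambda variable 3-10	adaptive-immunity
IGLV3-25	Immunoglobulin lambda variable 3-25	adaptive-immunity
IGLV6-57	Immunoglobulin lambda variable 6-57	adaptive-immunity
IGKV6-21	Immunoglobulin kappa variable 6-21	adaptive-immunity
IGHV2-5	Immunoglobulin heavy variable 2-5	adaptive-immunity
PGLYRP2	N-acetylmuramoyl-L-alanine amidase	other-immune
ATRN	Attractin	other-immune
GULP1	PTB domain-containing engulfment adapter protein 1	other-immune
SLC2A(3,14)	Solute carrier family 2 members 3/14	other-immune
SLC2A	Solute carrier family 2 glucose transporter	other-immune
GARIN1B	Golgi-associated RAB2 interactor protein 1B	orphan
GPX3	Glutathione peroxidase 3	orphan
IGFALS	IGF-binding protein complex acid labile subunit	orphan
MYL6(B)	Myosin light polypeptide 6 / chain 6B	orphan
MYL6	Myosin light polypeptide 6	orphan
OR5M11	Olfactory receptor 5M11	orphan
AFM	Afamin	orphan
PKHD1	Fibrocystin	orphan
MDC1	Mediator of DNA damage checkpoint protein 1	orphan
APOA1	Apolipoprotein A-I	lipid-metabolism
APOB	Apolipoprotein B-100	lipid-metabolism
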