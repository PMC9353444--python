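function_class	function_group
actin-binding protein	actin-binding and motor protein
motor protein	actin-binding and motor protein
myosin	actin-binding and motor protein
kinesin	actin-binding and motor protein
dynein	actin-binding and motor protein
tropomyosin	actin-binding and motor protein
actin capping protein	actin-binding and motor protein
antimicrobial peptide	antimicrobial
antibiotic	antimicrobial
defensin	antimicrobial
antiviral defense protein	antimicrobial
bacteriolytic enzyme	antimicrobial
fungicide	antimicrobial
cytokine	cytokine
chemokine	cytokine
interleukin	cytokine
interferon	cytokine
tumor necrosis factor family member	cytokine
lymphokine	cytokine
monokine	cytokine
adipokine	cytokine
oxidoreductase	enzyme
dehydrogenase	enzyme
oxidase	enzyme
reductase	enzyme
peroxidase	enzyme
dioxygenase	enzyme
monooxygenase	enzyme
lyase	enzyme
isomerase	enzyme
ligase	enzyme
growth factor	growth factor
mitogen	growth factor
neurotrophic factor	growth factor
angiogenic factor	growth factor
colony-stimulating factor	growth factor
morphogen	growth factor
heparin-binding growth factor	growth factor
hormone	hormone
peptide hormone	hormone
neuropeptide	hormone
gonadotropin	hormone
somatotropin	hormone
incretin	hormone
natriuretic peptide	hormone
hydrolase	hydrolase
protease	hydrolase
serine protease	hydrolase
cysteine protease	hydrolase
aspartyl protease	hydrolase
metalloprotease	hydrolase
glycosidase	hydrolase
lipase	hydrolase
esterase	hydrolase
nuclease	hydrolase
phosphodiesterase	hydrolase
pyrophosphatase	hydrolase
ion channel	ion channel
voltage-gated channel	ion channel
ligand-gated ion channel	ion channel
calcium channel	ion channel
potassium channel	ion channel
sodium channel	ion channel
chloride channel	ion channel
porin	ion channel
aquaporin	ion channel
protease inhibitor	protein metabolism regulator
serine protease inhibitor	protein metabolism regulator
metalloenzyme inhibitor	protein metabolism regulator
chaperone	protein metabolism regulator
co-chaperone	protein metabolism regulator
ubiquitin ligase adaptor	protein metabolism regulator
proteasome regulator	protein metabolism regulator
protein folding catalyst	protein metabolism regulator
receptor	receptor
G-protein coupled receptor	receptor
receptor tyrosine kinase	receptor
cytokine receptor	receptor
nuclear hormone receptor	receptor
immunoglobulin receptor	receptor
pattern recognition receptor	receptor
cell adhesion receptor	receptor
integrin	receptor
transmembrane receptor kinase	receptor
scavenger receptor	receptor
transcription regulator	transcription regulator
transcription activator	transcription regulator
transcription repressor	transcription regulator
DNA-binding transcription factor	transcription regulator
homeobox transcription factor	transcription regulator
zinc-finger transcription factor	transcription regulator
chromatin remodeling factor	transcription regulator
histone-modifying regulator	transcription regulator
basal transcription factor	transcription regulator
signal transducer	transducer
G-protein	transducer
small GTPase	transducer
GTPase activator	transducer
guanine-nucleotide releasing factor	transducer
adaptor protein	transducer
second messenger generator	transducer
phospholipase	transducer
calmodulin-binding transducer	transducer
transferase	transferase
kinase	transferase
protein kinase	transferase
acyltransferase	transferase
glycosyltransferase	transferase
methyltransferase	transferase
aminotransferase	transferase
nucleotidyltransferase	transferase
sulfotransferase	transferase
phosphorylase	transferase
translation regulator	translation regulator
initiation factor	translation regulator
elongation factor	translation regulator
release factor	translation regulator
ribosomal protein	translation regulator
ribonucleoprotein	translation regulator
aminoacyl-tRNA synthetase	translation regulator
vasoactive peptide	vasoactive
vasoconstrictor	vasoactive
vasodilator	vasoactive
endothelin	vasoactive
kinin	vasoactive
angiotensin-processing factor	vasoactive
structural protein	other
storage protein	other
transporter	other
carrier protein	other
toxin	other
pigment-binding protein	other
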