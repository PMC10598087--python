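category	group	description
A	information	RNA processing and modification
B	information	Chromatin structure and dynamics
J	information	Translation, ribosomal structure and biogenesis
K	information	Transcription
L	information	Replication, recombination and repair
D	cellular	Cell cycle control, cell division, chromosome partitioning
M	cellular	Cell wall/membrane/envelope biogenesis
N	cellular	Cell motility
O	cellular	Posttranslational modification, protein turnover, chaperones
T	cellular	Signal transduction mechanisms
U	cellular	Intracellular trafficking, secretion, and vesicular transport
V	cellular	Defense mechanisms
W	cellular	Extracellular structures
Y	cellular	Nuclear structure
Z	cellular	Cytoskeleton
C	metabolism	Energy production and conversion
E	metabolism	Amino acid transport and metabolism
F	metabolism	Nucleotide transport and metabolism
G	metabolism	Carbohydrate transport and metabolism
H	metabolism	Coenzyme transport and metabolism
I	metabolism	Lipid transport and metabolism
P	metabolism	Inorganic ion transport and metabolism
Q	metabolism	Secondary metabolites biosynthesis, transport and catabolism
R	poorly_characterized	General function prediction only
S	poorly_characterized	Function unknown
X	viral	Miscellaneous: domains spanning unrelated general functions
Vc	viral	Capsid/virion-related, no cellular counterpart
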