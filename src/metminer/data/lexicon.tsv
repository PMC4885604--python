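# Bundled concept lexicon: surface<TAB>concept_type<TAB>normalized_id
# Normalized IDs are configuration values, not ground truth.
TGF-β	Gene	EntrezGene:7040
TGFB1	Gene	EntrezGene:7040
Snail	Gene	EntrezGene:6615
SNAI1	Gene	EntrezGene:6615
Slug	Gene	EntrezGene:6591
Twist	Gene	EntrezGene:7291
ZEB1	Gene	EntrezGene:6935
ZEB2	Gene	EntrezGene:9839
E-cadherin	Gene	EntrezGene:999
N-cadherin	Gene	EntrezGene:1000
Vimentin	Gene	EntrezGene:7431
PRL-3	Gene	EntrezGene:11156
Smad2	Gene	EntrezGene:4087
Smad3	Gene	EntrezGene:4088
Smad4	Gene	EntrezGene:4089
STAT3	Gene	EntrezGene:6774
NF-κB	Gene	EntrezGene:4790
AKT1	Gene	EntrezGene:207
PTEN	Gene	EntrezGene:5728
KRAS	Gene	EntrezGene:3845
HIF-1α	Gene	EntrezGene:3091
VEGF	Gene	EntrezGene:7422
MMP-9	Gene	EntrezGene:4318
MMP-2	Gene	EntrezGene:4313
RhoA	Gene	EntrezGene:387
Rac1	Gene	EntrezGene:5879
β-catenin	Gene	EntrezGene:1499
Wnt5a	Gene	EntrezGene:7474
Notch1	Gene	EntrezGene:4851
EGFR	Gene	EntrezGene:1956
HER2	Gene	EntrezGene:2064
FOXC2	Gene	EntrezGene:2303
SOX4	Gene	EntrezGene:6659
miR-181a	MicroRNA	EntrezGene:406995
miR-21	MicroRNA	EntrezGene:406991
miR-200b	MicroRNA	EntrezGene:406984
miR-200c	MicroRNA	EntrezGene:406985
miR-155	MicroRNA	EntrezGene:406947
miR-34a	MicroRNA	EntrezGene:407040
miR-10b	MicroRNA	EntrezGene:406902
let-7a	MicroRNA	EntrezGene:406881
Metastasis	NeoplasmMetastasis	MeSH:D009362
Neoplasm metastasis	NeoplasmMetastasis	MeSH:D009362
Tumor metastasis	NeoplasmMetastasis	MeSH:D009362
Epithelial-mesenchymal transition	NeoplasmMetastasis	MeSH:D058750
EMT	NeoplasmMetastasis	MeSH:D058750
Tumor invasion	NeoplasmMetastasis	MeSH:D009361
Stress fiber	Cytoskeleton	MeSH:D022482
Cytoskeleton	Cytoskeleton	MeSH:D003599
Actin filament	Cytoskeleton	MeSH:D000199
Microtubule	Cytoskeleton	MeSH:D008870
Lamellipodia	Cytoskeleton	MeSH:D055346
Filopodia	Cytoskeleton	MeSH:D064448
Cell aggregation	CellMovement	MeSH:D002447
Cell migration	CellMovement	MeSH:D002465
Cell movement	CellMovement	MeSH:D002465
Cell motility	CellMovement	MeSH:D002465
Chemotaxis	CellMovement	MeSH:D002622
Cell adhesion	CellAdhesion	MeSH:D002448
Focal adhesion	CellAdhesion	MeSH:D022002
Adherens junction	CellAdhesion	MeSH:D022005
Liver cancer	Neoplasms	MeSH:D008113
Breast cancer	Neoplasms	MeSH:D001943
Lung cancer	Neoplasms	MeSH:D008175
Gastric cancer	Neoplasms	MeSH:D013274
Colorectal cancer	Neoplasms	MeSH:D015179
Hepatocellular carcinoma	Neoplasms	MeSH:D006528
Pancreatic cancer	Neoplasms	MeSH:D010190
Prostate cancer	Neoplasms	MeSH:D011471
Melanoma	Neoplasms	MeSH:D008545
Ovarian cancer	Neoplasms	MeSH:D010051
Liver	Organ	MeSH:D008099
Lung	Organ	MeSH:D008168
Brain	Organ	MeSH:D001921
Bone	Organ	MeSH:D001842
Kidney	Organ	MeSH:D007668
Spleen	Organ	MeSH:D013154
Stomach	Organ	MeSH:D013270
Pancreas	Organ	MeSH:D010179
Ovary	Organ	MeSH:D010053
Lymph node	Organ	MeSH:D008198
Adipose tissue	Tissues	MeSH:D000273
Connective tissue	Tissues	MeSH:D003238
Epithelium	Tissues	MeSH:D004848
Muscle tissue	Tissues	MeSH:D018482
Lymphoid tissue	Tissues	MeSH:D008221
Granulation tissue	Tissues	MeSH:D006067
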