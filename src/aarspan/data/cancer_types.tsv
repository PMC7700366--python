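abbreviation	full_name	median_os_months
ACC	Adrenocortical carcinoma	18.1
BLCA	Bladder Urothelial Carcinoma	13.5
BRCA	Breast invasive carcinoma	41.8
CESC	Cervical squamous cell carcinoma and endocervical adenocarcinoma	19.9
CHOL	Cholangio carcinoma	18
COAD	Colon adenocarcinoma	13.3
DLBC	Lymphoid Neoplasm Diffuse Large B-cell Lymphoma	19.5
ESCA	Esophageal carcinoma	11.5
GBM	Glioblastoma multiforme	12.6
HNSC	Head and Neck squamous cell carcinoma	14.1
KICH	Kidney Chromophobe	24.3
KIRC	Kidney renal clear cell carcinoma	26.9
KIRP	Kidney renal papillary cell carcinoma	21.1
LAML	Acute Myeloid Leukemia	9
LGG	Brain Lower Grade Glioma	26.7
LIHC	Liver hepatocellular carcinoma	13.7
LUAD	Lung adenocarcinoma	20.3
LUSC	Lung squamous cell carcinoma	18.1
MESO	Mesothelioma	15
OV	Ovarian serous cystadenocarcinoma	35.3
PAAD	Pancreatic adenocarcinoma	12.9
PCPG	Pheochromocytoma and Paraganglioma	14.9
PRAD	Prostate adenocarcinoma	36.2
READ	Rectum adenocarcinoma	22
SARC	Sarcoma	21.3
SKCM	Skin Cutaneous Melanoma	35.3
STAD	Stomach adenocarcinoma	11.3
TGCT	Testicular Germ Cell Tumors	18.6
THCA	Thyroid carcinoma	33.5
THYM	Thymoma	28
UCEC	Uterine Corpus Endometrial Carcinoma	23.3
UCS	Uterine Carcinosarcoma	17.1
UVM	Uveal Melanoma	19.9
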