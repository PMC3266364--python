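NPC	nasopharyngeal carcinoma
CRC	colorectal cancer
HCC	hepatocellular carcinoma
NSCLC	non-small cell lung cancer
SCLC	small cell lung cancer
AML	acute myeloid leukemia
ALL	acute lymphoblastic leukemia
CML	chronic myeloid leukemia
CLL	chronic lymphocytic leukemia
RCC	renal cell carcinoma
ESCC	esophageal squamous cell carcinoma
HNSCC	head and neck squamous cell carcinoma
SCC	squamous cell carcinoma
GBM	glioblastoma multiforme
DLBCL	diffuse large b-cell lymphoma
MM	multiple myeloma
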