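nasopharyngeal carcinoma	nasopharyngeal carcinoma
colorectal cancer	colorectal cancer
breast cancer	breast cancer
hepatocellular carcinoma	hepatocellular carcinoma
non-small cell lung cancer	non-small cell lung cancer
small cell lung cancer	small cell lung cancer
acute myeloid leukemia	acute myeloid leukemia
acute lymphoblastic leukemia	acute lymphoblastic leukemia
chronic myeloid leukemia	chronic myeloid leukemia
chronic lymphocytic leukemia	chronic lymphocytic leukemia
renal cell carcinoma	renal cell carcinoma
squamous cell carcinoma	squamous cell carcinoma
esophageal squamous cell carcinoma	esophageal squamous cell carcinoma
head and neck squamous cell carcinoma	head and neck squamous cell carcinoma
malignant melanoma	malignant melanoma
multiple myeloma	multiple myeloma
hodgkin lymphoma	hodgkin lymphoma
non-hodgkin lymphoma	non-hodgkin lymphoma
diffuse large b-cell lymphoma	diffuse large b-cell lymphoma
glioblastoma multiforme	glioblastoma multiforme
gastric adenocarcinoma	gastric adenocarcinoma
prostate adenocarcinoma	prostate adenocarcinoma
cervical intraepithelial neoplasia	cervical intraepithelial neoplasia
wilms tumor	wilms tumor
ewing sarcoma	ewing sarcoma
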