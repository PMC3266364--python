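breast
lung
colorectal
colon
rectal
gastric
stomach
liver
hepatic
esophageal
oesophageal
bladder
kidney
renal
ovarian
cervical
endometrial
uterine
prostate
pancreatic
brain
skin
oral
head
neck
thyroid
testicular
laryngeal
nasopharyngeal
pharyngeal
lymphatic
bone
blood
gallbladder
salivary
adrenal
pituitary
pleural
peritoneal
anal
tongue
intestinal
duodenal
hematologic
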