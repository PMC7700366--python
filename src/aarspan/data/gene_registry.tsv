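symbol	locality	family	msc_member
AARS1	cytoplasmic	aaRS	false
CARS1	cytoplasmic	aaRS	false
DARS1	cytoplasmic	aaRS	true
EPRS1	cytoplasmic	aaRS	true
FARSA	cytoplasmic	aaRS	false
FARSB	cytoplasmic	aaRS	false
GARS1	dual	aaRS	false
HARS1	cytoplasmic	aaRS	false
IARS1	cytoplasmic	aaRS	true
KARS1	dual	aaRS	true
LARS1	cytoplasmic	aaRS	true
MARS1	cytoplasmic	aaRS	true
NARS1	cytoplasmic	aaRS	false
QARS1	cytoplasmic	aaRS	true
RARS1	cytoplasmic	aaRS	true
SARS1	cytoplasmic	aaRS	false
TARS1	cytoplasmic	aaRS	false
VARS1	cytoplasmic	aaRS	false
WARS1	cytoplasmic	aaRS	false
YARS1	cytoplasmic	aaRS	false
AARS2	mitochondrial	aaRS	false
CARS2	mitochondrial	aaRS	false
DARS2	mitochondrial	aaRS	false
EARS2	mitochondrial	aaRS	false
FARS2	mitochondrial	aaRS	false
HARS2	mitochondrial	aaRS	false
IARS2	mitochondrial	aaRS	false
LARS2	mitochondrial	aaRS	false
MARS2	mitochondrial	aaRS	false
NARS2	mitochondrial	aaRS	false
PARS2	mitochondrial	aaRS	false
RARS2	mitochondrial	aaRS	false
SARS2	mitochondrial	aaRS	false
TARS2	mitochondrial	aaRS	false
VARS2	mitochondrial	aaRS	false
WARS2	mitochondrial	aaRS	false
YARS2	mitochondrial	aaRS	false
AIMP1	cytoplasmic	AIMP	true
AIMP2	cytoplasmic	AIMP	true
EEF1E1	cytoplasmic	AIMP	true
RB1	cytoplasmic	reference	false
MYC	cytoplasmic	reference	false
EIF4E	cytoplasmic	reference	false
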