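genus	trophic	cp	source
Aphelenchus	FF	2	verified
Filenchus	FF	2	verified
Prodesmodora	BF	3	verified
Helicotylenchus	PF	3	verified
Eucephalobus	BF	2	verified
Plectus	BF	2	verified
Miconchus	Pr	4	verified
Clarkus	Pr	4	verified
Prodorylaimus	Om	5	verified
Protorhabditis	BF	1	verified
Wilsonema	BF	2	verified
Lelenchus	PF	2	verified
Aporcelaimellus	Om	5	verified
Paratylenchus	PF	2	curated
Pratylenchus	PF	3	curated
Pratylenchoides	PF	3	curated
Rotylenchus	PF	3	curated
Tylenchorhynchus	PF	3	curated
Merlinius	PF	3	curated
Amplimerlinius	PF	3	curated
Geocenamus	PF	3	curated
Heterodera	PF	3	curated
Criconema	PF	3	curated
Criconemoides	PF	3	curated
Hemicycliophora	PF	3	curated
Trichodorus	PF	4	curated
Paratrichodorus	PF	4	curated
Longidorus	PF	5	curated
Xiphinema	PF	5	curated
Acrobeles	BF	2	curated
Acrobeloides	BF	2	curated
Cephalobus	BF	2	curated
Chiloplacus	BF	2	curated
Heterocephalobus	BF	2	curated
Monhystera	BF	2	curated
Anaplectus	BF	2	curated
Rhabditis	BF	1	curated
Mesorhabditis	BF	1	curated
Panagrolaimus	BF	1	curated
Alaimus	BF	4	curated
Prismatolaimus	BF	3	curated
Teratocephalus	BF	3	curated
Aphelenchoides	FF	2	curated
Ditylenchus	FF	2	curated
Tylencholaimus	FF	4	curated
Eudorylaimus	Om	4	curated
Mesodorylaimus	Om	4	curated
Dorylaimus	Om	4	curated
Aporcelaimus	Om	5	curated
Microdorylaimus	Om	4	curated
Mononchus	Pr	4	curated
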