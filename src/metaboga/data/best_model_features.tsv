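comparison	method	feature
Control-Prediabetes	svm	GPCho(20:2/18:1)
Control-Prediabetes	svm	Cer(d18:1/24:1) i2
Control-Prediabetes	svm	PA(i-19:0/20:3-2OH)
Control-Prediabetes	svm	PC(20:3-OH/P-18:1)
Control-Prediabetes	svm	TG(17:1/17:2/22:5)
Control-T2DM	nearcent	Androst-16-ene
Control-T2DM	nearcent	Ganoderic acid C2
Control-T2DM	nearcent	Cer(d18:2/20:4-3OH)
Control-T2DM	nearcent	SM(d18:1/24:1) i2
Control-T2DM	nearcent	(Z)-11-Hexadecenal
Prediabetes-T2DM	svm	lysine phosphoester
Prediabetes-T2DM	svm	PC(18:1-O/20:1)
Prediabetes-T2DM	svm	CE(20:4-2OH)
Prediabetes-T2DM	svm	SM(d17:1/18:0)
Prediabetes-T2DM	svm	Androst-16-ene
Prediabetes-T2DM	svm	Ganoderic acid C2
Prediabetes-T2DM	svm	12-Methylheptadecanoylcarnitine
Prediabetes-T2DM	svm	Glufosinate
Prediabetes-T2DM	svm	PE-NMe(22:0/18:1)
Prediabetes-T2DM	svm	5alpha-Androsta-16-ene-3-ol
Prediabetes-T2DM	svm	PC(PGJ2/DiMe)
Prediabetes-T2DM	svm	PC(P-16:0/20:4-3OH)
Prediabetes-T2DM	svm	SM(d18:0/18:1)
Prediabetes-T2DM	svm	MGDG(26:0/22:4)
Prediabetes-T2DM	svm	Isobehenic acid
Prediabetes-T2DM	svm	(Melle-4)cyclosporin
Prediabetes-T2DM	svm	DG(a-17:0/0:0/8:0) i2
Prediabetes-T2DM	svm	DG(18:3/18:1/0:0)
Prediabetes-T2DM	svm	GPCho(22:5/18:0)
Prediabetes-T2DM	svm	SM(d18:1/18:1)
Prediabetes-T2DM	svm	TG(16:0/17:1/18:1)
Prediabetes-T2DM	svm	MGDG(24:1/18:1)
Prediabetes-T2DM	svm	PE(15:0/18:4)
Prediabetes-T2DM	svm	GPCho(16:1/16:1)
Prediabetes-T2DM	svm	GPCho(24:1/22:6)
Prediabetes-T2DM	svm	4-Hydroperoxycyclophosphamide
Prediabetes-T2DM	svm	PC(22:6-2OH/24:0) i2
Prediabetes-T2DM	svm	GPCho(24:4/20:5)
Control-DN	knn	5beta-Cholestanone
Control-DN	knn	GPSer(18:1/11:0)
Control-DN	knn	GPEtn(18:0/20:4)
Control-DN	knn	TG(16:0/17:1/18:1)
Control-DN	knn	1,1-Dimethylbiguanide
Control-DN	knn	5-Pentahydroxy-5-cucurbiten-11-one 3-[glucosyl-(1->6)-glucoside]
Control-DN	knn	PG(PGF1alpha/i-16:0)
Control-DN	knn	TG(16:0/18:1/18:1)
Control-DN	knn	DG(i-18:0/22:6-OH/0:0)
Control-DN	knn	Butyl methacrylate
Control-DN	knn	DG(20:4/16:0/0:0)
Control-DN	knn	Androst-16-ene
Control-DN	knn	Threonyltyrosine
Control-DN	knn	DG(a-25:0/0:0/a-13:0)
Control-DN	knn	GPCho(20:2/18:0)
Control-DN	knn	Cholest-8-en-3-ol
Control-DN	knn	Cer(d18:1/24:1) i2
Control-DN	knn	9-Decenoylcarnitine
Control-DN	knn	PA(22:1/17:0)
Control-DN	knn	PE(TXB2/DiMe)
Control-DN	knn	(2Z,4E,6Z)-Decatrienoylcarnitine
Control-DN	knn	delta-24-Cholesterol
Control-DN	knn	3-methoxy-4-hydroxy-5-all-trans-hexaprenylbenzoate
Control-DN	knn	N-Methylethanolaminium phosphate
T2DM-DN	nearcent	SM(d19:0/20:3-OH)
T2DM-DN	nearcent	TG(16:0/17:1/18:1)
T2DM-DN	nearcent	5-Pentahydroxy-5-cucurbiten-11-one 3-[glucosyl-(1->6)-glucoside]
T2DM-DN	nearcent	PS(PGJ2/22:6)
T2DM-DN	nearcent	TG(16:0/18:1/18:1)
T2DM-DN	nearcent	GPEtn(18:0/20:4)
T2DM-DN	nearcent	Butyl methacrylate
T2DM-DN	nearcent	PC(22:6-2OH/P-16:0)
T2DM-DN	nearcent	Cer(d18:1/24:1) i2
T2DM-DN	nearcent	PC(P-20:0/14:1)
T2DM-DN	nearcent	PA(19:1/16:0)
T2DM-DN	nearcent	CerP(d15:0/2:0)
T2DM-DN	nearcent	PC(22:6-2OH/P-18:0)
T2DM-DN	nearcent	SM(d16:1/18:0)
T2DM-DN	nearcent	MG(20:4/0:0/0:0)
T2DM-DN	nearcent	MG(18:1/0:0/0:0)
T2DM-DN	nearcent	1,1-Dimethylbiguanide
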