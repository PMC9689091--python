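comparison	models	metabolite
Control-Prediabetes	knn_nearcent_svm	PC(20:3-OH/P-18:1)
Control-Prediabetes	knn_nearcent_svm	TG(17:1/17:2/22:5)
Control-Prediabetes	knn_nearcent	TG(17:1/18:1/18:1)
Control-Prediabetes	knn_nearcent	Glufosinate
Control-Prediabetes	knn_nearcent	PC(18:1-O/20:1)
Control-Prediabetes	knn_nearcent	DGDG(20:5/14:0)
Control-Prediabetes	knn_nearcent	TG(18:0/18:1/20:2)
Control-Prediabetes	knn_nearcent	lysine phosphoester
Control-Prediabetes	knn_nearcent	TG(17:0/18:1/20:2)
Control-Prediabetes	knn_svm	GPCho(20:2/18:1)
Control-Prediabetes	knn_svm	Cer(d18:1/24:1) i2
Control-T2DM	knn_nearcent_svm	Androst-16-ene
Control-T2DM	knn_nearcent_svm	Ganoderic acid C2
Control-T2DM	knn_nearcent_svm	Cer(d18:2/20:4-3OH)
Control-T2DM	knn_nearcent_svm	SM(d18:1/24:1) i2
Control-T2DM	knn_svm	Cholestan-3-one
Control-T2DM	knn_svm	PA(18:1/18:2) i2
Control-T2DM	knn_svm	GPA(26:2/6:0)
Control-T2DM	knn_svm	CE(18:2+=O)
Control-T2DM	nearcent_svm	(Z)-11-Hexadecenal
Prediabetes-T2DM	knn_nearcent	PC(20:3-OH/P-18:1)
Prediabetes-T2DM	knn_svm	Ganoderic acid C2
Control-DN	knn_nearcent_svm	5beta-Cholestanone
Control-DN	knn_nearcent_svm	DG(a-25:0/0:0/a-13:0)
Control-DN	knn_nearcent_svm	PG(PGF1alpha/i-16:0)
Control-DN	knn_nearcent_svm	DG(20:4/16:0/0:0)
Control-DN	knn_nearcent_svm	N-Methylethanolaminium phosphate
Control-DN	knn_nearcent_svm	GPEtn(18:0/20:4)
Control-DN	knn_nearcent_svm	TG(16:0/17:1/18:1)
Control-DN	knn_svm	Cer(d18:1/24:1) i2
Control-DN	nearcent_svm	GPSer(18:1/11:0)
Control-DN	nearcent_svm	PC(18:0/18:1-2OH)
T2DM-DN	knn_nearcent_svm	Butyl.methacrylate
T2DM-DN	knn_nearcent_svm	TG(16:0/17:1/18:1)
T2DM-DN	knn_nearcent_svm	Cer(d18:1/24:1) i2
T2DM-DN	knn_nearcent_svm	TG(16:0/18:1/18:1)
T2DM-DN	knn_nearcent_svm	1,1-Dimethylbiguanide
T2DM-DN	knn_nearcent_svm	PS(PGJ2/22:6)
T2DM-DN	knn_nearcent_svm	5-Pentahydroxy-5-cucurbiten-11-one 3-[glucosyl-(1->6)-glucoside]
T2DM-DN	knn_nearcent	SM(d19:0/20:3-OH)
T2DM-DN	knn_nearcent	GPEtn(18:0/20:4)
T2DM-DN	knn_nearcent	PC(22:6-2OH/P-16:0)
T2DM-DN	knn_nearcent	CerP(d15:0/2:0)
T2DM-DN	knn_nearcent	PC(22:6-2OH/P-18:0)
T2DM-DN	knn_nearcent	SM(d16:1/18:0)
T2DM-DN	knn_nearcent	PA(19:1/16:0)
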