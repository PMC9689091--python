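comparison	method	average_accuracy
Control-Prediabetes	knn	0.8143
Control-Prediabetes	nearcent	0.8321
Control-Prediabetes	svm	0.8464
Control-T2DM	knn	0.9268
Control-T2DM	nearcent	0.9286
Control-T2DM	svm	0.9036
Prediabetes-T2DM	knn	0.7821
Prediabetes-T2DM	nearcent	0.7982
Prediabetes-T2DM	svm	0.8214
Control-DN	knn	0.9893
Control-DN	nearcent	0.9714
Control-DN	svm	0.9857
T2DM-DN	knn	0.9054
T2DM-DN	nearcent	0.9125
T2DM-DN	svm	0.8804
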