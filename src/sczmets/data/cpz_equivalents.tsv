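drug_name	cpz_factor
chlorpromazine	1.0
quetiapine	1.33
olanzapine	20.0
aripiprazole	13.3
clozapine	1.0
risperidone	50.0
haloperidol	50.0
amisulpride	1.0
sertindole	25.0
flupentixol	33.3
perphenazine	10.0
ziprasidone	2.5
levomepromazine	1.0
zuclopenthixol	4.0
chlorprothixene	1.0
sulpiride	0.5
cariprazine	33.3
melperone	1.0
fluphenazine	50.0
paliperidone	33.3
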