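pt	soc
Abnormal behavior	Psychiatric disorders
Abortion spontaneous	Pregnancy, puerperium and perinatal conditions
Acute psychosis	Psychiatric disorders
Affective disorder	Psychiatric disorders
Aggression	Psychiatric disorders
Agitation	Psychiatric disorders
Altered state of consciousness	Nervous system disorders
Amnesia	Nervous system disorders
Anger	Psychiatric disorders
Anticoagulation drug level abnormal	Investigations
Anticonvulsant drug level above therapeutic	Investigations
Anticonvulsant drug level decreased	Investigations
Anticonvulsant drug level increased	Investigations
Apathy	Psychiatric disorders
Aphasia	Nervous system disorders
Apraxia	Nervous system disorders
Ataxia	Nervous system disorders
Atrial flutter	Cardiac disorders
Atrial septal defect	Congenital, familial and genetic disorders
Atrioventricular block	Cardiac disorders
Atrioventricular block complete	Cardiac disorders
Atrioventricular block first degree	Cardiac disorders
Atrioventricular block second degree	Cardiac disorders
Balance disorder	Nervous system disorders
Behavior disorder	Psychiatric disorders
Blood sodium decreased	Investigations
Bradycardia	Cardiac disorders
Bradycardia neonatal	Cardiac disorders
Bradyphrenia	Nervous system disorders
Brain fog	Nervous system disorders
Brugada syndrome	Congenital, familial and genetic disorders
Bundle branch block left	Cardiac disorders
Bundle branch block right	Cardiac disorders
Cardiac septal defect	Congenital, familial and genetic disorders
Cell death	Metabolism and nutrition disorders
Cerebral disorder	Nervous system disorders
Clumsiness	Nervous system disorders
Coarctation of the aorta	Congenital, familial and genetic disorders
Cognitive disorder	Nervous system disorders
Communication disorder	Psychiatric disorders
Conduction disorder	Cardiac disorders
Confusional state	Psychiatric disorders
Congenital hydronephrosis	Congenital, familial and genetic disorders
Coordination abnormal	Nervous system disorders
Crying	General disorders and administration site conditions
Cryptorchism	Congenital, familial and genetic disorders
Cytogenetic abnormality	Congenital, familial and genetic disorders
Defect conduction intraventricular	Cardiac disorders
Delirium	Psychiatric disorders
Dementia	Nervous system disorders
Diplopia	Eye disorders
Disturbance in attention	Nervous system disorders
Dizziness	Nervous system disorders
Drop attacks	Nervous system disorders
Drug eruption	Skin and subcutaneous tissue disorders
Drug interaction	General disorders and administration site conditions
Drug intolerance	General disorders and administration site conditions
Drug withdrawal convulsions	Nervous system disorders
Dysarthria	Nervous system disorders
Dysgraphia	Nervous system disorders
Dyslexia	Nervous system disorders
Dysphemia	Psychiatric disorders
Dysstasia	Nervous system disorders
Electrocardiogram pr prolongation	Cardiac disorders
Electrocardiogram qrs complex prolonged	Cardiac disorders
Emotional disorder	Psychiatric disorders
Epilepsy	Nervous system disorders
Eye movement disorder	Nervous system disorders
Fall	Injury, poisoning and procedural complications
Fatigue	General disorders and administration site conditions
Febrile convulsion	Nervous system disorders
Feeling abnormal	General disorders and administration site conditions
Feeling drunk	General disorders and administration site conditions
Fetal malformation	Congenital, familial and genetic disorders
Gait disturbance	General disorders and administration site conditions
Gait inability	General disorders and administration site conditions
Headache	Nervous system disorders
Hepatic arteriovenous malformation	Congenital, familial and genetic disorders
Hiccups	Respiratory, thoracic and mediastinal disorders
Homicidal ideation	Psychiatric disorders
Hydrops foetalis	Pregnancy, puerperium and perinatal conditions
Hyperammonaemia	Metabolism and nutrition disorders
Hypersomnia	Nervous system disorders
Impaired quality of life	Social circumstances
Impaired work ability	Social circumstances
Impulse-control disorder	Psychiatric disorders
Inappropriate affect	Psychiatric disorders
Insomnia	Psychiatric disorders
Irritability	Psychiatric disorders
Lethargy	Nervous system disorders
Lichenoid keratosis	Skin and subcutaneous tissue disorders
Logorrhoea	Psychiatric disorders
Loss of consciousness	Nervous system disorders
Marasmus	Metabolism and nutrition disorders
Memory impairment	Nervous system disorders
Mental impairment	Psychiatric disorders
Mood altered	Psychiatric disorders
Mood swings	Psychiatric disorders
Motor dysfunction	Nervous system disorders
Multiple congenital abnormalities	Congenital, familial and genetic disorders
Multiple-drug resistance	General disorders and administration site conditions
Nystagmus	Nervous system disorders
Paranoia	Psychiatric disorders
Partial seizures	Nervous system disorders
Persecutory delusion	Psychiatric disorders
Personality change	Psychiatric disorders
Polydactyly	Congenital, familial and genetic disorders
Premature baby	Pregnancy, puerperium and perinatal conditions
Premature delivery	Pregnancy, puerperium and perinatal conditions
Psychomotor retardation	Psychiatric disorders
Psychotic disorder	Psychiatric disorders
Screaming	General disorders and administration site conditions
Sedation	Nervous system disorders
Seizure	Nervous system disorders
Sinus arrest	Cardiac disorders
Sinus bradycardia	Cardiac disorders
Sinus node dysfunction	Cardiac disorders
Slow speech	Nervous system disorders
Somnolence	Nervous system disorders
Speech disorder	Nervous system disorders
Spina bifida	Congenital, familial and genetic disorders
Staring	Psychiatric disorders
Stillbirth	Pregnancy, puerperium and perinatal conditions
Suicidal ideation	Psychiatric disorders
Supraventricular extrasystoles	Cardiac disorders
Syncope	Nervous system disorders
Systolic hypertension	Vascular disorders
Tongue biting	Nervous system disorders
Tremor	Nervous system disorders
Trisomy 18	Congenital, familial and genetic disorders
Ventricular tachycardia	Cardiac disorders
Vision blurred	Eye disorders
Drug ineffective	General disorders and administration site conditions
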