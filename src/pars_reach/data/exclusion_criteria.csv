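id,direction,category,pattern,description,source
EXC001,exclusion,moderate/severe asthma,J45.4*,Moderate persistent asthma (all subcodes),reconstruction
EXC002,exclusion,moderate/severe asthma,J45.5*,Severe persistent asthma (all subcodes),reconstruction
EXC003,exclusion,recent myocardial infarction,I21*,Acute myocardial infarction,reconstruction
EXC004,exclusion,recent myocardial infarction,I22*,Subsequent ST/non-ST elevation myocardial infarction,reconstruction
EXC005,exclusion,recent myocardial infarction,I23*,Current complications following acute myocardial infarction,reconstruction
EXC006,exclusion,embolism,I26*,Pulmonary embolism,reconstruction
EXC007,exclusion,embolism,I74*,Arterial embolism and thrombosis,reconstruction
EXC008,exclusion,embolism,I82*,Other venous embolism and thrombosis,reconstruction
EXC009,exclusion,embolism,I80.1*,Phlebitis and thrombophlebitis of femoral vein,reconstruction
EXC010,exclusion,embolism,I80.2*,Phlebitis and thrombophlebitis of other and unspecified deep vessels of lower extremities,reconstruction
EXC011,exclusion,embolism,I81,Portal vein thrombosis,reconstruction
EXC012,exclusion,aortic stenosis,I35.0,Nonrheumatic aortic (valve) stenosis,reconstruction
EXC013,exclusion,aortic stenosis,I35.2,Nonrheumatic aortic (valve) stenosis with insufficiency,reconstruction
EXC014,exclusion,aortic stenosis,I06.0,Rheumatic aortic stenosis,reconstruction
EXC015,exclusion,atrial fibrillation,I48.0,Paroxysmal atrial fibrillation,reconstruction
EXC016,exclusion,atrial fibrillation,I48.1*,Persistent atrial fibrillation,reconstruction
EXC017,exclusion,atrial fibrillation,I48.2*,Chronic atrial fibrillation,reconstruction
EXC018,exclusion,atrial fibrillation,I48.91,Unspecified atrial fibrillation,reconstruction
EXC019,exclusion,atrial fibrillation,I48.92,Unspecified atrial flutter,reconstruction
EXC020,exclusion,arrhythmia,I47*,Paroxysmal tachycardia,reconstruction
EXC021,exclusion,arrhythmia,I49.01,Ventricular fibrillation,reconstruction
EXC022,exclusion,cardiac arrest,I46*,Cardiac arrest,reconstruction
EXC023,exclusion,heart failure,I50.2*,Systolic (congestive) heart failure,reconstruction
EXC024,exclusion,heart failure,I50.3*,Diastolic (congestive) heart failure,reconstruction
EXC025,exclusion,heart failure,I50.4*,Combined systolic and diastolic heart failure,reconstruction
EXC026,exclusion,heart failure,I50.9,"Heart failure, unspecified",reconstruction
EXC027,exclusion,unstable angina,I20.0,Unstable angina,reconstruction
EXC028,exclusion,myocarditis,I40*,Acute myocarditis,reconstruction
EXC029,exclusion,myocarditis,I51.4,"Myocarditis, unspecified",reconstruction
EXC030,exclusion,pericarditis,I30*,Acute pericarditis,reconstruction
EXC031,exclusion,endocarditis,I33*,Acute and subacute endocarditis,reconstruction
EXC032,exclusion,hypertrophic cardiomyopathy,I42.1,Obstructive hypertrophic cardiomyopathy,reconstruction
EXC033,exclusion,hypertrophic cardiomyopathy,I42.2,Other hypertrophic cardiomyopathy,reconstruction
EXC034,exclusion,aortic aneurysm/dissection,I71.0*,Dissection of aorta,reconstruction
EXC035,exclusion,aortic aneurysm/dissection,I71.1,"Thoracic aortic aneurysm, ruptured",reconstruction
EXC036,exclusion,aortic aneurysm/dissection,I71.3,"Abdominal aortic aneurysm, ruptured",reconstruction
EXC037,exclusion,stroke,I60*,Nontraumatic subarachnoid hemorrhage,reconstruction
EXC038,exclusion,stroke,I61*,Nontraumatic intracerebral hemorrhage,reconstruction
EXC039,exclusion,stroke,I63*,Cerebral infarction,reconstruction
EXC040,exclusion,transient ischemic attack,G45*,Transient cerebral ischemic attacks and related syndromes,reconstruction
EXC041,exclusion,mitral stenosis,I05.0,Rheumatic mitral stenosis,reconstruction
EXC042,exclusion,pulmonary hypertension,I27.0,Primary pulmonary hypertension,reconstruction
EXC043,exclusion,chronic kidney disease,N18.1,Chronic kidney disease stage 1,reconstruction
EXC044,exclusion,chronic kidney disease,N18.2,Chronic kidney disease stage 2 (mild),reconstruction
EXC045,exclusion,chronic kidney disease,N18.30,Chronic kidney disease stage 3 unspecified,reconstruction
EXC046,exclusion,chronic kidney disease,N18.31,Chronic kidney disease stage 3a,reconstruction
EXC047,exclusion,chronic kidney disease,N18.32,Chronic kidney disease stage 3b,reconstruction
EXC048,exclusion,chronic kidney disease,N18.4,Chronic kidney disease stage 4 (severe),reconstruction
EXC049,exclusion,chronic kidney disease,N18.5,Chronic kidney disease stage 5,reconstruction
EXC050,exclusion,dialysis dependence,Z99.2,Dependence on renal dialysis,reconstruction
EXC051,exclusion,fracture,S02*,Fracture of skull and facial bones,reconstruction
EXC052,exclusion,fracture,S12*,Fracture of cervical vertebra and other parts of neck,reconstruction
EXC053,exclusion,fracture,S22*,"Fracture of rib(s), sternum and thoracic spine",reconstruction
EXC054,exclusion,fracture,S32*,Fracture of lumbar spine and pelvis,reconstruction
EXC055,exclusion,fracture,S42*,Fracture of shoulder and upper arm,reconstruction
EXC056,exclusion,fracture,S52*,Fracture of forearm,reconstruction
EXC057,exclusion,fracture,S62*,Fracture at wrist and hand level,reconstruction
EXC058,exclusion,fracture,S72*,Fracture of femur,reconstruction
EXC059,exclusion,fracture,S82*,"Fracture of lower leg, including ankle",reconstruction
EXC060,exclusion,fracture,S92*,"Fracture of foot and toe, except ankle",reconstruction
EXC061,exclusion,acute respiratory failure,J96.0*,Acute respiratory failure,reconstruction
EXC062,exclusion,COPD exacerbation,J44.1,Chronic obstructive pulmonary disease with (acute) exacerbation,reconstruction
EXC063,exclusion,acute illness,J18*,"Pneumonia, unspecified organism",reconstruction
EXC064,exclusion,acute illness,A41*,Other sepsis,reconstruction
EXC065,exclusion,acute illness,U07.1,COVID-19,reconstruction
EXC066,exclusion,syncope,R55,Syncope and collapse,reconstruction
EXC067,exclusion,dizziness,R42,Dizziness and giddiness,reconstruction
EXC068,exclusion,acute illness,D62,Acute posthemorrhagic anemia,reconstruction
EXC069,exclusion,acute illness,K92.2,"Gastrointestinal hemorrhage, unspecified",reconstruction
EXC070,exclusion,orthostatic hypotension,I95.1,Orthostatic hypotension,reconstruction
EXC071,exclusion,active cancer treatment,Z51.1*,Encounter for antineoplastic chemotherapy and immunotherapy,reconstruction
EXC072,exclusion,palliative care,Z51.5,Encounter for palliative care,reconstruction
EXC073,exclusion,oxygen dependence,Z99.81,Dependence on supplemental oxygen,reconstruction
EXC074,exclusion,recent surgery,Z48.0*,Encounter for attention to dressings and sutures,reconstruction
EXC075,exclusion,recent surgery,Z48.2*,Encounter for aftercare following organ transplant,reconstruction
EXC076,exclusion,recent surgery,Z47.1,Aftercare following joint replacement surgery,reconstruction
EXC077,exclusion,recent surgery,T84.0*,Mechanical complication of internal joint prosthesis,reconstruction
EXC078,exclusion,acute respiratory distress,J80,Acute respiratory distress syndrome,reconstruction
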