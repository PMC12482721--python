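id,direction,category,pattern,description,source
INC001,inclusion,physical inactivity,Z71.82,Exercise counseling,reconstruction
INC002,inclusion,physical inactivity,Z72.3,Lack of physical exercise,reconstruction
INC003,inclusion,physical inactivity,Z91.89,"Other specified personal risk factors, not elsewhere classified (e.g. sedentary)",reconstruction
INC004,inclusion,obesity,E66.01,Morbid (severe) obesity due to excess calories,reconstruction
INC005,inclusion,obesity,E66.09,Other obesity due to excess calories,reconstruction
INC006,inclusion,obesity,E66.1,Drug-induced obesity,reconstruction
INC007,inclusion,obesity,E66.9,"Obesity, unspecified",reconstruction
INC008,inclusion,obesity,Z68.30,Body mass index (BMI) 30.0-30.9 adult,reconstruction
INC009,inclusion,obesity,Z68.31,Body mass index (BMI) 31.0-31.9 adult,reconstruction
INC010,inclusion,obesity,Z68.32,Body mass index (BMI) 32.0-32.9 adult,reconstruction
INC011,inclusion,obesity,Z68.33,Body mass index (BMI) 33.0-33.9 adult,reconstruction
INC012,inclusion,obesity,Z68.34,Body mass index (BMI) 34.0-34.9 adult,reconstruction
INC013,inclusion,obesity,Z68.35,Body mass index (BMI) 35.0-35.9 adult,reconstruction
INC014,inclusion,obesity,Z68.36,Body mass index (BMI) 36.0-36.9 adult,reconstruction
INC015,inclusion,obesity,Z68.37,Body mass index (BMI) 37.0-37.9 adult,reconstruction
INC016,inclusion,obesity,Z68.38,Body mass index (BMI) 38.0-38.9 adult,reconstruction
INC017,inclusion,obesity,Z68.39,Body mass index (BMI) 39.0-39.9 adult,reconstruction
INC018,inclusion,obesity,Z68.41,Body mass index (BMI) 40.0-44.9 adult,reconstruction
INC019,inclusion,obesity,Z68.42,Body mass index (BMI) 45.0-49.9 adult,reconstruction
INC020,inclusion,obesity,Z68.43,Body mass index (BMI) 50.0-59.9 adult,reconstruction
INC021,inclusion,dyslipidemia,E78.00,"Pure hypercholesterolemia, unspecified",reconstruction
INC022,inclusion,dyslipidemia,E78.1,Pure hyperglyceridemia,reconstruction
INC023,inclusion,dyslipidemia,E78.2,Mixed hyperlipidemia,reconstruction
INC024,inclusion,dyslipidemia,E78.5,"Hyperlipidemia, unspecified",reconstruction
INC025,inclusion,diabetes,E10.9,Type 1 diabetes mellitus without complications,reconstruction
INC026,inclusion,diabetes,E11.9,Type 2 diabetes mellitus without complications,reconstruction
INC027,inclusion,diabetes,E11.65,Type 2 diabetes mellitus with hyperglycemia,reconstruction
INC028,inclusion,diabetes,E13.9,Other specified diabetes mellitus without complications,reconstruction
INC029,inclusion,diabetes,R73.03,Prediabetes,reconstruction
INC030,inclusion,hypertension,I10,Essential (primary) hypertension,reconstruction
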