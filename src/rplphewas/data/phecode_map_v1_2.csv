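icd_code,icd_flavor,phecode,phecode_string,category
626.4,9,626.4,Irregular menstrual cycle/bleeding,genitourinary
N92.6,10,626.4,Irregular menstrual cycle/bleeding,genitourinary
626.0,9,626.1,Absent or infrequent menstruation,genitourinary
N91.1,10,626.1,Absent or infrequent menstruation,genitourinary
626.2,9,626.2,Excessive or frequent menstruation,genitourinary
N92.0,10,626.2,Excessive or frequent menstruation,genitourinary
625.3,9,625.1,Dysmenorrhea,genitourinary
N94.6,10,625.1,Dysmenorrhea,genitourinary
628.9,9,628,"Infertility, female",genitourinary
N97.9,10,628,"Infertility, female",genitourinary
617.9,9,615,Endometriosis,genitourinary
N80.9,10,615,Endometriosis,genitourinary
256.4,9,256.4,Polycystic ovaries,endocrine/metabolic
E28.2,10,256.4,Polycystic ovaries,endocrine/metabolic
256.9,9,256.3,Ovarian dysfunction,endocrine/metabolic
E28.9,10,256.3,Ovarian dysfunction,endocrine/metabolic
256.31,9,256.2,Premature menopause and other ovarian failure,endocrine/metabolic
E28.3,10,256.2,Premature menopause and other ovarian failure,endocrine/metabolic
244.9,9,244,Hypothyroidism,endocrine/metabolic
E03.9,10,244,Hypothyroidism,endocrine/metabolic
245.2,9,245.21,Chronic lymphocytic thyroiditis,endocrine/metabolic
E06.3,10,245.21,Chronic lymphocytic thyroiditis,endocrine/metabolic
289.81,9,286.81,Primary hypercoagulable state,hematopoietic
D68.59,10,286.81,Primary hypercoagulable state,hematopoietic
250.00,9,250.2,Type 2 diabetes,endocrine/metabolic
E11.9,10,250.2,Type 2 diabetes,endocrine/metabolic
401.9,9,401,Essential hypertension,circulatory system
I10,10,401,Essential hypertension,circulatory system
278.00,9,278.1,Obesity,endocrine/metabolic
E66.9,10,278.1,Obesity,endocrine/metabolic
300.00,9,300,Anxiety disorder,mental disorders
F41.9,10,300,Anxiety disorder,mental disorders
311,9,296.2,Depression,mental disorders
F32.9,10,296.2,Depression,mental disorders
465.9,9,465,Acute upper respiratory infection,respiratory
J06.9,10,465,Acute upper respiratory infection,respiratory
616.10,9,619,Vaginitis and vulvovaginitis,genitourinary
N76.0,10,619,Vaginitis and vulvovaginitis,genitourinary
614.9,9,614,Pelvic inflammatory disease (NOS),genitourinary
N73.9,10,614,Pelvic inflammatory disease (NOS),genitourinary
218.9,9,218,Uterine leiomyoma,genitourinary
D25.9,10,218,Uterine leiomyoma,genitourinary
621.0,9,621.3,Polyp of corpus uteri,genitourinary
N84.0,10,621.3,Polyp of corpus uteri,genitourinary
277.7,9,277.7,Dysmetabolic syndrome X,endocrine/metabolic
E88.81,10,277.7,Dysmetabolic syndrome X,endocrine/metabolic
285.9,9,285,Other anemias,hematopoietic
D64.9,10,285,Other anemias,hematopoietic
564.00,9,563,Constipation,digestive
K59.00,10,563,Constipation,digestive
634.91,9,634.1,Miscarriage; stillbirth,pregnancy complications
O03.9,10,634.1,Miscarriage; stillbirth,pregnancy complications
650,9,650,Normal delivery,pregnancy complications
O80,10,650,Normal delivery,pregnancy complications
642.40,9,642,Preeclampsia and eclampsia,pregnancy complications
O14.90,10,642,Preeclampsia and eclampsia,pregnancy complications
646.90,9,649,Other complications of pregnancy NEC,pregnancy complications
O26.90,10,649,Other complications of pregnancy NEC,pregnancy complications
008.8,9,008,Intestinal infection,infectious diseases
A09,10,008,Intestinal infection,infectious diseases
079.99,9,079,Viral infection,infectious diseases
B34.9,10,079,Viral infection,infectious diseases
784.0,9,339,Headache,neurological
R51,10,339,Headache,neurological
493.90,9,495,Asthma,respiratory
J45.909,10,495,Asthma,respiratory
530.81,9,530.11,Gastroesophageal reflux disease,digestive
K21.9,10,530.11,Gastroesophageal reflux disease,digestive
V70.0,9,1019,Other tests,symptoms
Z00.00,10,1019,Other tests,symptoms
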