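term,group
aaa abdominal aortic aneurysm without mention of rupture,vascular
abdominal aneurysm which has ruptured,vascular
acid reflux,gastrointestinal
acute cor pulmonale,vascular
acute coronary syndrome,cardiac
acute exacerbation of asthma,respiratory
acute exacerbation of chronic obstructive airways disease,respiratory
acute infective otitis externa,infection
acute lower respiratory tract infection,infection
acute myeloid leukaemia,cancer
acute non st myocardial infarction,cardiac
acute non st segment elevation myocardial infarction,cardiac
acute pericarditis,cardiac
acute renal failure,renal
acute st elevation myocardial infarction,cardiac
acute st myocardial infarction,cardiac
acute upper respiratory tract infection,infection
alcohol withdrawal syndrome,other
alcoholic cirrhosis of liver,gastrointestinal
angioedema,other
aortic regurgitation alone cause unspecified,cardiac
aortic stenosis,cardiac
aortic stenosis alone cause unspecified,cardiac
arterial leg ulcer,vascular
arthralgia of hip,osteoarticular
arthropathy nos,osteoarticular
aspiration pneumonitis,respiratory
atrial flutter,cardiac
background diabetic retinopathy,endocrine
basal pneumonia due to unspecified organism,infection
bowel infarction,vascular
breathlessness,other
bullous pemphigoid,other
callosity on foot,osteoarticular
cardiac arrest,cardiac
cardiac arrhythmias,cardiac
cardiac dysrhythmia nos,cardiac
cardiac dysrhythmias,cardiac
cardiac failure,cardiac
cardiomegaly,cardiac
cardiomyopathy,cardiac
catheter complications,frailty
cellulitis nos,infection
cerebellar stroke syndrome,cerebrovascular
cerebral infarction due to thrombosis of cerebral artery,cerebrovascular
cerebral infarction due to unspecified occlusion or stenosis of unspecified cerebral artery,cerebrovascular
cerebral infarction nos,cerebrovascular
cerebrovascular disease nos,cerebrovascular
chronic anaemia,haematological
chronic myeloid leukaemia,cancer
chronic osteomyelitis,infection
chronic pancreatitis,endocrine
chronic skin ulcer,frailty
cirrhosis and chronic liver disease,gastrointestinal
clostridium difficile infection,infection
confusion,frailty
conjunctivitis,infection
constipation nos,gastrointestinal
copd,respiratory
coronary artery bypass occlusion,cardiac
coronary artery disease,cardiac
cva cerebral artery occlusion,cerebrovascular
diabetes mellitus with peripheral circulatory disorder,vascular
diffuse pulmonary fibrosis,respiratory
double coronary vessel disease,cardiac
drug hypersensitivity nos,other
echocardiogram abnormal,cardiac
ectopic beats,cardiac
empyema,infection
folic acid deficiency,endocrine
fragility fracture,osteoarticular
generalized anxiety disorder,other
geriatric fall,frailty
glioblastoma multiforme,cancer
glucose intolerance,endocrine
heart beats irregular,cardiac
heart failure,cardiac
hepatocelullar carcinoma,cancer
homonymous hemianopia,other
hypomagnesemia,endocrine
hyponatraemia,endocrine
idiopathic thrombocytopenic purpura,haematological
impaired fasting glycemia,endocrine
impaired glucose tolerance,endocrine
impaired renal function,renal
incisional hernia,other
infarction of basal ganglia,cerebrovascular
infected dermatitis,infection
infection toe,infection
infective otitis externa,infection
ingrowing great toe nail,other
injury and poisoning nos,other
insulin dependent diabetes mellitus,endocrine
intracerebral haemorrhage,bleeding
iron deficiency,endocrine
ischaemia of legs,vascular
ischaemic cardiomyopathy,cardiac
keloid scar,other
laryngopharyngeal reflux,respiratory
left sided cva,cerebrovascular
left ventricular systolic dysfunction,cardiac
leg pain,osteoarticular
lipodermatosclerosis,vascular
low blood pressure reading,vascular
malignant neoplasm of endometrium of corpus uteri,cancer
malignant neoplasm of oesophagus,cancer
malignant neoplasm of oesophagus nos,cancer
malignant neoplasm of trachea bronchus and lung,cancer
malignant pleural effusion,cancer
mechanical complication of urethral catheter,frailty
meningiomas,cancer
microcytic hypochromic anaemia,haematological
mitral regurgitation,cardiac
mitral stenosis,cardiac
mixed venous and arterial leg ulcer,vascular
moderate chronic obstructive pulmonary disease,respiratory
moderate depressive episode,other
multiple organ failure,frailty
nasal vestibulitis,infection
non proliferative diabetic retinopathy,endocrine
obstructive sleep apnoea,respiratory
oesophageal cancer,cancer
other aspiration pneumonia as a complication of care,infection
other cellulitis and abscess,infection
other specified pneumonia or influenza,infection
palpitations,cardiac
pancytopenia acquired,haematological
pancytopenia nos,haematological
paronychia of toe,infection
paroxysmal atrial tachycardia,cardiac
perforation of intestine,gastrointestinal
peripheral oedema,vascular
peritonitis,infection
pilonidal sinus cyst,infection
pleural effusion nos,respiratory
pneumonia influenza,infection
polyarthropathy nec,osteoarticular
polycythaemia vera,cancer
prediabetes,endocrine
primary pulmonary hypertension,vascular
problem with vaginal pessary,other
proteinuria,renal
pruritus vulvae,other
pseudogout,osteoarticular
pulmonary embolism,vascular
pulmonary oedema nos,cardiac
raised blood pressure reading,vascular
recurrent chest infection,infection
respiratory failure,respiratory
right sided cerebral infarction,cerebrovascular
scalp psoriasis,other
seborrhoeic dermatitis capitis,other
sepsis,infection
severe chronic obstructive pulmonary disease,respiratory
single coronary vessel disease,cardiac
sinus tachycardia,cardiac
skin lesion,other
slurred speech,frailty
small bowel obstruction nos,gastrointestinal
stroke due to cerebral arterial occlusion,cerebrovascular
stroke unspecified,cerebrovascular
subdural haemorrhage nos,bleeding
supraventricular tachycardia nos,cardiac
symptoms signs and ill defined conditions,frailty
tachycardia unspecified,cardiac
thyrotoxicosis,endocrine
tired all the time,frailty
triple vessel disease of the heart,cardiac
ulcer of skin,frailty
uncertain diagnosis,frailty
venous ulcer of leg,vascular
ventricular septal defect,cardiac
ventricular tachycardia,cardiac
viral gastroenteritis,infection
vitamin d deficiency,endocrine
wet senile macular degeneration,frailty
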