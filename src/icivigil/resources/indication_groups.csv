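keyword,group
LUNG,Lung cancer
NSCLC,Lung cancer
SMALL CELL,Lung cancer
BRONCH,Lung cancer
MELANOMA,Melanoma
RENAL,Tumors of urinary system
KIDNEY,Tumors of urinary system
BLADDER,Tumors of urinary system
UROTHELIAL,Tumors of urinary system
URETER,Tumors of urinary system
URINARY,Tumors of urinary system
HEAD AND NECK,Head and neck cancer
NASOPHARYN,Head and neck cancer
OROPHARYN,Head and neck cancer
LARYN,Head and neck cancer
LYMPHOMA,Hematological cancer and lymphoma
HODGKIN,Hematological cancer and lymphoma
LEUKAEMIA,Hematological cancer and lymphoma
LEUKEMIA,Hematological cancer and lymphoma
MYELOMA,Hematological cancer and lymphoma
OVARIAN,Tumors of female reproductive organs
CERVIX,Tumors of female reproductive organs
CERVICAL,Tumors of female reproductive organs
ENDOMETRI,Tumors of female reproductive organs
UTERINE,Tumors of female reproductive organs
FALLOPIAN,Tumors of female reproductive organs
GASTRIC,Gastrointestinal cancer
STOMACH,Gastrointestinal cancer
COLORECTAL,Gastrointestinal cancer
COLON,Gastrointestinal cancer
RECTAL,Gastrointestinal cancer
OESOPHAG,Gastrointestinal cancer
ESOPHAG,Gastrointestinal cancer
PANCREA,Gastrointestinal cancer
BREAST,Breast cancer
MESOTHELIOMA,Mesothelioma
HEPATOCELLULAR,Hepatocellular carcinoma
HEPATIC CANCER,Hepatocellular carcinoma
LIVER CANCER,Hepatocellular carcinoma
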