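characteristic,level,fatal,nonfatal
sex,female,137,424
sex,male,337,923
sex,unknown,33,91
age_band,<18,0,7
age_band,18-64,147,407
age_band,>=65,269,781
age_band,unknown,91,243
year,2011,7,12
year,2012,8,22
year,2013,5,19
year,2014,8,28
year,2015,23,58
year,2016,43,86
year,2017,55,179
year,2018,86,228
year,2019,85,260
year,2020,80,243
year,2021,107,303
continent,Europe,154,490
continent,America,186,648
continent,Asia,160,247
continent,Oceania,7,46
continent,Africa,0,4
continent,Unknown,0,3
indication,Lung cancer,175,452
indication,Melanoma,92,306
indication,Tumors of urinary system,75,241
indication,Head and neck cancer,32,39
indication,Hematological cancer and lymphoma,12,44
indication,Tumors of female reproductive organs,16,31
indication,Gastrointestinal cancer,17,27
indication,Breast cancer,6,26
indication,Mesothelioma,2,26
indication,Hepatocellular carcinoma,9,13
indication,Other,71,233
outcome,DE,507,0
outcome,LT,0,150
outcome,DS,0,25
outcome,HO,0,934
outcome,OT,0,299
outcome,RI,0,6
outcome,CA,0,1
outcome,NS,0,23
tto_band,0-30,154,404
tto_band,31-60,54,145
tto_band,61-90,37,88
tto_band,91-180,26,98
tto_band,>180,29,106
tto_band,unknown,207,597
regimen,Pembrolizumab,105,270
regimen,Nivolumab,197,564
regimen,Cemiplimab,2,6
regimen,Atezolizumab,54,170
regimen,Avelumab,7,22
regimen,Durvalumab,19,37
regimen,Ipilimumab,46,132
regimen,Ipilimumab + nivolumab,69,219
regimen,Ipilimumab + pembrolizumab,1,4
regimen,Tremelimumab + durvalumab,4,5
regimen,Pembrolizumab + atezolizumab,3,9
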