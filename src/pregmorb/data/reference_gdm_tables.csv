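condition,a,b,c,d,published_chi2
overweight,27542,7042,10617,3301,66.4
obesity,30570,6907,7589,3436,822.8
mental_disorders,34716,9472,3443,871,3.6
pcos,37164,9874,995,469,103.3
cardiovascular_disease,36991,9986,1168,357,3.9
substance_use,33079,9390,5080,953,125.1
thyroid_disease,35502,9424,2657,919,43.7
urinary_tract_infection,37386,10132,773,211,0.0
hypertension,37792,10129,367,214,83.4
vitamin_deficiency,27527,6956,10632,3387,94.2
asthma,34871,9505,3288,838,2.7
other_respiratory_disease,37978,10273,181,70,6.1
blood_disorders,34399,9282,3760,1061,1.4
iron_deficiency_anemia,37079,10115,1080,228,0.6
endometrial_disease,36732,9843,1427,500,25.3
migraine,37182,10046,977,297,1.0
kidney_disease,37829,10281,330,62,6.8
bowel_disease,37903,10301,256,42,8.9
genital_herpes,37899,10289,260,54,2.9
hemorrhoids,37963,10282,196,61,0.8
autoimmune_disease,37897,10270,262,73,0.0
musculoskeletal_disease,37628,10208,531,135,0.4
infertility,38077,10300,82,43,12.0
multimorbidity,23612,5356,14547,4987,344.3
advanced_age,30476,7113,7683,3230,573.8
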