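# Printed per-sample albumin-referenced relative amounts (human serum),
# three subjects (H1-H3) sampled in each trimester; columns t<tri>_<subj>.
# printed_* columns are the summary columns as printed (2 decimals);
# blank printed ratio cells correspond to an undetectable baseline.
category,no,protein,entry,accession,mw_kda,t1_H1,t1_H2,t1_H3,t2_H1,t2_H2,t2_H3,t3_H1,t3_H2,t3_H3,printed_mean1,printed_mean2,printed_mean3,printed_ratio21,printed_p21,printed_ratio31,printed_p31
1a,1,Pregnancy zone protein,PZP_HUMAN,P20742,164,8.32,0.00,0.00,25.59,4.32,4.03,21.75,0.00,0.00,2.77,11.32,7.25,4.08,0.09,2.61,0.21
1a,2,Antithrombin-III,ANT3_HUMAN,P01008,53,0.00,0.00,1.00,0.00,6.05,0.00,0.00,0.00,0.92,0.33,2.02,0.31,6.07,0.26,0.92,0.21
1a,3,Alpha-1-antichymotrypsin,AACT_HUMAN,P01011,48,0.00,0.00,0.00,0.00,6.05,0.00,0.00,0.00,0.00,0.00,2.02,0.00,,0.21,,
1a,4,Complement C1q subcomponent subunit C,C1QC_HUMAN,P02747,26,0.00,0.00,0.00,0.00,3.46,0.00,0.00,0.00,0.00,0.00,1.15,0.00,,0.21,,
1b,5,Serotransferrin,TRFE_HUMAN,P02787,77,39.51,30.93,31.92,29.68,69.20,57.49,86.98,26.89,177.83,34.12,52.12,97.23,1.53,0.17,2.85,0.14
1b,6,Apolipoprotein C-II,APOC2_HUMAN,P02655,11,5.20,12.80,13.96,7.16,10.38,20.17,20.71,28.01,21.08,10.65,12.57,23.27,1.18,0.26,2.18,0.02
1b,7,Sex hormone-binding globulin,SHBG_HUMAN,P04278,44,13.52,1.07,13.96,20.47,6.05,21.18,28.99,20.17,22.00,9.52,15.90,23.72,1.67,0.01,2.49,0.02
1b,8,Fibronectin,FINC_HUMAN,P02751,263,0.00,7.47,6.98,0.00,17.30,1.01,15.53,13.45,18.33,4.82,6.10,15.77,1.27,0.40,3.27,0.03
1b,9,Apolipoprotein L1,APOL1_HUMAN,O14791,44,2.08,3.20,3.99,1.02,2.60,4.03,6.21,10.08,4.58,3.09,2.55,6.96,0.83,0.12,2.25,0.08
1b,10,Hemoglobin subunit beta,HBB_HUMAN,P68871,16,0.00,1.07,0.00,2.05,0.86,0.00,3.11,0.00,10.08,0.36,0.97,4.40,2.73,0.24,12.37,0.17
1b,11,Hemoglobin subunit alpha,HBA_HUMAN,P69905,15,0.00,0.00,0.00,3.07,0.86,1.01,2.07,0.00,9.17,0.00,1.65,3.75,,0.07,,0.15
1b,12,Fibulin-1,FBLN1_HUMAN,P23142,77,0.00,0.00,0.00,0.00,1.73,1.01,5.18,5.60,10.08,0.00,0.91,6.95,,0.11,,0.02
1b,13,Complement component C8 alpha chain,CO8A_HUMAN,P07357,65,0.00,0.00,0.00,0.00,0.86,0.00,1.04,1.12,0.92,0.00,0.29,1.02,,0.21,,0.002
1b,14,Pregnancy-specific beta-1-glycoprotein 1,PSG1_HUMAN,P11464,47,0.00,0.00,0.00,0.00,0.00,0.00,21.75,11.20,22.00,0.00,0.00,18.32,,,,0.02
1b,15,"Actin, cytoplasmic 1",ACTB_HUMAN,P60709,42,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,22.00,0.00,0.00,7.33,,,,0.21
1b,16,Pregnancy-specific beta-1-glycoprotein 9,PSG9_HUMAN,Q00887,48,0.00,0.00,0.00,0.00,0.00,0.00,9.32,0.00,5.50,0.00,0.00,4.94,,,,0.10
2a,17,Complement C5,CO5_HUMAN,P01031,188,8.32,10.67,12.97,1.02,1.73,10.09,5.18,6.72,4.58,10.65,4.28,5.49,0.40,0.04,0.52,0.04
2a,18,Complement C1s subcomponent,C1S_HUMAN,P09871,77,2.08,3.20,2.99,0.00,0.00,3.03,1.04,3.36,0.92,2.76,1.01,1.77,0.37,0.10,0.64,0.13
2a,19,Plasma kallikrein,KLKB1_HUMAN,P03952,71,0.00,1.07,5.98,0.00,0.86,2.02,0.00,1.12,2.75,2.35,0.96,1.29,0.41,0.20,0.55,0.22
2a,20,Carboxypeptidase N subunit 2,CPN2_HUMAN,P22792,61,1.04,0.00,2.99,0.00,0.00,0.00,0.00,0.00,4.58,1.34,0.00,1.53,0.00,0.13,1.14,0.42
2b,21,Ig gamma-1 chain C region,IGHG1_HUMAN,P01857,36,29.12,18.13,26.93,22.52,23.36,14.12,9.32,6.72,15.58,24.73,20.00,10.54,0.81,0.89,0.43,0.02
2b,22,Ig lambda-2 chain C regions,LAC2_HUMAN,P0CG05,11,7.28,16.00,4.99,7.16,19.03,7.06,4.14,8.96,0.00,9.42,11.09,4.37,1.18,0.11,0.46,0.02
2b,23,Ig kappa chain C region,IGKC_HUMAN,P01834,12,2.08,3.20,2.99,3.07,4.32,2.02,2.07,0.00,0.92,2.76,3.14,1.00,1.14,0.32,0.36,0.10
2b,24,Histidine-rich glycoprotein,HRG_HUMAN,P04196,60,2.08,3.20,0.00,2.05,0.86,0.00,0.00,0.00,0.00,1.76,0.97,0.00,0.55,0.21,0.00,0.10
2b,25,Inter-alpha-trypsin inhibitor heavy chain H3,ITIH3_HUMAN,Q06033,100,2.08,2.13,0.00,2.05,0.00,0.00,1.04,6.72,0.00,1.40,0.68,2.59,0.49,0.21,1.84,0.28
2b,26,Leucine-rich alpha-2-glycoprotein,A2GL_HUMAN,P02750,38,1.04,0.00,1.00,1.02,1.73,1.01,0.00,0.00,0.92,0.68,1.25,0.31,1.85,0.21,0.45,0.19
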