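# Printed per-sample albumin-referenced relative amounts (marmoset serum),
# subjects M1-M3 sampled at 50/100/120 days (trimesters 1-3); M3 had a
# premature birth, so its third-trimester cell is missing (blank, not zero).
category,no,protein,entry,accession,mw_kda,t1_M1,t1_M2,t1_M3,t2_M1,t2_M2,t2_M3,t3_M1,t3_M2,t3_M3,printed_mean1,printed_mean2,printed_mean3,printed_ratio21,printed_p21,printed_ratio31,printed_p31
1a,1,Alpha-2-macroglobulin-like,675677766,XP_002752342,165,31.05,0.00,14.15,331.99,217.41,230.18,75.30,35.86,,15.07,259.86,55.58,17.25,0.01,3.69,
1a,2,Hemoglobin alpha chain,122366,P18972,15,10.09,9.06,9.10,120.17,138.98,127.57,7.44,47.34,,9.41,128.91,27.39,13.69,0.001,2.91,
1a,3,Hemoglobin beta chain,122577,P18985,16,2.33,6.79,5.05,72.83,58.57,92.44,4.65,35.86,,4.72,74.62,20.26,15.79,0.01,4.29,
1a,4,Apolipoprotein A-II,296229454,XP_002760286,11,1.55,0.00,3.03,1.82,4.96,8.32,1.86,7.17,,1.53,5.03,4.52,3.29,0.08,2.96,
1a,5,Complement component C6,390460019,XP_002745070,106,1.55,0.00,0.00,6.07,3.97,2.77,2.79,0.00,,0.52,4.27,1.39,8.26,0.01,2.70,
1a,6,Pigment epithelium-derived factor,675657740,XP_008994618,47,0.78,1.13,1.01,0.00,13.90,0.00,1.86,0.00,,0.97,4.63,0.93,4.76,0.25,0.96,
1a,7,Immunoglobulin heavy chain variable region,20502564,AAM22526,15,1.55,0.00,0.00,1.21,1.99,2.77,0.93,0.00,,0.52,1.99,0.46,3.85,0.13,0.90,
1a,8,Zinc-alpha-2-glycoprotein-like,675642469,XP_008981062,27,0.78,0.00,0.00,3.03,0.00,2.77,0.93,0.00,,0.26,1.94,0.46,7.48,0.09,1.80,
1a,9,Insulin-like growth factor-binding protein complex acid labile subunit,296219288,XP_002755809,66,1.55,0.00,0.00,3.03,0.99,0.00,0.93,0.00,,0.52,1.34,0.46,2.59,0.10,0.90,
1a,10,Apolipoprotein E,296234066,XP_002762273,36,0.00,0.00,0.00,2.43,0.00,2.77,0.00,0.00,,0.00,1.73,0.00,,0.09,,
1a,11,Complement component C8 beta chain,296208073,XP_002750920,67,0.00,0.00,0.00,1.21,0.99,0.92,0.93,0.00,,0.00,1.04,0.46,,0.003,,
1b,12,Plasma serine protease inhibitor,675692410,XP_002754293,50,0.78,0.00,2.02,0.00,3.97,2.77,0.00,5.74,,0.93,2.25,2.87,2.41,0.22,3.08,
2a,13,Haptoglobin,296231486,XP_002761163,38,87.70,19.24,107.14,0.00,0.00,0.00,21.38,0.00,,71.36,0.00,10.69,0.00,0.06,0.15,
2b,14,Angiotensinogen,675750692,XP_008984059,54,32.60,21.51,33.35,17.60,19.86,30.51,15.80,7.17,,29.15,22.65,11.49,0.78,0.13,0.39,
2b,15,Alpha-1-acid glycoprotein 1,296229919,XP_002760492,25,16.30,21.51,5.05,6.07,9.93,2.77,3.72,2.87,,14.29,6.26,3.29,0.44,0.05,0.23,
2b,16,Complement C4-A,675651995,XP_002746418,193,20.96,5.66,16.17,12.14,8.93,21.26,9.30,0.00,,14.26,14.11,4.65,0.99,0.03,0.33,
2b,17,Gelsolin,675639222,XP_009000537,86,7.76,10.19,6.06,5.46,3.97,4.62,4.65,1.43,,8.00,4.69,3.04,0.59,0.08,0.38,
2b,18,Leucine-rich alpha-2-glycoprotein,296232579,XP_002761694,38,5.43,1.13,16.17,1.21,12.91,3.70,0.00,0.00,,7.58,5.94,0.00,0.78,0.23,0.00,
2b,19,Complement factor H,675747009,XP_008983383,140,6.99,2.26,6.06,7.89,3.97,1.85,3.72,0.00,,5.10,4.57,1.86,0.90,0.40,0.36,
2b,20,Serum amyloid A-4 protein,675698869,XP_009006030,15,5.43,3.40,5.05,1.82,0.00,5.55,2.79,0.00,,4.63,2.46,1.39,0.53,0.12,0.30,
2b,21,Plasminogen,675655078,XP_008993588,15,10.87,0.00,0.00,10.32,0.00,6.47,0.00,0.00,,3.62,5.60,0.00,1.55,0.24,0.00,
2b,22,Aminopeptidase N,675663052,XP_008996656,109,3.88,1.13,0.00,1.82,0.00,0.00,0.00,0.00,,1.67,0.61,0.00,0.36,0.11,0.00,
2b,23,Immunoglobulin heavy chain,20502592,AAM22540,11,3.10,0.00,0.00,3.03,0.00,0.00,0.00,0.00,,1.03,1.01,0.00,0.98,0.21,0.00,
2b,24,Complement component C9,675646263,XP_002745089,65,3.10,0.00,0.00,2.43,0.00,0.00,0.00,0.00,,1.03,0.81,0.00,0.78,0.21,0.00,
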