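id,age,sex,tp53_deletion,protein_status,fold_expression,karyotype
M1,60,F,+,-,3.787,Complex
M2,27,F,+,-,7.653,Complex
M3,87,M,-,+,1.187,Complex
M4,59,F,-,+,3.927,Complex
M5,59,F,-,-,2.703,Complex
M6,61,M,-,-,4.639,Complex
M7,78,M,-,+,1.636,Complex
M8,64,M,-,-,0.398,Complex
M9,29,F,-,+,N.D,Complex
M10,29,F,-,+,1.435,Complex
M11,68,M,-,+,2.002,Complex
M12,61,F,-,+,3.228,Normal
M13,63,F,+,+,0.873,Complex
M14,55,F,-,N.D,2.323,Normal
M15,67,F,-,-,5.158,Complex
M16,67,F,-,-,15.633,Complex
M17,73,F,-,N.D,1.150,Complex
M18,27,M,-,+,2.513,Complex
M19,48,F,-,-,7.756,Complex
M20,66,F,-,N.D,3.045,Complex
M21,72,F,+,-,6.974,Complex
M22,45,F,-,+,5.737,Normal
M23,46,M,-,-,3.857,Complex
M24,59,M,-,-,10.461,Complex
M25,47,F,-,N.D,6.246,Complex
M26,27,F,+,-,5.227,Complex
M27,37,F,-,N.D,18.311,Complex
M28,56,F,+,-,9.260,Complex
M29,84,F,-,N.D,3.068,Complex
M30,61,M,-,+,3.328,Normal
M31,74,M,+,N.D,5.849,Complex
M32,61,M,-,+,2.354,Complex
M33,74,M,-,N.D,16.343,Complex
M34,74,M,-,N.D,3.031,Complex
M35,65,F,-,N.D,0.808,Normal
M36,65,F,-,+,0.959,Normal
M37,81,F,+,+,1.490,Complex
M38,75,F,-,+,3.671,Normal
M39,85,M,-,N.D,3.026,Normal
M40,71,M,-,+,3.021,Complex
M41,77,M,-,+,0.962,Complex
M42,62,M,-,-,7.275,Complex
M43,49,F,-,-,9.842,Complex
M44,51,F,-,+,3.676,Normal
M45,51,F,-,N.D,1.096,Normal
M46,58,M,+,+,2.825,Complex
M47,68,F,+,+,1.113,Complex
M48,59,M,-,N.D,8.061,Complex
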