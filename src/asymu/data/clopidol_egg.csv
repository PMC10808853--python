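block,Breeding,Operator,HPLC,Extract storage,0.2,0.5,1,2,4,6
01,Conventional,Routine,Batch 1 (Old),With,0.22,0.49,0.82,2.11,4.66,6.45
02,Conventional,Routine,Batch 2 (New),With,0.24,0.47,1.20,2.18,4.98,7.32
03,Conventional,Occasional,Batch 1 (Old),Without,0.28,0.57,1.07,2.62,3.67,6.78
04,Conventional,Occasional,Batch 2 (New),Without,0.22,0.55,1.06,1.74,3.72,5.56
05,Organic,Routine,Batch 1 (Old),Without,0.16,0.42,0.91,2.00,4.42,5.53
06,Organic,Routine,Batch 2 (New),Without,0.23,0.55,1.24,2.11,4.52,5.91
07,Organic,Occasional,Batch 1 (Old),With,0.42,0.73,1.19,2.26,4.44,4.99
08,Organic,Occasional,Batch 2 (New),With,0.32,0.56,1.08,1.82,3.25,5.01
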