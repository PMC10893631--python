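model,se,sp,ya,e,acc,dr,f1,mcc
Ph4-1,0.753,0.955,0.344,11.240,0.948,0.789,0.4721,0.4875
Ph4-2,0.753,0.958,0.362,11.832,0.952,0.786,0.4889,0.5017
Ph4-3,0.753,0.959,0.369,12.070,0.953,0.785,0.4955,0.5073
Ph4-4,0.753,0.961,0.377,12.318,0.954,0.784,0.5023,0.5131
Ph4-5,0.740,0.962,0.383,12.523,0.956,0.769,0.5047,0.5128
Ph4-6,0.726,0.964,0.387,12.650,0.956,0.753,0.5048,0.5106
Ph4-7,0.753,0.942,0.289,9.465,0.936,0.800,0.4183,0.4422
Ph4-8,0.753,0.935,0.267,8.730,0.929,0.806,0.3943,0.4220
Ph4-9,0.767,0.919,0.230,7.535,0.915,0.835,0.3544,0.3908
Ph4-10,0.767,0.936,0.273,8.932,0.930,0.820,0.4029,0.4318
Ph4-11,0.767,0.924,0.242,7.927,0.920,0.830,0.3684,0.4027
Ph4-12,0.808,0.905,0.211,6.915,0.902,0.893,0.3352,0.3822
Ph4-13,0.849,0.773,0.105,3.448,0.775,1.099,0.1876,0.2486
Ph4-14,0.849,0.824,0.132,4.323,0.825,1.031,0.2288,0.2918
Ph4-15,0.849,0.861,0.161,5.279,0.860,0.987,0.2713,0.3328
Ph4-16,0.479,0.952,0.240,7.839,0.938,0.504,0.3196,0.3100
Ph4-17,0.425,0.986,0.484,15.838,0.969,0.431,0.4526,0.4375
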