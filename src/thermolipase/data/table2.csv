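enzyme,temperature_c,alpha1,alpha1_se,k1,k1_se,k2,k2_se
SP14,70,0.647,0.021,2.24e-2,0.37e-2,1.82e-4,0.27e-4
SP14,80,0.759,0.007,1.54e-1,0.12e-1,1.83e-3,0.10e-3
SP14,90,0.690,0.026,2.30e-1,0.65e-1,2.81e-3,0.45e-3
SP14,100,0.328,0.027,3.59e-1,0.40e-1,7.84e-3,2.32e-3
SP22,70,0.589,0.060,5.06e-3,1.14e-3,9.42e-5,1.49e-5
SP22,80,0.879,0.035,3.45e-1,0.36e-1,4.85e-4,0.31e-4
SP22,90,0.687,0.026,5.33e-1,0.36e-1,4.96e-3,0.56e-3
SP22,100,0.432,0.006,8.81e-1,0.37e-1,1.45e-2,0.07e-2
SP29,70,0.662,0.055,1.43e-2,0.44e-2,8.26e-4,1.13e-4
SP29,80,0.673,0.040,1.57e-1,0.54e-1,1.76e-3,0.64e-3
SP29,90,0.566,0.031,2.04e-1,0.45e-1,3.05e-3,0.66e-3
SP29,100,0.500,0.011,6.47e-1,0.54e-1,7.43e-3,0.68e-3
SP73,70,0.740,0.021,3.21e-2,0.74e-2,7.06e-4,0.62e-4
SP73,80,0.726,0.028,1.66e-1,0.47e-1,3.21e-3,0.35e-3
SP73,90,0.562,0.059,1.45e-1,0.52e-1,3.27e-3,1.22e-3
SP73,100,0.399,0.034,6.27e-1,1.27e-1,9.42e-3,2.68e-3
SP75,70,0.267,0.030,2.54e-1,0.30e-1,3.59e-4,1.33e-4
SP75,80,0.459,0.044,2.07e-1,0.45e-1,9.20e-3,1.48e-3
SP75,90,0.335,0.005,3.96e-1,0.13e-1,9.09e-3,0.34e-3
SP75,100,0.302,0.009,1.42e0,0.08e0,6.19e-2,0.32e-2
SP76,70,0.493,0.055,5.36e-2,1.21e-2,3.77e-3,0.82e-3
SP76,80,0.377,0.008,2.02e-1,0.08e-1,4.21e-3,0.25e-3
SP76,90,0.270,0.048,2.90e-1,0.68e-1,2.06e-2,0.35e-2
SP76,100,0.176,0.054,3.68e-1,0.58e-1,3.23e-2,1.50e-2
SP79,70,0.639,0.013,7.23e-2,1.63e-2,1.39e-3,0.16e-3
SP79,80,0.384,0.047,8.01e-2,1.17e-2,3.04e-3,0.64e-3
SP79,90,0.330,0.022,1.48e-1,0.10e-1,7.81e-3,1.43e-3
SP79,100,0.313,0.013,5.05e-1,0.27e-1,1.77e-2,0.27e-2
SP83,70,0.627,0.026,4.12e-2,0.53e-2,3.30e-3,0.24e-3
SP83,80,0.458,0.029,1.64e-1,0.23e-1,4.88e-3,0.80e-3
SP83,90,0.254,0.053,2.77e-1,0.60e-1,1.12e-2,0.49e-2
SP83,100,0.491,0.052,1.19e1,0.47e1,9.49e-2,0.88e-2
SP93,70,0.662,0.006,2.57e-2,0.12e-2,5.63e-4,0.13e-4
SP93,80,0.380,0.011,7.22e-2,0.23e-2,1.09e-2,0.03e-2
SP93,90,0.366,0.083,2.02e-1,0.05e-1,2.62e-2,0.61e-2
SP93,100,0.271,0.065,1.87e0,0.46e0,7.25e-2,1.50e-2
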