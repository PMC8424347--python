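# Published leave-one-out prediction results for a 27-sample human aortic
# media cohort: per-sample predictive accuracy R^2 and material parameters
# (c, k1 in kPa; k2 dimensionless) for the standard-fitting baseline and the
# hybrid model.  table = "roi" restricts to the six samples inside the
# latent-space region of interest; table = "full" runs all 27 samples with
# the held-out sample reused as test sample.  r2_censored = 1 marks entries
# reported only as "< -1".
table,sample,method,r2,r2_censored,c,k1,k2
roi,3,standard,0.206,0,16.42,12.08,2.36
roi,5,standard,0.869,0,16.58,12.08,3.04
roi,7,standard,0.922,0,19.65,12.33,2.36
roi,15,standard,0.483,0,16.42,12.97,2.36
roi,24,standard,0.883,0,19.65,12.08,2.85
roi,26,standard,0.140,0,19.65,12.97,2.36
roi,3,hybrid,0.963,0,6.05,34.08,29.32
roi,5,hybrid,0.992,0,1.56,23.99,21.74
roi,7,hybrid,0.955,0,3.49,26.75,9.24
roi,15,hybrid,0.974,0,0.11,10.66,17.02
roi,24,hybrid,0.968,0,1.92,21.08,9.84
roi,26,hybrid,0.960,0,0.00,4.56,16.72
full,1,standard,0.994,0,16.42,12.97,2.36
full,2,standard,0.633,0,16.42,12.08,3.04
full,3,standard,0.206,0,16.42,12.08,2.36
full,4,standard,,1,19.65,12.08,3.04
full,5,standard,0.869,0,16.58,12.08,3.04
full,6,standard,,1,19.65,12.08,3.04
full,7,standard,0.922,0,19.65,12.33,2.36
full,8,standard,,1,19.65,12.97,3.04
full,9,standard,0.798,0,19.65,12.08,2.36
full,10,standard,0.997,0,16.42,12.97,3.04
full,11,standard,-0.345,0,16.42,12.97,2.36
full,12,standard,0.996,0,16.42,12.97,2.36
full,13,standard,,1,19.65,12.08,3.04
full,14,standard,,1,19.65,12.97,3.04
full,15,standard,0.483,0,16.42,12.97,2.36
full,16,standard,-0.039,0,16.42,12.97,2.36
full,17,standard,0.631,0,16.42,12.97,2.36
full,18,standard,1.000,0,16.42,12.97,2.36
full,19,standard,-0.129,0,16.42,12.97,2.36
full,20,standard,,1,19.65,12.97,3.04
full,21,standard,-0.202,0,16.42,12.08,3.04
full,22,standard,-0.094,0,16.42,12.08,2.36
full,23,standard,0.603,0,19.65,12.08,3.04
full,24,standard,0.883,0,19.65,12.08,2.85
full,25,standard,,1,19.65,12.08,3.04
full,26,standard,0.140,0,19.65,12.97,2.36
full,27,standard,,1,19.65,12.08,3.04
full,1,hybrid,0.929,0,28.25,9.10,0.00
full,2,hybrid,0.986,0,38.35,33.31,0.00
full,3,hybrid,0.995,0,45.05,13.75,16.73
full,4,hybrid,0.901,0,23.81,0.02,19.62
full,5,hybrid,0.998,0,22.64,17.45,2.42
full,6,hybrid,0.995,0,6.35,12.56,0.41
full,7,hybrid,0.935,0,17.19,22.04,1.28
full,8,hybrid,0.998,0,14.95,10.66,0.00
full,9,hybrid,0.897,0,17.03,9.75,5.47
full,10,hybrid,0.954,0,36.55,66.73,0.00
full,11,hybrid,-0.087,0,36.87,58.85,0.00
full,12,hybrid,0.731,0,29.44,28.04,0.00
full,13,hybrid,0.996,0,12.05,12.34,0.22
full,14,hybrid,0.999,0,13.96,3.33,0.00
full,15,hybrid,0.965,0,12.16,16.93,0.00
full,16,hybrid,-0.029,0,67.77,50.37,24.01
full,17,hybrid,0.734,0,30.40,49.28,0.00
full,18,hybrid,0.991,0,15.99,13.58,1.13
full,19,hybrid,0.938,0,114.86,322.75,10.40
full,20,hybrid,0.986,0,15.76,9.20,0.00
full,21,hybrid,0.972,0,32.67,61.95,3.77
full,22,hybrid,0.447,0,38.31,63.03,0.00
full,23,hybrid,0.964,0,2.54,24.20,0.00
full,24,hybrid,0.964,0,13.80,17.05,0.00
full,25,hybrid,0.862,0,27.15,19.75,0.00
full,26,hybrid,0.951,0,7.16,15.31,0.00
full,27,hybrid,0.984,0,22.42,7.61,0.64
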