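species,pair,short_arm,long_arm,total_se,ar_se,reported_ar,reported_type
O. minor,1,2.43,2.54,0.17,0.15,1.05,M
O. minor,2,2.28,2.49,0.11,0.12,1.09,M
O. minor,3,2.22,2.51,0.05,0.08,1.13,M
O. minor,4,2.30,2.43,0.13,0.12,1.06,M
O. minor,5,2.36,2.36,0.06,0.13,1.00,M
O. minor,6,2.28,2.36,0.01,0.05,1.04,M
O. minor,7,2.21,2.38,0.05,0.01,1.08,M
O. minor,8,2.19,2.40,0.11,0.14,1.10,M
O. minor,9,2.16,2.38,0.05,0.02,1.12,M
O. minor,10,2.13,2.15,0.12,0.10,1.01,M
O. minor,11,2.12,2.16,0.03,0.07,1.01,M
O. minor,12,2.03,2.17,0.14,0.13,1.07,M
O. minor,13,1.92,2.04,0.07,0.09,1.06,M
O. minor,14,1.91,1.98,0.15,0.14,1.04,M
O. minor,15,1.88,1.98,0.09,0.10,1.05,M
O. minor,16,1.36,1.90,0.11,0.13,1.40,M
O. minor,17,1.42,1.54,0.12,0.18,1.08,M
O. minor,18,1.28,1.29,0.05,0.10,1.01,M
O. minor,19,1.24,1.27,0.13,0.11,1.02,M
O. minor,20,0.93,1.19,0.08,0.10,1.28,M
O. minor,21,0.95,0.96,0.10,0.05,1.01,M
O. minor,22,1.85,3.14,0.05,0.05,1.70,SM
O. minor,23,1.01,2.87,0.10,0.11,2.84,SM
O. minor,24,0.97,2.90,0.09,0.02,2.99,SM
O. minor,25,1.03,3.52,0.13,0.13,3.42,ST
O. minor,26,0.83,3.17,0.01,0.04,3.82,ST
O. minor,27,-,3.02,0.01,,inf,T
O. minor,28,-,3.02,0.05,,inf,T
O. minor,29,-,1.77,0.01,,inf,T
O. minor,30,-,1.15,0.07,,inf,T
A. fangsiao,1,3.33,3.55,0.18,0.08,1.06,M
A. fangsiao,2,2.99,3.46,0.70,0.12,1.16,M
A. fangsiao,3,3.04,3.15,0.47,0.02,1.03,M
A. fangsiao,4,2.86,2.87,0.19,0.11,1.00,M
A. fangsiao,5,2.53,2.96,0.07,0.17,1.17,M
A. fangsiao,6,1.94,2.12,0.20,0.04,1.09,M
A. fangsiao,7,1.97,2.09,0.10,0.01,1.06,M
A. fangsiao,8,1.66,2.18,0.21,0.01,1.31,M
A. fangsiao,9,1.82,1.91,0.22,0.02,1.05,M
A. fangsiao,10,1.63,2.07,0.06,0.01,1.27,M
A. fangsiao,11,1.55,1.95,0.31,0.08,1.26,M
A. fangsiao,12,1.68,1.76,0.11,0.04,1.05,M
A. fangsiao,13,1.42,1.79,0.27,0.21,1.26,M
A. fangsiao,14,1.56,1.64,0.04,0.13,1.05,M
A. fangsiao,15,1.47,1.69,0.32,0.32,1.15,M
A. fangsiao,16,1.32,1.69,0.05,0.13,1.28,M
A. fangsiao,17,2.48,4.39,0.13,0.28,1.77,SM
A. fangsiao,18,2.37,4.30,0.07,0.14,1.81,SM
A. fangsiao,19,1.92,3.59,0.24,0.29,1.87,SM
A. fangsiao,20,2.02,3.46,0.09,0.12,1.71,SM
A. fangsiao,21,1.53,2.66,0.26,0.20,1.74,SM
A. fangsiao,22,1.12,2.50,0.18,0.11,2.23,SM
A. fangsiao,23,1.05,2.53,0.19,0.01,2.41,SM
A. fangsiao,24,0.74,2.13,0.03,0.30,2.88,SM
A. fangsiao,25,0.32,2.86,0.66,0.13,8.90,T
A. fangsiao,26,0.22,2.88,0.40,0.32,12.90,T
A. fangsiao,27,-,2.71,0.42,,inf,T
A. fangsiao,28,-,2.54,0.16,,inf,T
A. fangsiao,29,-,1.90,0.03,,inf,T
A. fangsiao,30,-,0.90,0.03,,inf,T
C. chinensis,1,4.13,4.15,0.05,0.10,1.00,M
C. chinensis,2,3.64,3.75,0.11,0.02,1.03,M
C. chinensis,3,3.60,3.78,0.07,0.02,1.05,M
C. chinensis,4,3.15,3.44,0.12,0.03,1.09,M
C. chinensis,5,3.33,3.35,0.09,0.11,1.01,M
C. chinensis,6,3.14,3.18,0.15,0.04,1.01,M
C. chinensis,7,2.97,3.19,0.04,0.01,1.07,M
C. chinensis,8,2.83,2.98,0.20,0.07,1.05,M
C. chinensis,9,2.42,2.48,0.17,0.11,1.02,M
C. chinensis,10,2.29,2.44,0.06,0.06,1.07,M
C. chinensis,11,2.28,2.45,0.15,0.08,1.07,M
C. chinensis,12,2.24,2.27,0.11,0.03,1.01,M
C. chinensis,13,1.99,2.31,0.07,0.01,1.16,M
C. chinensis,14,1.96,2.27,0.10,0.03,1.16,M
C. chinensis,15,2.03,2.10,0.16,0.12,1.03,M
C. chinensis,16,1.75,1.99,0.05,0.07,1.14,M
C. chinensis,17,1.58,1.96,0.03,0.08,1.24,M
C. chinensis,18,1.55,1.55,0.02,0.04,1.00,M
C. chinensis,19,1.02,1.23,0.04,0.06,1.21,M
C. chinensis,20,1.52,4.53,0.08,0.06,2.98,SM
C. chinensis,21,1.23,2.46,0.16,0.20,2.00,SM
C. chinensis,22,1.02,2.42,0.08,0.08,2.37,SM
C. chinensis,23,1.15,4.63,0.09,0.04,4.03,ST
C. chinensis,24,1.10,3.89,0.03,0.01,3.54,ST
C. chinensis,25,0.55,3.35,0.16,0.13,6.09,ST
C. chinensis,26,0.73,3.15,0.10,0.13,4.32,ST
C. chinensis,27,-,2.71,0.02,,inf,T
C. chinensis,28,-,2.74,0.06,,inf,T
C. chinensis,29,-,1.69,0.07,,inf,T
C. chinensis,30,-,1.56,0.10,,inf,T
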