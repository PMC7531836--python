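# Synthetic stand-in for the digitized lysis-vs-MAC-density dose-response
# (sheep erythrocytes carrying human C5b-7, titrated C8/C9).  Generated
# from the Hill model with gamma=1.60, MAC50=1.15 MAC/cell and 2.5%
# full-scale Gaussian noise, seed 20201002.  NOT experimental data.
mac_per_cell,percent_hemolysis
0.1,0.898086
0.125906,4.96816
0.158522,4.81999
0.199588,6.14732
0.251292,7.28114
0.316391,9.66128
0.398354,13.368
0.501549,23.2408
0.631478,31.7703
0.795066,36.1813
1.00103,44.4833
1.26035,56.8345
1.58686,64.2793
1.99794,69.6587
2.51552,76.3663
3.16717,86.6732
3.98765,84.9971
5.02067,89.9125
6.3213,91.8161
7.95886,96.1899
10.0206,95.0992
12.6165,96.6734
15.8849,97.9
20,99.8787
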