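wavelength_nm,xbar10,ybar10,zbar10
380,0.000160,0.000017,0.000705
390,0.002362,0.000253,0.010482
400,0.019110,0.002004,0.086011
410,0.084736,0.008756,0.389366
420,0.204492,0.021391,0.972542
430,0.314679,0.038676,1.553480
440,0.383734,0.062077,1.967280
450,0.370702,0.089456,1.994800
460,0.302273,0.128201,1.745370
470,0.195618,0.185190,1.317560
480,0.080507,0.253589,0.772125
490,0.016172,0.339133,0.415254
500,0.003816,0.460777,0.218502
510,0.037465,0.606741,0.112044
520,0.117749,0.761757,0.060709
530,0.236491,0.875211,0.030451
540,0.376772,0.961988,0.013676
550,0.529826,0.991761,0.003988
560,0.705224,0.997340,0.000000
570,0.878655,0.955552,0.000000
580,1.014160,0.868934,0.000000
590,1.118520,0.777405,0.000000
600,1.123990,0.658341,0.000000
610,1.030480,0.527963,0.000000
620,0.856297,0.398057,0.000000
630,0.647467,0.283493,0.000000
640,0.431567,0.179828,0.000000
650,0.268329,0.107633,0.000000
660,0.152568,0.060281,0.000000
670,0.081260,0.031800,0.000000
680,0.040851,0.015905,0.000000
690,0.019941,0.007749,0.000000
700,0.009577,0.003718,0.000000
710,0.004553,0.001768,0.000000
720,0.002089,0.000846,0.000000
730,0.001047,0.000426,0.000000
740,0.000508,0.000207,0.000000
750,0.000251,0.000102,0.000000
760,0.000126,0.000051,0.000000
770,0.000065,0.000026,0.000000
780,0.000033,0.000014,0.000000
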