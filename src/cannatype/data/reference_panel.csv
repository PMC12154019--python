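sample_id,pct_thc,pct_cbd,log_ratio,chemotype,thcas,cbdas
TK1,0.744,2.823,-0.579,II,T,D
TK2,0.928,0.062,1.175,I,T,d
TK3,1.657,0.155,1.029,I,T,d
TK4,2.084,0.144,1.159,I,T,d
TK6,0.831,0.03,1.437,I,T,d
TK7,1.8,0.138,1.114,I,T,d
TK8,0.953,0.077,1.092,I,T,d
TK9,1.968,0.077,1.405,I,T,d
TK11,1.045,0.141,0.869,I,T,d
TK12,0.503,0.034,1.172,I,T,d
TK13,1.547,0.12,1.111,I,T,d
TK14,1.339,3.053,-0.358,II,T,D
TK17,0.614,0.035,1.249,I,T,d
TK18,1.472,0.14,1.023,I,T,d
TK19,1.212,0.024,1.709,I,T,d
TK20,2.174,0.12,1.26,I,T,d
TK25,2.052,0.116,1.249,I,T,d
TK28,1.21,0.097,1.095,I,T,d
TK29,1.656,0.08,1.313,I,T,d
TK33,1.144,0.03,1.574,I,T,d
TK34,1.317,0.043,1.489,I,T,d
TK36,2.183,0.053,1.615,I,T,d
TK37,1.688,0.106,1.203,I,T,d
TK40,0.85,0.048,1.249,I,T,d
TK41,1.195,0.023,1.722,I,T,d
TK42,1.015,0.014,1.855,I,T,d
TK43,1.72,0.048,1.55,I,T,d
TK44,1.885,0.044,1.635,I,T,d
TK45,0.538,1.341,-0.397,II,T,D
TK46,1.884,0.062,1.482,I,T,d
TK47,0.445,0.008,1.723,I,T,d
TK48,0.374,0.011,1.547,I,T,d
TK51,1.907,0.051,1.572,I,T,d
TK52,0.488,0.002,2.301,I,T,d
TK55,1.638,0.037,1.65,I,T,d
TK56,2.475,0.056,1.649,I,T,d
TK57,1.518,0.034,1.646,I,T,d
TK58,0.782,0.018,1.632,I,T,d
TK59,0.913,0.035,1.415,I,T,d
TK60,0.065,2.382,-1.561,III,t,D
TK61,0.072,2.96,-1.613,III,t,D
TK62,0.784,0.039,1.306,I,T,d
TK63,0.852,0.01,1.921,I,T,d
TK64,0.838,0.041,1.308,I,T,d
TK65,1.394,0.001,3.144,I,T,d
TK69,0.892,0.001,2.95,I,T,d
TK70,0.48,0.001,2.682,I,T,d
TK73,1.251,0.029,1.641,I,T,d
TK74,0.468,0.001,2.67,I,T,d
TK76,1.66,0.038,1.637,I,T,d
TK77,2.036,0.052,1.591,I,T,d
TK78,0.931,0.001,2.969,I,T,d
TK86,0.817,0.042,1.289,I,T,d
TK88,0.209,0.001,2.32,I,T,d
TK89,0.611,0.001,2.786,I,T,d
TK90,0.977,0.033,1.468,I,T,d
TK92,2.86,0.069,1.616,I,T,d
TK94,0.712,0.001,2.853,I,T,d
TK96,0.874,0.032,1.441,I,T,d
TK97,0.542,1.309,-0.383,II,T,D
TK98,0.536,1.332,-0.396,II,T,D
TK101,0.306,0.015,1.322,I,T,d
TK102,0.906,0.056,1.212,I,T,d
TK103,0.071,0.861,-1.085,III,t,D
TK105,0.847,0.023,1.564,I,T,d
TK106,0.878,0.017,1.717,I,T,d
TK108,0.499,0.002,2.311,I,T,d
TK111,2.144,0.132,1.21,I,T,d
TK115,0.881,0.025,1.554,I,T,d
TK117,0.107,0.018,0.762,I,T,d
TK118,0.92,0.015,1.795,I,T,d
TK121,1.107,0.016,1.828,I,T,d
TK122,1.178,0.055,1.33,I,T,d
TK126,1.517,3.371,-0.347,II,T,D
TK127,1.695,3.039,-0.254,II,T,D
TK132,3.678,4.598,-0.097,II,T,D
TK133,2.244,0.068,1.518,I,T,d
TK134,3.122,0.1,1.494,I,T,d
TK136,1.179,0.043,1.435,I,T,d
TK137,2.028,0.078,1.413,I,T,d
TK138,2.796,0.143,1.292,I,T,d
TK139,0.141,2.776,-1.294,III,t,D
TK140,2.676,6.495,-0.385,II,T,D
TK61F1-C0-2G,1.381,3.388,-0.39,II,T,D
TK61F1-C0-5P,0.507,1.658,-0.515,II,T,D
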