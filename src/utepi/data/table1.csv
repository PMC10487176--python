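horse,limb,slope,slope_se,r,excluded
horse1,LF,-0.012,9.13e-5,-0.16,0
horse1,RF,,,,1
horse1,LH,-0.010,7.13e-5,-0.23,0
horse1,RH,-0.011,7.20e-5,-0.24,0
horse2,LF,-0.0098,6.87e-5,-0.18,0
horse2,RF,-0.0094,6.16e-5,-0.29,0
horse2,LH,-0.0094,5.83e-5,-0.29,0
horse2,RH,-0.0094,5.53e-5,-0.35,0
horse3,LF,-0.0090,6.87e-5,-0.30,0
horse3,RF,-0.0090,6.27e-5,-0.34,0
horse3,LH,-0.0094,5.41e-5,-0.33,0
horse3,RH,-0.0087,5.49e-5,-0.43,0
horse4,LF,-0.0086,5.89e-5,-0.36,0
horse4,RF,-0.0082,7.12e-5,-0.29,0
horse4,LH,-0.0084,5.70e-5,-0.32,0
horse4,RH,-0.0077,6.39e-5,-0.30,0
horse5,LF,-0.0074,8.36e-5,-0.22,0
horse5,RF,-0.0072,8.65e-5,-0.24,0
horse5,LH,-0.0074,7.14e-5,-0.28,0
horse5,RH,-0.0076,6.66e-5,-0.30,0
horse6,LF,-0.0069,7.25e-5,-0.31,0
horse6,RF,-0.0057,8.80e-5,-0.14,0
horse6,LH,-0.0048,7.27e-5,-0.32,0
horse6,RH,-0.0048,7.39e-5,-0.40,0
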