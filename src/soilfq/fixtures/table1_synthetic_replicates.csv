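treatment,replicate,ear_number,ear_grain_number,thousand_grain_weight,grain_yield,synthetic_replicate
FNT,1,550.45,19.59,25.38,2919.57,True
FNT,2,558.0,20.0,25.8,2985.0,True
FNT,3,565.55,20.41,26.22,3050.43,True
FST,1,603.96,21.78,26.43,3378.46,True
FST,2,608.0,22.0,26.8,3483.0,True
FST,3,612.04,22.22,27.17,3587.54,True
FPT,1,577.34,19.65,26.69,3002.0,True
FPT,2,584.0,20.0,27.5,3028.0,True
FPT,3,590.66,20.35,28.31,3054.0,True
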