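confounder,group_a,group_b,correct_a,correct_b,incorrect_a,incorrect_b,printed_chi2
clothing,scrubs,casual,3638,2459,557,470,10.71
sex,male,female,4211,1886,613,414,35.35
height,above_median,below_median,3925,2121,550,472,46.51
scenery,hospital,regular,2934,3163,282,745,151.51
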