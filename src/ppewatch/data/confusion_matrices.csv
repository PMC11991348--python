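item,split,a,b,c,d
mask,training,2620,148,74,2832
mask,live,476,70,118,1120
gloves,training,5577,264,468,4527
gloves,live,1161,168,186,1765
gown,training,3725,51,136,3117
gown,live,376,29,239,1561
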