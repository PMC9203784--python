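direction,goal,score
out,1,3
out,2,0
out,4,3
out,5,0
out,6,0
out,7,0
out,8,3
out,9,1
out,10,2
out,11,1
out,12,2
out,13,0
out,14,0
out,15,0
out,16,1
out,18,0
in,1,1
in,2,2
in,4,2
in,5,2
in,6,3
in,7,2
in,8,2
in,9,2
in,10,2
in,11,3
in,12,2
in,13,1
in,14,1
in,15,1
in,16,2
in,18,1
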