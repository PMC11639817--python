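# 31P MRS of human brain at 7 T: beta-ATP triplet and alpha-ATP doublet
Index,BATP,BATP2,BATP3,AATP,AATP2
Initial Values,,,,,
amplitude,1.41,BATP/2,BATP/2,1.545,AATP
chemicalshift,-16.15,BATP-15Hz,BATP+15Hz,-7.49,AATP-16Hz
linewidth,58.12,BATP,BATP,32.28,AATP
phase,0,BATP,BATP,BATP,BATP
g,0,0,0,0,0
Bounds,,,,,
amplitude,"(0,","(0,","(0,","(0,","(0,"
chemicalshift,"(-16.30, -16.00)","(-16.30, -16.00)","(-16.30, -16.00)","(-7.72, -7.42)","(-7.72, -7.42)"
linewidth,"(54.335, 61.911)","(54.335, 61.911)","(54.335, 61.911)","(31.226, 33.327)","(31.226, 33.327)"
phase,"(-180, 180)","(-180, 180)","(-180, 180)","(-180, 180)","(-180, 180)"
g,"(0, 1)","(0, 1)","(0, 1)","(0, 1)","(0, 1)"
# Use the same phase for all peaks
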