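name,in_ring,tb_k,tc_k,vc_k
-CH3,False,23.58,0.0141,65
-CH2-,False,22.288,0.0189,56
>CH-,False,21.74,0.0164,41
>C<,False,18.25,0.0067,27
=CH2,False,18.18,0.0113,56
=CH-,False,24.96,0.0129,46
=C<,False,24.14,0.0117,38
-O-,False,22.42,0.0168,18
>C=O,False,94.97,0.0284,55
-OH,False,92.88,0.0741,28
-CH2-,True,27.15,0.0100,48
>CH-,True,21.78,0.0122,38
>C<,True,21.32,0.0042,27
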