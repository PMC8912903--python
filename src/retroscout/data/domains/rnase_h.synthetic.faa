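>rnase_h|tf_like.1 lineage=tf_like
VLDFAAWYPLTRQVRPVVWFEAITFTCKGWPHISSVRHVFKNYPQDQIWQRRIMKYWTINQMAHVLKGDMCPYSNFGWKHNRIDYNFVRTCCVHCQHIHCDKTHAVEDDL
>rnase_h|tf_like.2 lineage=tf_like
VLDFAAWYPLTRYLRPVFWREAATFTCKGWPHISSVRHVFKNYPQDQIWQRRIMTEVTINQMAHVLKGDMCPYSQFWWKHNRTDYNFVRTCCVHCEHIHYDKTHATEDDL
>rnase_h|ty3_like.1 lineage=ty3_like
DGDFAAWAPATRQVRKHNIHEWYTFGCLMWPHISSGPHNFKFYPQDQIWQRRIMQYWIWNKMAQVLHPMMSSYSWFGGDINRIVYWFLYTCCVHLCPNHCSKTHDYEDDT
>rnase_h|ty3_like.2 lineage=ty3_like
DGDFAAWADATRQVRKMNIHEWYTFGCLMWPHESSGPHNFKFEPQDKIWQRRDMQYWIWNKMALVLHPVMSSASWFGGDISRIVYWFLYTTCVHLCPNHHSKHHDYEDDT
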