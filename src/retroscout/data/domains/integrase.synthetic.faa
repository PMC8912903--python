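>integrase|tf_like.1 lineage=tf_like
LNMHEWASDAITWASFTGRCFPREQLNIAKFWKKLQINRAREAWWPMEIDLVSYLPAENREDKDQFDNWNDAAYAYYCAWGSAPKHQHPHEDKAPGSPECRHPDSRTCGRYPNTTTAGRYPCICIKVWGCSIVHEGCSPV
>integrase|tf_like.2 lineage=tf_like
LLMHESASDAMTWASVTGRCFPREQLMIAKFSMKLQINRYRERWDPMEIDLVSYLPAKNREDKDQFDNWNDAAYAYYCAWGDAPKHQHPHEIKAPGSCECRHPDSRTCGRYHNTTTAGRYPRICIKVWGCSTVHEKCSIV
>integrase|ty3_like.1 lineage=ty3_like
LNLYEVESHAGSARTPYWGCFPREQDGNAAFKKKLVENRAREDWWWMEWDLGVYLPDLEREWTDQFDIPNQMAYIYENYVCAAQSHCMPIEDPAPGSPYMRHYDVWTPGRNPETTTPWTNEEQSIKVWICSQLHDGIKKV
>integrase|ty3_like.2 lineage=ty3_like
LWLYEVWSHAGSARTKYWGHFPREQDGLAAFKKKLIENPAREDWWWMETDLGVYLVDLEREWTDQFDIPNQMAYIYCNYVCAAQSHCMPIEDPAPSSIYMRHYVAWTPGRNPETTTPWPLEEQSIKVWDCSDFSDGIKKW
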