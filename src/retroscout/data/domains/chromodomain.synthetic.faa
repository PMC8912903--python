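>chromodomain|ty3_like.1 lineage=ty3_like
SYSWPFQDIWYQNQEVRGNEIDPGQWVWSENTTYCLCHRSPCPCIYSHEK
>chromodomain|ty3_like.2 lineage=ty3_like
SYSWPFQDIWYQNQEVRGNEIDEGQWVWSEATTYCLCHHSPCPCIKSREK
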