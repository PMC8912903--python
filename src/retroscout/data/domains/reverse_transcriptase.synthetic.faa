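>reverse_transcriptase|tf_like.1 lineage=tf_like
IPCKDADTEMCHIIAPQKSIMMFMPTKCHSHQNEVINHHVPRGFCDIHTPHTYYIGVGHEQGFRTTGCIEEEQTYTKTPDHQCDTKKNDNVTVTNLTIENKWQTTRWWHKNPGPPMYLTRWATSLFFGATEYVYMFPYDELYVQERQRHDKRQKPHCIPMNVFITGTAFHMARAPAYEHH
>reverse_transcriptase|tf_like.2 lineage=tf_like
IPCKDMLTEMCHIIAPQKSIMMFMPTKCHRHQNEVINHHQPRGFDDCHTPHTYYIGVGHEQGFRTTGCIETEQTYTKTPCHQQDTKCNDNVTVTNLTIENKWQTTRYWHKNPGPPMYLGRWATSLFFGATEYVYMFPYDELYVQERQRHDKRQKPHQIPMNVRIKITAFHMANAPASEHH
>reverse_transcriptase|ty3_like.1 lineage=ty3_like
HRCCDQDTYVCQIIHPQKGIHNFDFGKKHCSKNEGINTCVPCIFNEIKQHHTYAIGVRRENGFRTLGCIEYEITYTLTTDQQCDVKKADAVEMTNLTIRNCWTTSRNWHMNDGDPNYPRRWDTSLIFGYTEYEYMFPYDQRSSQKREVHDKRQCISPCPDNSFITGTAFTMACLAAYFHG
>reverse_transcriptase|ty3_like.2 lineage=ty3_like
HRCCDQDTYVCQNIHPQKGIHNFDFGYCHCSKNEGINYCVPCIFVEIEQHWTYAYGVRRENHFRTLGCCEVEITYMLTTDYQCWVKKADAVEMTNLTIRNFWTTSRNWHMNDGDPNYPPPWDTSLIFGYTEYEYMFPYDQRSSQKREVHDKRQCISPCPDNSFITGTAFTEACLVAYFHG
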