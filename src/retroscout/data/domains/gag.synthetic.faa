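>gag|tf_like.1 lineage=tf_like
PETALNMGVFANDWFALNYFIAGKSFLSQCTVEQQIVIEDLTFCCVAVRCFINTDMHGYNVCKSDIYCHWVPTEGNDTRPWGFKAAVADCPASIKYKRGRQRRNDREHSREEILGDVNML
>gag|tf_like.2 lineage=tf_like
PETALNMGVFANDWSALNYFIAGKSLLSQCTVEQQIEIEDLCFQQVANCCFINTDMHGYNVCYSDIYCHWVYTEGNDTRPWGFKLAVADCEASIKYKRRRCRINDREHSREEILGDVNML
>gag|ty3_like.1 lineage=ty3_like
PFQTQNMICFANVWFALNYDHAGASWDYQCGVEQQIVIEIIPFHPVTMLCFINTDMHGVNTCKSAIDCHSDFTMCNDKQPWGRHAVHADCDASIHYKNWRCFYNDRGYHRMEILGDVTCL
>gag|ty3_like.2 lineage=ty3_like
PFQTYNMICFANVWFALNYDHAGASWDYQCGYEQQEVIEIILFHPVTMLCFWNTDMHGWNTCKSAIDCHSDFTMCNDGQPWGRHAVHADCDASIHYKNWRCFYNDRGYYRMGILCDVTCL
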