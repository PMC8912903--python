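>protease|tf_like.1 lineage=tf_like
FANNNKHVRENGKGERPWHHPPGHFLFWAPQHFLNLSYWNSEYWNTFTRMILANVYCGIFGKHNYVPFIMCIFTNIEFFTWVIFIPIILA
>protease|tf_like.2 lineage=tf_like
FANNNKHCRENGKGERPWRHPPGHFLFWAPQHFRNLSYFNSNYWNTFTRKYLANVYCGIFGKHNYVPFIYCIFTDIEFFTWVIFIPIILA
>protease|ty3_like.1 lineage=ty3_like
FLNNNYHVRIFGKKEYPWFHFPGENLVCAPQHIILLMRWNSEYWNDFERMANCAVYMGIKSKGNEVPFDRCILCIYNVNTWVIFYEAALA
>protease|ty3_like.2 lineage=ty3_like
FLNNNYHVRIFGKKEYPWFWFPGENIVCAQQHIILLMRWNSEYWNDFERMACCAVYMGIKSIGFWVPFDRCIPCIYNVNTWVLFYEAALA
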