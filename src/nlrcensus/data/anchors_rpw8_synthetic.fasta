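>CONIFER_G1_A synthetic exemplar, conifer RNL group 1
SGTSWCYRSDDFRRQATANILNKTHLVYVGEEAMPWLTRPYPSRCTTLRQCDHAGSWELE
SGPRGDIDFILVKYYRDRRTDFTGVLTVFLPEDKKHKWTSWWAAKDLWKSFYICMWEQTT
NINSTSPFFC
>CONIFER_G1_B synthetic exemplar, conifer RNL group 1
SWTSWFSRSDIFRRQATANCLNKAHLVYVSEEAMVWLTRPYGSRCTHLRYCMHAYDWKLD
SGMRGDIDFILVKYFRCRRTDFTGHRTVFLREDKKHKPTSIWFAKDLWKDQYICKWEQTK
NINSTSPFFW
>ADR1 synthetic stand-in for the ADR1 RPW8 domain (BAF00531.1), RNL group 2
CIQAKIAVNWEGRCTTFRINHPAQDVKLYFCWNALWVMRWHMCGPRNKGRWICAGHHKCV
WYMENATHDFYSHQSTYNVYVLWYFENKYFYAQQRWKCSGDKNNLPIPKRFCAHRTPDQE
YWQQQYFATI
>CONIFER_G3_A synthetic exemplar, conifer RNL group 3
CGHHFWVIGLCTDDYQWHLTSMFSWNKTPPLGVMQTHKNWCKCTPPESNCDDNPLNYWKM
PGSQECFHPFQSMMPPHWFRPQRGTLMNNVEVFFIVQFESFSGAYTQEADELKACIGRPP
RGIIYQVKAI
>CONIFER_G3_B synthetic exemplar, conifer RNL group 3
CGHHFPVAGLCHDDYQWQLTSMFSWNKTPPLGVPQTVKCWSKCTPPESQADDSPLNYWHM
GLDQECFHAHQSMMPPHWRRPQRGTLMNNVDWRFIVQVEVFPGAYTQEADLLKIAKGFPP
RGIIYQFKAI
>NRG1 synthetic stand-in for the NRG1 RPW8 domain (AAY54606.1), RNL group 4
ATQQIHINGVRPCGIIYWKFTTIQHATCTVQGTSNYGYCTAFWYQSWVHTLTCCRAFQLI
HHWSRFTRYKPPFMYFFGVRYWMKSKPEKETVNCKTVTHYGMGRKVMAVSQLIECRVFPA
EMHRGPNLQW
>RPW8_1 synthetic stand-in for the RPW8.1 domain (ACJ05907.1), RNL group 4
ADQWIHINGVRGCGIIYWKFTTIQHATCTDQGTSNYGYQTAFWYQAWVHTLTCCTYAQLI
HHWVRFPRYKPLFWNEFGCRYLMASNLEKETVFCDKDTRYGMGMKVMIVSMLAECRWFPA
EMHCGPNLQY
>RPW8_2 synthetic stand-in for the RPW8.2 domain (ACJ72031.1), RNL group 4
ANQQIHINGVRWCGIIYWKFQHEVHATDDVQGTSNWPIGGWHWPQSAVHTLTCVRAFQLL
HFWSSFTRYKPPFVIFFLERYLMKSKPEKETVNCKTVWHYGMGRKVMHISQLIECRCFPC
GMHRGPNLQW
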