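BCR : 1 : input
CD40 : 1 : input
IL21/4 : 1 : input
SYK : 1 : 1 <- BCR
BTK : 1 : 1 <- BCR
PI3K : 1 : 1 <- SYK & BTK
RAF : 1 : 1 <- BTK
ERK : 1 : 1 <- RAF & !STAT
CBM : 1 : 1 <- BTK
TRAF6 : 1 : 1 <- CD40
IKKc : 2 : 2 <- TRAF6 ; 1 <- CBM
NFkB : 2 : 2 <- IKKc:2 ; 1 <- IKKc
STAT : 1 : 1 <- IL21/4
IRF4 : 2 : 2 <- NFkB:2 ; 1 <- NFkB
MYC : 1 : 1 <- PI3K & NFkB & !BLIMP1 & !BCL6
BCL6 : 1 : 1 <- IRF4 & !IRF4:2 & !(ERK | BLIMP1)
BLIMP1 : 1 : 1 <- IRF4:2 & STAT & !BCL6
AID : 1 : 1 <- NFkB & STAT & !BLIMP1
BCL2 : 1 : 1 <- (PI3K | NFkB) & !BCL6
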