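>IS200_IS605_ORFA|synthetic synthetic stand-in, IS200/IS605-family ORF A (tyrosine recombinase-like)
EGMEKLSVYGISPHDVVYPDEGEWDCPRIFGLFVETEGHEVMVRLKLKGSQVSDLTFCNY
VYDGAMNAKIIEDQHSEGDYHGTLGICYSIDTNLPNYVRPERVELYGQEPGRFDRQLFPV
TPAKGPQLSDEKKNVAGGLQYKKFKSCLEP
>IS607_ORFA|synthetic synthetic stand-in, IS607-family ORF A (serine recombinase-like)
RLVEWVSLGPEGLLLFNAGVGMIQRNLLFTTCQRTQGKIGRLNDFGGKFGKVEDAVDAGP
DPKITCYQANRHIRTTMLLARIYCMPVSQARNETFLPQSYESRRLGKSSQYNLEWLQPQA
LKNQFYGADISNRSVYASFAVLIAKRVAMIAILLLAELTEYKLSSKKLYKPSRDSMDNTI
FEIGLAMQSPALAFDNI
>IS200_IS605_ORFB|synthetic synthetic stand-in, IS200/IS605-family ORF B
IRTNYIDEIKMRLFYNFTAFVGVDPHERYVTDPRASQAPQRQYCTMLPDSYCGSEVYGAT
LEFASQTQILHLLQFATNPAKKTNSTKSIPNFIFLFAKRPRVAGVNVSDGLASILDRWVL
GCIKRALEMVGCGQIIVDCVRKRVYGQILPAKSGMTKFWSIVHDCAVESEKESNERSYIA
LDSMFTKTWKGTKEKGANGKRFTNVEVKVKVEELREPHRRSLKILTAITVLRLKNNVVRT
RDQLLMNLHIQLGAATGQKQGPKFHWWKVSYGGPGFAVNGSAFGCPQDTLAGFSFAYSAF
IFRWQTLPVVLTRGEDLLRWVIARHFKIETIINVHDGPLFLVFIGLPSAAMVLGEVHDNA
IPRQKEQLVTYTVRPSLKAAIPRAVRCVSLRSRIQNIGR
>IS607_ORFB|synthetic synthetic stand-in, IS607-family ORF B
RGTANHKYGKLYLMAGDQYASTIKTAAFLSNCKEPRWQLIYSFQLSHGDPYKSRIEGLFV
AAVGWVVPTVNDSLESAFVNAARLKASYEKDIYSQKYELVAPSDAMLRDGDWTAGNELFS
NPSLVPRSQKTTYQVTVQHTLSTIVGGAPIFHTIQLTERLLKKYVDQDKYIQAVREESEG
VNHLEIAVFIVCRDIESKHLTGHGTVLFNGARKDTISNIKLGVNQLIDSSAETRYTGGMK
FFSESLANLDVGLGLAGYQNEANFVPNEDQVLLTTEPTAEFTELYTLSKGHLNKWPQNNP
QMATKSEVDADSRSEELEKESTEKKQNTPTKGSIDYTAKVAAPSKKESGGLDKQHAICEE
LFIVSLPNMVGLLLQGKDPTALSRTGKAENNAMNTTEIT
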