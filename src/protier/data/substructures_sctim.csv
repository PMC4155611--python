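label,kind,range,sequence
D1,beta,2-15,ARTFFVGGNFKLNG
D2,alpha,15-30,GSKQSIKEIVERLNTA
D3,beta,30-43,ASIPENVEVVICPP
D4,alpha,43-55,PATYLDYSVSLVK
D5,loop,55-74,KKPQVTVGAQNAYLKASGAF
D6,alpha,74-88,FTGENSVDQIKDVGA
D7,beta,88-96,AKWVILGHS
D8,alpha,96-105,SERRSYFHED
D9,alpha,105-120,DDKFIADKTKFALGQG
D10,beta,12-130,GVGVILCIGET
D11,alpha,130-139,TLEEKKAGKT
D12,alpha,139-151,TLDVVERQLNAVL
D13,beta,151-166,LEEVKDWTNVVVAYEP
D14,loop,166-177,PVWAIGTGLAAT
D15,alpha,177-204,TPEDAQDIHASIRKFLASKLGDKAASEL
D16,beta,204-211,LRILYGGS
D17,alpha,211-225,SANGSNAVTFKDKAD
D18,beta,225-237,DVDGFLVGGASLK
D19,alpha,237-248,KPEFVDIINSRN
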