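>UTIL_TRYP1 synthetic placeholder, trypsin
SKEPIMEWSKEFKEMFYQTSKHSEEFSHMVISNCMAMHSISRYGLHWFT
>UTIL_TRYP2 synthetic placeholder, trypsin fragment
YRTERYGMYIEERELECANGMPCTFTCWIEGKPYNFVGCEDLIKAHSGESAGAMVRYIHC
LPMTICYGCIEKCRWC
>UTIL_TRYP3 synthetic placeholder, trypsin fragment
CHAFPWICTYPIRLYADMEEQMLHEQVNTVMISNFNKQCIGEGMDKSWSIKMEQGEDSLI
FQGVEVIFVAINDHGMTGI
>UTIL_CHYM1 synthetic placeholder, chymotrypsin
YYMEVGYYSPYNIMHRTMKEMPPLWQLFGCAAPWIPWGWVAHISWNYSQADLPYDHCLGN
GVAIYWPGFDE
>UTIL_CHYM2 synthetic placeholder, chymotrypsin fragment
SQQTWLVTHYAPGWDMAWHFDDSMTFDDHEVPSIWMHMGCFIQMPDFASYYANLFLSNTP
VSVE
>UTIL_CHYM3 synthetic placeholder, chymotrypsin fragment
HQYYCYGMWGFNCISHSWVNDRAYMHYQHNGLILIRARWYTVHTDARESYSTFQVKSMYV
IID
>UTIL_ARGC1 synthetic placeholder, Arg-C protease
DKIAYLKRQAGQWAQHFRWTEWDHQSCFDLWINPCPWQHRIRLGKQVSTVMKKVTQDMTV
RGFNCWVFGFTPNMSIDTPCT
>UTIL_ARGC2 synthetic placeholder, Arg-C fragment
CQDMLPHDRELDVEVNQPVLLNWSNKQDHQNPRWYPMAVRTCKQITPVWLSIIELI
>UTIL_LYSC1 synthetic placeholder, Lys-C protease
EIIRSHKGIYDSWQAQIKKPQGHSYMAQYFPRYCANITCMADEAGTCEHRQKDVEQCCWY
>UTIL_LYSC2 synthetic placeholder, Lys-C fragment
LKCRGTPGPIAPVKDWQCGTNKHHCYAHPAYWFYNTCGMWYPLSEKMLALSKYC
>UTIL_ASPN1 synthetic placeholder, Asp-N protease
WNCTVAFWRRFTSLIKLAWFSWIAMGNYCRCVHCKEFYPPTRMSYDTVCVDAMVIAVLMI
PCAWEASHSLPEAFGYFDCKTTEY
>UTIL_ASPN2 synthetic placeholder, Asp-N fragment
YACQFMMFQCSNKTITPQPFNMRWELRLCVPQKYAAECQVNDWNPDHHYCPMCWFQETDA
FCAWADHYCKKITPS
>UTIL_ENO1 synthetic placeholder, yeast enolase 1 mass standard
VWKFRLKFEPPAAHHGNQFYYDWTKKVPGRLMCYRWWDGRESHQDYWPTNEVNETNQHPV
AIFAEPKQCIQVRSFFNHPPWEDV
>UTIL_ENO2 synthetic placeholder, yeast enolase 2 mass standard
VNLGCSFSCGSNLMVTKWSAPYFDQFLWEFCPYVLANYFKIDYMNPEGFPDLRDWKH
>UTIL_ENO3 synthetic placeholder, yeast enolase fragment
KLALKMKPKLDATVESWPMTVQRKVCATFRTDYIDVVAKGVRLFMWQRWYHQLSVRDYRR
>UTIL_ENO4 synthetic placeholder, yeast enolase fragment
FRTRDCPGRTCRASHASHGQHKFNASDPDPFKTLRFLNGQETYCCMTNGWKLVGEHQKEK
>UTIL_PROT1 synthetic placeholder, protease fragment
WEHKQKNRSTKDIRMGMTLLRHIIADEHTILWRIAGLYPEGHTDDTMHIDNWYSQIDMRA
NYWWHPAPDLRRITIWPFMCSAFMF
>UTIL_PROT2 synthetic placeholder, protease fragment
ASYIDCDRGFHLGVRFGYTGWAKNCHYPFPGDDVDWCGDVQEVNSFIARRWNCNKHMFE
>UTIL_PROT3 synthetic placeholder, protease fragment
PCEFAFYYAGISPFCVCYHIDTCLQCSINKHRSILGCKAEEPPCPIKMDFQELLIMIF
>UTIL_PROT4 synthetic placeholder, protease fragment
MSNVKPWFVGQKKRNEIAHMMHSKRAEIFKKSITARYPTGRFKQVNCKCDINCC
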