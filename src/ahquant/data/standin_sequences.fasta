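>STANDIN-PTPRZ1 synthetic stand-in sequence, average mass 254087.0 Da
IGKFTTGHGRGGIHFFSNLNKNEGCCEGNVGWEAATCRIAGHQCTGICSHHDCRTIWGTT
FDTGTGFKAGWTEYGFVASDLAKRTGYIEEYIKGRFPWGEMLQRKGGNHDSTGDIWPYMC
AGWGMIHCTGKPQVTSWGIYNKDWGFMMGVWHGFAGETGPNGRQGTAKSFLEAAGWMQGW
GGIRPDGFTDGTDWFGNQSYGYTTLDGSGLGICGKSGKGWWRDGTNVQTGNGFGINRFMN
SHGWAWDTGYDRVTYGPHGAFALWTYFYEFEGFPRMISTRGPGGKWSAGEPLIVGAHFLP
QSRWDAHWYHRWWGGGIMHAYVIGSSIDGEGRNGGGGHDCHFSYHNWDQGQMCGGKTTCW
GCVHWYPYAEPDCMGGNLCSSYMEVGIGPQVGGCCQWFEGHWSATSGFHAGEGSTGMSIK
CFNKGVDELSVFCAFAGECGGLSGRMGTMAGPGNWFSPMRGWYVQRYWALVGRTNFEEIS
RYSAFMCYCHNRGSEECETVGQEKSVASGDRWKACRFEIVLAIIMAFGGPTEFSGEIMTH
WRLWSWVQGTNAYRGGHGCTGFRSGRIWRILCVEMCGANGDHVQFSSQPPCALEGGMADY
KQAKGHVTNTDEEHPWERPTWGSMGRIGMSKGKFNQEFGINGMRYMMFSDGVWKEGYHVD
HDYWPDNMIVCKCPIFKHPGHWEGRVVYEYWKGAAGIYWNGETKPQGGQCAHGRWCEHAT
WGVFDWNGAVWCCCGGDWEMGLWRHQGKYGQAHGVAGHDGPGTDPRFEVRYPPLANAHGH
GGMCRLGKNRGNQMSNGDHGGQIMLFSQYIGSGMGMGPYCKSMADKQQANFMSRRHGDSI
PGMQGCYRTVFWDAQEYHGPGGWTFMRWGCAGINHDHCIEGPGYGHWVQGMSPSNHWMQG
QGGQFICENGGRGICCNGRQLWCSMGEQFCGGAFHGQMPPKRGGFGLGGIPPCFNLGAQR
GNAYDAKNGNGGSLRLRTIGGFIGGSGTWMDDFQSPSNWVKNRWLGDLGMHLLMGDVGPG
RNEVWRIDRAEGLFNTFGGGGGGNCQTQGKRGRPLGPLCTSGQHEFTYGVSSTCCGIAKF
GGNSGLEFCYKGEDQTPNGSFSGGQHPSVPWMGASDRRMPIAAADEGYICGPRFHGGCRG
QAFGQGYGSGIWYLRQTIMDEWTKGTEGECGLDGWNGVGWMMRSWGLVGGVVGVISGQYI
TGVEIGTHCAGTIGGEVPKYAFWGPFWGAGGLGGASKTQGGEDEPGVLTQLELRLGMKQR
HVCVYGCMCVGWANIWHGRILCKRVHHGGHMAYGGLRFSIDQGFGGEPEFVGDGKAWRSG
TIHDSGLTRHCRNENGITYWQGYGGLYVPLITLFGLVGSMTTVWWPTMIVMFQQTVGYQT
MGMSQMTGSIGMIWYIFGVSDSWVGTQGFCHFFMAVPVDHELYSEECNKGWGPPFQGPRN
IGKGCRGPGQSCFCQGIIYPESQCMINGNQGHNWTEGDKGMGFATGGDAESLCRCFPWDM
NVQGFLGPCGGSRSDWGNLARDKKPCATLCATGDLHDSGAHGTGCSTDHLCATCTGFGNG
KPLTAVVQNGSYGSQCGPCKEYAKDVQYAACGREMGPGGDNYIMKTFILCGYLYPFGQEG
TKKAPTCAGKKAGQWGGPIWFMIPWYNFIRFMAGQLPPDDIGWGVGMDFPGGLYDTRFFR
LNKGPQNCMLAFTRKCTTAFFHDYWCHGWHDGRWHMHSGQFWHGAGPNGDGKMGNGKWQP
SHGMIHEEANQYKEGMKRNLQRAGSGMVDLEGEFLFQMGPHQEGAWNTFGFGSWGIGGGT
YTTFGGTDGNDFKFGAVKGWDGMGGGRRVAWDGYHAGGGNNGVGRCYYQGQYSATFMASG
SRPCNNSQGTCSLFWRSKPGRFLDAGHHGERVVAYGWWIISVDMSTLWVCYPNFWEHRCY
GYCYWTDGPFDFHKWKGAHTGRNRYVQGKENGGIYRGSTNVHTEIGGGCEGLTQKFFGST
LNYKIFYGSNPDFWDWDLKNQMWGANKGCPLKISWGNFIQHESQSCQDHAYCQTRKVMHA
AGQADQVWLPLGGYRTSAGCVLQGLYPWRCPGGRGQESNLNGGERGYWWEYDIEGCGCHD
NPHFGCHFGKDGVFGPRWKKDWTAGGVLHKFSGPGGCGENHHPVPVCGGPGGQLAPGGWD
GMNMWWELHNKHRCGGCVKQFPGHGCYWPGKVLGKNHCPVPPGWKHFKFGDAGFCFMLTQ
NGVGSHVGGEHAAYEQETGMGPDGGISPQDHRITPGDGQKGMGAPAMPWFGFYWGGHFGL
MGFGYKKGGGPNTDFEISKQKYMLVYKSNGCIERY
>STANDIN-ALB synthetic stand-in sequence, average mass 69367.0 Da
RGWVDTGRVGQHDGVMIRGKDCPGWECLPTWPLNMEETEGMGENWGVKGMMWLCADDSMF
TFYWTHLAQRFNPTLRFKLGRKSYHHAVCDHWIDTVEGMKDGGYVRHTGPVRMQGNKSAQ
QHGMKSRPQARRTKMLWSDMYCVHWVPNWVMYVVGLHNNGTPMMITKIKGSAYGECGGGF
EDDSEVIDHHGPMCKVFDLGIWLTIHNDWYQGNSKPTFRSDECQDYTRMSGIDYENGRPV
MNYLGPIIKKSGIECDGRIGFKIHLMILEENMTRWRLPQGSDVCILSELEGQCNIVGYRE
MRAFGGMGNGNLEWSGGQSDQDISIDKQMGGLHICIQNLEKMGKKQRVARAHPDTPWDMY
HEGKAMDAHNSTGHEGEVRSSGGVIDFEHGWGGSKYDGGQQVLCYFRMLKGDHYKKDQYV
LIQGIKDYNKTWPGMQELNYGFINNKYGPEWSMNQTALGHGMWQPNNQSLRSWGSYWITK
GKQKGLAGGTHIVLHGSSDGNPPSGLAAKSVRCNYGERHQDQWCWKRGDSACFWKLIQGY
QKWGGNCWWARGVLQWYYPRWNYQYIGRPGSAGLTRSMQLYGFKGGWGMGASMMIGQYTD
MRYGGMGAN
>STANDIN-TF synthetic stand-in sequence, average mass 77064.0 Da
RQHRIGGNMNYVMFQTQADLQPYVMGFGGLPKQIVCGWGYFRGTNGCIEFDGIVKMQGEH
FNFDPIVTNHCRKRMPQTNKQTGWQGHKEMGAGEEFESYFCTTIVLQLCGKGIVFLQIAV
WRRGGVHEKGRGQHYYGTRNIPPMQEVDCGSPDNAGPMTHQSGGEVRGGVFNGLLELEDG
GTGAYIIGGIAIRPNSTISNLNEYTFATCHMWMFGMNMEFWYHGFEDPWWVEHHVTRAED
RAWIGIGNGKVGSRGIMGWCTRLAQGIYFHMTGGDNEDTAGYGQYAHDIMHSEKDNTGWF
GEIMWKGEDRPNLDHTGYMYQMDGGKIWLEFPKTGKFCQYGMVKAFAIMWPVSWGSCGGR
GFEGKTGHIGHHHKAGKSYTSMFVGCSNGSDNGVFALIYGHGWDITEDWQTGGGKPGNAI
MGNNVYHDDIGGTPSEGRCRLQLEIYHRGTRELGPEVFWGQMHLFLPTKKSQIEFVMWPY
QYTMYMGAAKGFLTGVYPGEEVGSGGTNGLGYSGQCGLLRSWPDCGNNGGGIEWHHGTHM
GFAMWVFLGEKSDFVEGWGMQPNGGGAQMETIYCGHEFYGTVGEEGQCPGYWGHWGHHAN
GTLHPKVYLGIMLYQGHGPALLSIHGPWWAQAGFGYMAAMVEGYCWEPEVSPFGGPGYTH
VHHACANKNQPEGAAQKGRGVGQLMGMGPQGGGDNGHS
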