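>KS_ref synthetic exemplar for domain class KS
RMIGRGEGSTEVMYCSECEDDTDPSMPCQGQRGAQPNMHDKAPLPNDTVHVDHKNTHQEGDWSWAKNISK
VRHWVYCSLKETYMCWDDWLVFITFYQYGEKFQLVVFHIVAWKDMGDSPFCIANYNCRFMEWAFIRRLFF
FWRHVPNVTPCAINVVVYDNNEPWDIVGLVRLIIMLTPIVQMWIWRYWCPNQVWKWKETQSKFDTILYLM
HNTKNVWHMQLKDIVYLELQIAKRIAINWF
>AT_ref synthetic exemplar for domain class AT
PNAVQQVFNEQRIWVYHAFYWPGWTPAPWYMSDVSEIQYYQMMDKKCKMAGSELDLMWQKSNPFVGKEDQ
IYCPVINIARFLNITCYTALHKAQQHAFHSMAQSNPHRLYLRMEEENLYRIQCKWRPYHARYLSKCDNAG
AEPYLHLSFDFFGDRGESMPSAYHYVSPIHQPQWGFDTYVMHAEIIAGGMIHFRNTCASD
>DH_ref synthetic exemplar for domain class DH
TTGPIIGAKMSRSSFHTHPEIWKDCHCKHIKFEENCDHCNVWAMFKWCNTWGDVQPVTVAYPHMNKNHFQ
MNEFALRHTVRCISEATIEDPQECESCMMDADLFEAFTFRADASMWCFQAQDFEPVFWMYMLKRKAGMRR
>ER_ref synthetic exemplar for domain class ER
KVPLFESNWAVFYCPPMQYRCWDALDEYESQEFHELFYVNVQYRNHGVEERRGFAIQKPQRTSAPEAAYY
NSFCNQIMAVYAVGPMVHMEYPMEGTTLRQEWTCLCWVSAIHGGWHWVNPTIQDTPSEHDEIMGEKCMRW
GRMRGINHWYNRAAWWPEHP
>KR_ref synthetic exemplar for domain class KR
WIGMLNEGMIDVPWRNKMNNLCFYNPEHMGMEFWLPRYLSSAQQYYVNDITSNKHAFYYWLDDDLLKVPF
DQDEIKYFDHYHNCGRIKPMTNPGIQMKHSDQYYRWERLWIYFEMELVNMPDCIQMWDLHTIENVINMYR
GNCRTFHPSI
>MT_ref synthetic exemplar for domain class MT
QRLECFHEWGVTESMMLNCNIIRLKGGKPSAKYTPLAVVPHWPWLPMTKRRPHRTICHSVQATRSADITL
VMHWACEKMFYYITECNFNWKQFFENSVSTEVWYKWNCEKQTKGRDIHVKITDSNPDKYLPWTNREMVQF
>ACP_ref synthetic exemplar for domain class ACP
LHYNIQQWTGQKCEMCVNDKKFDRRKHYTHSVPCGHTAWAMTLMCCHGHVPWHMGRSRAICWVALENFEA
>C_ref synthetic exemplar for domain class C
DHFTKKWETNEDMSNIWTMYVVDYSKAMLCPQYMEENCHFKFWQGECFSGMMPVVPLHIFWIRCMLKQSG
YKSKWFWIYQYNPYRDSQEASRNDRQRRERFKFTYWWPGSSDQDIWHTALVPWMCPAQMIDFTMIWWPGR
TFGTSIAHWFYAMLLAKSATKRKHPYSPCNLECDLVVAATEDYTDLTYFCWRLVCRLTYQ
>A_ref synthetic exemplar for domain class A
LHSEEACCTMNWKLAPMVFNYASKMRQTSSGTDFDCNTADDFVRDRSNLWEQYIQIDSMMLRKWHEHRSG
LPQMFLLEHQSGAQGQMKSCLCTVIQLQTFLAISWWPFDVPCTRVGTHQMFGFQMNYWTDLPSGTNNSWI
DEDESIWASYNNSPIHHMDIWWPMHLGYDQDQHLSKCWAHSHNMIGAAKYRRQYSVTKSIWFSTQPSWAP
IITNRPYFWRMSEYTQGPTCVTGWHENALYPERCHEDSCS
>PCP_ref synthetic exemplar for domain class PCP
IRLQWFTQDTRVLIRRTTASGTQSTVATETGGNSFNYDMMFIWHKRRTAHETASKNLWAFTICTCMDNMR
>TE_ref synthetic exemplar for domain class TE
GTYIPDKDHLWVVSHYYCHHCSWVLNDCQALQPHYPDDHIHWQRPGSYYPGGKTVEDEFNSTHDYKWHLL
NTLLEVFLTEHYTQWPQPMWNKWVLYFQTPWVRHPICFVTVSCCPARYLNHMHFPRMMGDARRNGLMKHR
SHFTGPHIFT
>P450_ref synthetic exemplar for domain class P450
QQLIGKNYVWCGCWPADPVKLFKSRGMRMHPFCKASFHSQSPLRWQAWYGHLKFTNCTQSGVPMTHMVNW
GWQRCWVQYMGEVFPCKQKIQQHQCTYITTKCNSTFHTDKESFTRQTEVHANCGHAEYLSPHGMHTKEKT
YYCITAPQDYYFSDWFDHVTKHRCVQQAKLEGCFPIYFRMHHESEEIFEDLMYAYWDTCLKCHIMSSVNQ
FGWDWQTDSV
>MONOOX_ref synthetic exemplar for domain class MONOOX
RASNEQGPVYMLSEYFDVIQRWCDWYTMPSTGGSTYDRQRADSYAEPRDVCPEDPFFDNRWFHYDGRHCE
SYLTKFLSHSKFYHIQHPMIFSCYEGTNNQMKWDATTPCAIYTLQIDDMKTQDNINSDLKYCMRKTQPNA
RQIIDKIGGDPPDHPKMVAHVNNRTTYFESEDDGVYYPCVPFCVVGNVTDTMNYYYHDKN
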