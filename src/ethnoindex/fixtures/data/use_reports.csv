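informant_id,taxon_id,ailment,category,village,count
,morchella_esculenta,,GAS,,11
,morchella_esculenta,,CAR,,18
,asplenium_crinicaule,,CAR,,16
,equisetum_arvense,,GAS,,12
,adiantum_capillus_veneris,,RES,,8
,adiantum_capillus_veneris,,GAS,,11
,acorus_calamus,,CAR,,10
,acorus_calamus,,RES,,18
,acorus_calamus,,GAS,,5
,allium_sativum,,RES,,9
,allium_sativum,,MET,,3
,arisaema_jacquemontii,,CAR,,13
,arisaema_jacquemontii,,DER,,14
,arisaema_jacquemontii,,RES,,10
,asparagus_racemosus,,GYN,,36
,dioscorea_deltoidea,,GAS,,9
,dioscorea_deltoidea,,GYN,,4
,iris_kashmiriana,,SKE,,17
,iris_kashmiriana,,FVR,,5
,fritillaria_cirrhosa,,CAN,,21
,fritillaria_cirrhosa,,DER,,13
,fritillaria_cirrhosa,,GYN,,11
,notholirion_thomsonianum,,SKE,,2
,avena_fatua,,EY,,11
,cynodon_dactylon,,RES,,9
,cynodon_dactylon,,SKE,,5
,oryza_sativa,,DER,,12
,sorghum_halepense,,DER,,13
,sambucus_wightiana,,SKE,,8
,sambucus_wightiana,,ETH,,4
,amaranthus_viridis,,FVR,,10
,trachyspermum_ammi,,GAS,,24
,arctium_lappa,,CAR,,12
,arctium_lappa,,DER,,11
,artemisia_absinthium,,CAN,,8
,artemisia_absinthium,,MET,,11
,artemisia_absinthium,,SKE,,7
,artemisia_brevifolia,,GAS,,16
,artemisia_imponens,,GAS,,2
,artemisia_imponens,,PAR,,7
,cichorium_intybus,,DER,,7
,cichorium_intybus,,GYN,,2
,cichorium_intybus,,ETH,,6
,dolomiaea_macrocephala,,GAS,,16
,dolomiaea_macrocephala,,ETH,,5
,matricaria_chamomilla,,RES,,3
,dolomiaea_costus,,SKE,,4
,dolomiaea_costus,,GAS,,7
,dolomiaea_costus,,DER,,13
,dolomiaea_costus,,RES,,6
,taraxacum_officinale,,DER,,17
,taraxacum_officinale,,EY,,13
,berberis_aristata,,RES,,14
,berberis_aristata,,SKE,,6
,podophyllum_hexandrum,,MET,,9
,podophyllum_hexandrum,,SKE,,4
,podophyllum_hexandrum,,CAN,,11
,arnebia_benthamii,,CAN,,12
,arnebia_benthamii,,RES,,2
,hackelia_uncinata,,DER,,12
,capsella_bursa_pastoris,,GAS,,20
,cardamine_impatiens,,RES,,5
,nasturtium_officinale,,ETH,,8
,nasturtium_officinale,,SKE,,4
,codonopsis_rotundifolia,,MET,,33
,cannabis_sativa,,NER,,16
,celtis_australis,,CAR,,2
,dipsacus_inermis,,SKE,,2
,valeriana_jatamansi,,DER,,31
,valeriana_jatamansi,,SKE,,16
,stellaria_media,,CAR,,5
,cuscuta_cassytoides,,MET,,4
,cuscuta_cassytoides,,SKE,,9
,rhodiola_himalensis,,CAN,,16
,solena_amplexicaulis,,GAS,,8
,euphorbia_royleana,,GAS,,5
,euphorbia_royleana,,SKE,,2
,indigofera_heterantha,,RES,,4
,trifolium_repens,,RES,,9
,trigonella_foenum_graecum,,GAS,,7
,gentiana_kurrao,,FVR,,12
,geranium_wallichianum,,ENT,,7
,geranium_wallichianum,,SKE,,9
,parrotiopsis_jacquemontiana,,DER,,4
,juglans_regia,,SKE,,23
,ajuga_bracteosa,,GAS,,19
,ajuga_bracteosa,,ETH,,13
,lamium_album,,CAR,,21
,mentha_piperita,,RES,,12
,nepeta_cataria,,ETH,,5
,nepeta_cataria,,MET,,3
,prunella_vulgaris,,CAN,,8
,thymus_linearis,,GAS,,7
,thymus_linearis,,FVR,,5
,abutilon_indicum,,GAS,,5
,alcea_rosea,,RES,,3
,eriolaena_candollei,,GAS,,2
,malva_cashemiriana,,DER,,3
,malva_sylvestris,,ENT,,3
,trillium_govanianum,,CAN,,21
,ficus_carica,,GYN,,9
,ficus_carica,,RES,,7
,morus_alba,,GAS,,13
,corydalis_govaniana,,CAN,,13
,papaver_somniferum,,NER,,12
,phytolacca_acinosa,,NER,,10
,picrorhiza_kurroa,,GAS,,16
,picrorhiza_kurroa,,SKE,,11
,plantago_lanceolata,,CAR,,12
,wulfeniopsis_amherstiana,,DER,,11
,persicaria_hydropiper,,IB,,6
,persicaria_hydropiper,,GAS,,2
,persicaria_mitis,,GAS,,4
,rheum_australe,,CAR,,17
,rheum_emodi,,MET,,10
,rumex_acetosa,,RES,,18
,rumex_acetosa,,EY,,17
,portulaca_oleracea,,CAN,,15
,portulaca_oleracea,,CAR,,8
,portulaca_oleracea,,SKE,,10
,lysimachia_arvensis,,DER,,3
,lysimachia_arvensis,,ENT,,9
,lysimachia_arvensis,,RES,,3
,aconitum_chasmanthum,,GYN,,13
,aconitum_heterophyllum,,RES,,7
,aconitum_heterophyllum,,GYN,,11
,anemonastrum_obtusilobum,,CAR,,13
,anemonastrum_obtusilobum,,NER,,4
,aquilegia_vulgaris,,GYN,,2
,aquilegia_vulgaris,,DER,,9
,ranunculus_hirtellus,,ETH,,3
,ranunculus_hirtellus,,RES,,9
,zizyphus_mauritiama,,CAR,,21
,zizyphus_mauritiama,,DER,,3
,cormus_domestica,,RES,,15
,cydonia_oblonga,,RES,,12
,fragaria_vesca,,ENT,,13
,fragaria_vesca,,GAS,,2
,geum_elatum,,RES,,4
,potentilla_indica,,RES,,11
,rosa_webbiana,,RES,,8
,rosa_webbiana,,EY,,4
,galium_aparine,,GAS,,9
,verbascum_thapsus,,RES,,8
,populus_alba,,RES,,7
,salix_alba,,ETH,,2
,salix_alba,,RES,,6
,salix_alba,,SKE,,2
,aesculus_indica,,DER,,4
,aesculus_indica,,GAS,,5
,bergenia_ciliata,,ENT,,14
,bergenia_ciliata,,GAS,,11
,bergenia_ciliata,,FVR,,4
,atropa_acuminata,,GYN,,13
,datura_stramonium,,DER,,7
,datura_stramonium,,SKE,,9
,hyoscyamus_niger,,NER,,21
,solanum_pseudocapsicum,,CAN,,7
,urtica_dioica,,SKE,,16
,viola_odorata,,RES,,5
,viola_odorata,,FVR,,18
,vitis_vinifera,,RES,,11
,juniperus_communis,,GAS,,9
,cedrus_deodara,,DER,,16
,cedrus_deodara,,NER,,11
,pinus_roxburghii,,GAS,,4
,pinus_roxburghii,,EY,,11
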