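taxon_id,urs,fq,ri
morchella_esculenta,29,28.43,35.23
asplenium_crinicaule,16,15.69,38.64
equisetum_arvense,12,11.76,87.5
adiantum_capillus_veneris,19,18.63,26.14
acorus_calamus,33,32.35,39.77
allium_sativum,12,11.76,43.18
arisaema_jacquemontii,37,36.27,57.95
asparagus_racemosus,36,35.29,47.73
dioscorea_deltoidea,13,12.75,43.18
iris_kashmiriana,22,21.57,48.86
fritillaria_cirrhosa,45,44.12,48.86
notholirion_thomsonianum,2,1.96,26.14
avena_fatua,11,10.78,34.09
cynodon_dactylon,14,13.73,35.23
oryza_sativa,12,11.76,53.41
sorghum_halepense,13,12.75,35.23
sambucus_wightiana,12,11.76,34.09
amaranthus_viridis,10,9.8,44.32
trachyspermum_ammi,24,23.53,35.23
arctium_lappa,23,22.55,39.77
artemisia_absinthium,26,25.49,48.86
artemisia_brevifolia,16,15.69,53.41
artemisia_imponens,9,8.82,44.32
cichorium_intybus,15,14.71,53.41
dolomiaea_macrocephala,21,20.59,26.14
matricaria_chamomilla,3,2.94,48.86
dolomiaea_costus,26,25.49,65.91
taraxacum_officinale,30,29.41,62.5
berberis_aristata,20,19.61,44.32
podophyllum_hexandrum,24,23.53,53.41
arnebia_benthamii,14,13.73,48.86
hackelia_uncinata,12,11.76,35.23
capsella_bursa_pastoris,20,19.61,53.41
cardamine_impatiens,5,4.9,39.77
nasturtium_officinale,12,11.76,56.82
codonopsis_rotundifolia,33,32.35,51.14
cannabis_sativa,16,15.69,56.82
celtis_australis,2,1.96,48.86
dipsacus_inermis,2,1.96,26.14
valeriana_jatamansi,47,46.08,56.82
stellaria_media,5,4.9,47.73
cuscuta_cassytoides,13,12.75,26.14
rhodiola_himalensis,16,15.69,90.91
solena_amplexicaulis,8,7.84,38.64
euphorbia_royleana,7,6.86,52.27
indigofera_heterantha,4,3.92,26.14
trifolium_repens,9,8.82,53.41
trigonella_foenum_graecum,7,6.86,39.77
gentiana_kurrao,12,11.76,69.32
geranium_wallichianum,16,15.69,21.59
parrotiopsis_jacquemontiana,4,3.92,56.82
juglans_regia,23,22.55,39.77
ajuga_bracteosa,32,31.37,38.64
lamium_album,21,20.59,69.32
mentha_piperita,12,11.76,53.41
nepeta_cataria,8,7.84,52.27
prunella_vulgaris,8,7.84,30.68
thymus_linearis,12,11.76,60.23
abutilon_indicum,5,4.9,46.59
alcea_rosea,3,2.94,26.14
eriolaena_candollei,2,0.98,30.68
malva_cashemiriana,3,2.94,35.23
malva_sylvestris,3,2.94,61.36
trillium_govanianum,21,20.59,35.23
ficus_carica,16,15.69,56.82
morus_alba,13,12.75,48.86
corydalis_govaniana,13,12.75,35.23
papaver_somniferum,12,11.76,44.32
phytolacca_acinosa,10,9.8,35.23
picrorhiza_kurroa,27,26.47,26.14
plantago_lanceolata,12,11.76,44.32
wulfeniopsis_amherstiana,11,10.78,48.86
persicaria_hydropiper,8,7.84,21.59
persicaria_mitis,4,3.92,21.59
rheum_australe,17,16.67,43.18
rheum_emodi,10,9.8,26.14
rumex_acetosa,35,34.31,44.32
portulaca_oleracea,33,32.35,21.59
lysimachia_arvensis,15,14.71,47.73
aconitum_chasmanthum,13,12.75,78.41
aconitum_heterophyllum,18,17.65,47.73
anemonastrum_obtusilobum,17,6.86,55.68
aquilegia_vulgaris,11,10.78,48.86
ranunculus_hirtellus,12,11.76,53.41
zizyphus_mauritiama,24,20.59,30.68
cormus_domestica,15,14.71,48.86
cydonia_oblonga,12,11.76,44.32
fragaria_vesca,15,14.71,44.32
geum_elatum,4,3.92,48.86
potentilla_indica,11,10.78,47.73
rosa_webbiana,12,11.76,53.41
galium_aparine,9,8.82,26.14
verbascum_thapsus,8,7.84,35.23
populus_alba,7,6.86,73.86
salix_alba,10,9.8,21.59
aesculus_indica,9,8.82,26.14
bergenia_ciliata,29,28.43,39.77
atropa_acuminata,13,12.75,38.64
datura_stramonium,16,15.69,44.32
hyoscyamus_niger,21,20.59,30.68
solanum_pseudocapsicum,7,6.86,30.68
urtica_dioica,16,15.69,48.86
viola_odorata,23,22.55,55.68
vitis_vinifera,11,10.78,39.77
juniperus_communis,9,8.82,65.91
cedrus_deodara,27,26.47,47.73
pinus_roxburghii,15,14.71,44.32
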