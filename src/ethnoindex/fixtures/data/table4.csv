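family,urs,uv,fuv
Liliaceae,47,0.47,0.24
Poaceae,50,0.5,0.13
Asteraceae,169,1.66,0.17
Berberidaceae,44,0.44,0.22
Boraginaceae,26,0.26,0.13
Brassicaceae,37,0.37,0.12
Cannabaceae,18,0.18,0.09
Caprifoliaceae,49,0.48,0.24
Fabaceae,20,0.2,0.07
Lamiaceae,93,0.92,0.15
Malvaceae,15,0.15,0.03
Moraceae,29,0.29,0.15
Papaveraceae,25,0.25,0.13
Plantaginaceae,50,0.49,0.16
Polygonaceae,74,0.73,0.15
Portulacaceae,48,0.47,0.24
Ranunculaceae,61,0.61,0.12
Rosaceae,69,0.69,0.12
Salicaceae,17,0.17,0.09
Solanaceae,57,0.57,0.14
Pinaceae,42,0.41,0.21
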