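common_name,scientific_name,equivalent_radius_cm
"Euonymus, deciduous",Euonymus alatus,1.7
Paperbark maple,Acer griseum,1.7
River birch,Betula nigra,1.8
Ornamental cherry,Prunus spp.,1.8
American beech,Fagus grandifolia,2.1
Higan cherry,Prunus subhirtella,2.5
Ginkgo,Ginkgo biloba,2.5
Redbud,Cercis canadensis,2.8
Swamp white oak,Quercus bicolor,4.6
Pin oak,Quercus palustris,5.0
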