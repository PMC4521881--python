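taxon,group,context_tag
Amaranthus sp.,weeds/grasses,
Anagallis arvensis,weeds/grasses,
Arrhenatherum elatius,weeds/grasses,
Artemisia sp.,weeds/grasses,
Atriplex sp.,weeds/grasses,
Avena fatua,weeds/grasses,
Avenula pubescens,weeds/grasses,
Bromus sp.,weeds/grasses,
Capsella bursa-pastoris,weeds/grasses,
Carduus sp.,weeds/grasses,
Cichorium intybus,weeds/grasses,
Convolvulus arvensis,weeds/grasses,
Dactylis glomerata,weeds/grasses,
Deschampsia flexuosa,weeds/grasses,
Elymus repens,weeds/grasses,
Fagopyrum esculentum,weeds/grasses,volunteer
Fallopia convolvulus,weeds/grasses,
Festuca rubra agg,weeds/grasses,
Unidentified grass,weeds/grasses,
Hieracium sp.,weeds/grasses,
Hordeum murinum,weeds/grasses,
Hypochaeris,weeds/grasses,
Juncus sp.,weeds/grasses,
Lactuca virosa,weeds/grasses,
Lamium sp.,weeds/grasses,
Leontodon sp.,weeds/grasses,
Lolium sp.,weeds/grasses,
Lotus sp.,weeds/grasses,
Medicago sativa,weeds/grasses,
Nardus stricta,weeds/grasses,
Panicum miliaceum,weeds/grasses,
Papaver rhoeas,weeds/grasses,
Plantago lanceolata,weeds/grasses,
Poa sp.,weeds/grasses,
Polygonum aviculare,weeds/grasses,
Rubus caesius,weeds/grasses,
Silene sp.,weeds/grasses,
Stellaria media,weeds/grasses,
Thymus pulegioides,weeds/grasses,
Trifolium incarnatum/resupinatum,weeds/grasses,
Trifolium pratense,weeds/grasses,
Trifolium repens,weeds/grasses,
Trifolium sp.,weeds/grasses,
Verbascum sp.,weeds/grasses,
Unidentified weed,weeds/grasses,
Hordeum vulgare,cereals,
Secale cereale,cereals,
Triticum aestivum,cereals,
Zea mays,cereals,
Fagopyrum esculentum,intertillage,intertillage
Lathyrus sp.,intertillage,
Phacelia,intertillage,
Pisum sativum,intertillage,intertillage
Sinapis arvensis,intertillage,
Beta vulgaris,other field crops,
Daucus carota,other field crops,
Glycine max,other field crops,
Helianthus annuus,other field crops,
Pisum sativum,other field crops,crop
Cornus sanguinea,trees/shrubs,
Robinia pseudoacacia,trees/shrubs,
Malus domestica,trees/shrubs,
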