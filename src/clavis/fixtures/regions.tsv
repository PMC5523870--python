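# source: per-species geographic regions from the reference comparison table; code vocabulary from the key-outline diagrams
# vocabulary: C;E-northeast;E-southeast;N;S;Arg;Bol;Col;Ecu;FrG;Par;Per;Sur;Uru;Ven
# note: compound region strings are split on their separators and state qualifiers in parentheses are dropped; species not in the source table are absent here and reported as missing by the loader
taxon	region_codes
S. itapebiensis	Atlantic Forest
S. weddelliana	Atlantic Forest
S. hoehnei	Atlantic Forest
S. insignis	Atlantic Forest
S. amara	Caribbean
S. orinocensis	Amazon
S. stenopetala	Amazon
S. inajai	Amazon
S. botryophora	Atlantic Forest
S. stratincola	Amazon
S. cocoides	Amazon
S. flexuosa	Central Brazil
S. vermicularis	Amazon
S. pseudococos	Atlantic Forest
S. smithii	Amazon
S. sancona	Andes;Amazon
S. cardenasii	Andes
S. mendanhensis	Eastern Brazil
S. pleioclada	Eastern Brazil
S. comosa	Eastern Brazil;Central Brazil
S. gouveiana	Eastern Brazil
S. duartei	Eastern Brazil
S. kellyana	Eastern Brazil
S. coronata	Eastern Brazil
S. harleyi	Eastern Brazil
S. petraea	Bolivia
S. glaucescens	Eastern Brazil
S. glazioviana	Eastern Brazil;Central Brazil
S. rupicola	Central Brazil
S. longipedunculata	Central Brazil
S. oleracea	Eastern Brazil;Central Brazil
S. cearensis	Eastern Brazil
S. cerqueirana	Central Brazil;Paraguay
S. yungasensis	Andes
S. macrocarpa	Eastern Brazil
S. lorenzoniorum	Eastern Brazil
S. caerulescens	Central Brazil
S. campylospatha	Central Brazil;Paraguay
S. graminifolia	Central Brazil
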