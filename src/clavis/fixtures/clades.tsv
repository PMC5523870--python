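# source: reference comparison table of nuclear-DNA clades versus key branches
# note: clade labels normalize by dropping any /-suffix; 'molecular' = member of the clade in the original molecular analysis, 'listed' = printed in that clade row's key-branch species list
clade	key_branch	taxon	molecular	listed
Rain Forest/ Lytocaryum	53	S. itapebiensis	1	1
Rain Forest/ Lytocaryum	53	S. weddelliana	1	1
Rain Forest/ Lytocaryum	53	S. hoehnei	0	1
Rain Forest/ Lytocaryum	53	S. insignis	0	1
Rain Forest	57'	S. amara	1	1
Rain Forest	57'	S. orinocensis	1	1
Rain Forest	57'	S. stenopetala	1	1
Rain Forest	57'	S. inajai	0	1
Rain Forest	57'	S. botryophora	1	1
Rain Forest	57'	S. stratincola	0	1
Rain Forest	57'	S. cocoides	1	1
Rain Forest	57'	S. flexuosa	0	1
Rain Forest	57'	S. vermicularis	1	1
Rain Forest	57'	S. pseudococos	0	1
Rain Forest	57'	S. smithii	0	1
Rain Forest	57'	S. sancona	1	1
Rain Forest	57'	S. cardenasii	0	1
Rain Forest	57'	S. ruschiana	1	0
Eastern Brazilian	18	S. mendanhensis	0	1
Eastern Brazilian	18	S. pleioclada	0	1
Eastern Brazilian	18	S. comosa	0	1
Eastern Brazilian	18	S. gouveiana	0	1
Eastern Brazilian	18	S. duartei	0	1
Eastern Brazilian	18	S. kellyana	1	1
Eastern Brazilian	18	S. coronata	1	1
Eastern Brazilian	18	S. harleyi	0	1
Eastern Brazilian	18	S. petraea	0	1
Eastern Brazilian	18	S. glaucescens	1	1
Eastern Brazilian	18	S. glazioviana	0	1
Eastern Brazilian	18	S. rupicola	0	1
Eastern Brazilian	18	S. longipedunculata	0	1
Eastern Brazilian	43'	S. kellyana	1	1
Eastern Brazilian	43'	S. oleracea	1	1
Eastern Brazilian	43'	S. cearensis	1	1
Clustered stemmed	3'	S. cerqueirana	1	1
Clustered stemmed	3'	S. yungasensis	0	1
Clustered stemmed	3'	S. macrocarpa	1	1
Clustered stemmed	3'	S. lorenzoniorum	0	1
Clustered stemmed	3'	S. caerulescens	0	1
Clustered stemmed	3'	S. campylospatha	1	1
Clustered stemmed	3'	S. graminifolia	0	1
Clustered stemmed	3'	S. flexuosa	1	0
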