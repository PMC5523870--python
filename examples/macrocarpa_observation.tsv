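char_id	value
adaxial_fb_extent	over_one_third
mesophyll_minor_veins	few_or_none
marginal_vein_exaggerated	absent_or_small
adaxial_minor_veins	absent
lamina_thickness	0.2
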