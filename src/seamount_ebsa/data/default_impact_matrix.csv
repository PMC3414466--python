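activity,physical_habitat,corals_and_sponges,groundfish,large_pelagics,air_breathing_visitors
gillnet_bottom,1,1,1,1,1
hook_and_line,1,1,1,1,1
longline_bottom,1,1,1,2,5
longline_pelagic,1,5,5,1,1
pots_and_traps,2,1,2,1,1
purse_seine,1,5,1,1,1
trawl_bottom,5,1,1,5,1
trawl_midwater,1,1,3,1,1
mineral_extraction,5,5,3,1,1
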