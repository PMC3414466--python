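seamount,domain,item_id,status,quality
Sedlo,indicator,vents,absent,L
Sedlo,indicator,macrophytes,absent,H
Sedlo,indicator,cold_water_corals,present,H
Sedlo,indicator,sponge_aggregations,present,H
Sedlo,indicator,aggregating_fishes,present,H
Sedlo,indicator,threatened_bottom_fishes,present,H
Sedlo,indicator,threatened_air_breathing,present,M
Sedlo,indicator,threatened_visiting_pelagics,present,L
Sedlo,indicator,naturalness,present,H
Sedlo,indicator,shallow_depth,present,H
Sedlo,threat,gillnet_bottom,absent,H
Sedlo,threat,hook_and_line,absent,M
Sedlo,threat,longline_bottom,absent,M
Sedlo,threat,longline_pelagic,present,L
Sedlo,threat,pots_and_traps,absent,M
Sedlo,threat,purse_seine,absent,H
Sedlo,threat,trawl_bottom,absent,H
Sedlo,threat,trawl_midwater,absent,H
Sedlo,threat,mineral_extraction,absent,H
Condor,indicator,vents,absent,M
Condor,indicator,macrophytes,absent,M
Condor,indicator,cold_water_corals,present,H
Condor,indicator,sponge_aggregations,present,H
Condor,indicator,aggregating_fishes,present,M
Condor,indicator,threatened_bottom_fishes,present,M
Condor,indicator,air_breathing,present,M
Condor,indicator,threatened_visiting_pelagics,present,M
Condor,indicator,naturalness,absent,M
Condor,indicator,shallow_depth,present,H
Condor,threat,gillnet_bottom,absent,M
Condor,threat,hook_and_line,present,M
Condor,threat,longline_bottom,present,M
Condor,threat,longline_pelagic,present,M
Condor,threat,pots_and_traps,absent,M
Condor,threat,purse_seine,absent,M
Condor,threat,trawl_bottom,absent,M
Condor,threat,trawl_midwater,absent,M
Condor,threat,mineral_extraction,absent,M
Rosemary,indicator,vents,DD,
Rosemary,indicator,macrophytes,absent,H
Rosemary,indicator,cold_water_corals,present,L
Rosemary,indicator,sponge_aggregations,DD,
Rosemary,indicator,aggregating_fishes,present,H
Rosemary,indicator,threatened_bottom_fishes,present,H
Rosemary,indicator,air_breathing,present,M
Rosemary,indicator,threatened_visiting_pelagics,DD,
Rosemary,indicator,visiting_pelagics,DD,
Rosemary,indicator,naturalness,absent,M
Rosemary,indicator,shallow_depth,present,H
Rosemary,threat,gillnet_bottom,present,M
Rosemary,threat,hook_and_line,absent,M
Rosemary,threat,longline_bottom,present,M
Rosemary,threat,longline_pelagic,present,M
Rosemary,threat,pots_and_traps,present,M
Rosemary,threat,purse_seine,absent,M
Rosemary,threat,trawl_bottom,present,M
Rosemary,threat,trawl_midwater,present,M
Rosemary,threat,mineral_extraction,DD,
Anton Dohrn,indicator,vents,DD,
Anton Dohrn,indicator,macrophytes,absent,H
Anton Dohrn,indicator,cold_water_corals,present,M
Anton Dohrn,indicator,sponge_aggregations,present,L
Anton Dohrn,indicator,aggregating_fishes,present,H
Anton Dohrn,indicator,threatened_bottom_fishes,present,H
Anton Dohrn,indicator,threatened_air_breathing,present,M
Anton Dohrn,indicator,threatened_visiting_pelagics,DD,
Anton Dohrn,indicator,visiting_pelagics,DD,
Anton Dohrn,indicator,naturalness,absent,L
Anton Dohrn,indicator,shallow_depth,present,H
Anton Dohrn,threat,gillnet_bottom,absent,M
Anton Dohrn,threat,hook_and_line,absent,M
Anton Dohrn,threat,longline_bottom,present,M
Anton Dohrn,threat,longline_pelagic,absent,M
Anton Dohrn,threat,pots_and_traps,present,M
Anton Dohrn,threat,purse_seine,absent,M
Anton Dohrn,threat,trawl_bottom,present,M
Anton Dohrn,threat,trawl_midwater,absent,M
Anton Dohrn,threat,mineral_extraction,DD,
Josephine,indicator,vents,DD,
Josephine,indicator,macrophytes,absent,L
Josephine,indicator,cold_water_corals,present,M
Josephine,indicator,sponge_aggregations,present,M
Josephine,indicator,aggregating_fishes,present,H
Josephine,indicator,threatened_bottom_fishes,present,M
Josephine,indicator,threatened_air_breathing,present,M
Josephine,indicator,threatened_visiting_pelagics,DD,
Josephine,indicator,visiting_pelagics,DD,
Josephine,indicator,naturalness,absent,M
Josephine,indicator,shallow_depth,present,M
Josephine,threat,gillnet_bottom,present,L
Josephine,threat,hook_and_line,DD,
Josephine,threat,longline_bottom,present,L
Josephine,threat,longline_pelagic,present,L
Josephine,threat,pots_and_traps,DD,
Josephine,threat,purse_seine,DD,
Josephine,threat,trawl_bottom,present,L
Josephine,threat,trawl_midwater,present,L
Josephine,threat,mineral_extraction,absent,H
Gorringe,indicator,vents,DD,
Gorringe,indicator,macrophytes,present,H
Gorringe,indicator,cold_water_corals,present,M
Gorringe,indicator,sponge_aggregations,present,L
Gorringe,indicator,aggregating_fishes,present,M
Gorringe,indicator,threatened_bottom_fishes,present,M
Gorringe,indicator,threatened_air_breathing,present,H
Gorringe,indicator,threatened_visiting_pelagics,DD,
Gorringe,indicator,visiting_pelagics,DD,
Gorringe,indicator,naturalness,absent,M
Gorringe,indicator,shallow_depth,present,H
Gorringe,threat,gillnet_bottom,DD,
Gorringe,threat,hook_and_line,DD,
Gorringe,threat,longline_bottom,present,M
Gorringe,threat,longline_pelagic,DD,
Gorringe,threat,pots_and_traps,present,L
Gorringe,threat,purse_seine,present,L
Gorringe,threat,trawl_bottom,present,L
Gorringe,threat,trawl_midwater,present,L
Gorringe,threat,mineral_extraction,DD,
Bowie,indicator,vents,absent,M
Bowie,indicator,macrophytes,present,M
Bowie,indicator,cold_water_corals,absent,M
Bowie,indicator,sponge_aggregations,absent,M
Bowie,indicator,aggregating_fishes,present,M
Bowie,indicator,threatened_bottom_fishes,present,M
Bowie,indicator,threatened_air_breathing,present,M
Bowie,indicator,threatened_visiting_pelagics,present,M
Bowie,indicator,naturalness,absent,M
Bowie,indicator,shallow_depth,present,H
Bowie,threat,gillnet_bottom,absent,M
Bowie,threat,hook_and_line,present,M
Bowie,threat,longline_bottom,present,M
Bowie,threat,longline_pelagic,absent,M
Bowie,threat,pots_and_traps,present,M
Bowie,threat,purse_seine,absent,M
Bowie,threat,trawl_bottom,absent,M
Bowie,threat,trawl_midwater,absent,M
Bowie,threat,mineral_extraction,absent,M
Cobb,indicator,vents,DD,
Cobb,indicator,macrophytes,present,M
Cobb,indicator,cold_water_corals,absent,M
Cobb,indicator,sponge_aggregations,absent,M
Cobb,indicator,aggregating_fishes,present,M
Cobb,indicator,threatened_bottom_fishes,present,M
Cobb,indicator,threatened_air_breathing,present,M
Cobb,indicator,threatened_visiting_pelagics,present,M
Cobb,indicator,naturalness,absent,H
Cobb,indicator,shallow_depth,present,H
Cobb,threat,gillnet_bottom,present,M
Cobb,threat,hook_and_line,DD,
Cobb,threat,longline_bottom,present,H
Cobb,threat,longline_pelagic,DD,
Cobb,threat,pots_and_traps,present,H
Cobb,threat,purse_seine,DD,
Cobb,threat,trawl_bottom,absent,H
Cobb,threat,trawl_midwater,present,H
Cobb,threat,mineral_extraction,DD,
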