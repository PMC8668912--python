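setting,qb_ml_min,qd_ml_h,cd_mg_l,c_al_mg_l,c_rl_mg_l,percent_change,source_note
QB1QD3,100,3000,0,16.0,10.304,-35.6,reported maximum loss; assigned to the most loss-favourable flow corner (assumption)
QB3QD1,200,1000,0,16.0,14.592,-8.8,reported minimum loss; assigned to the least loss-favourable corner (assumption); exceeds the diffusive ceiling qd/qb=8.33% there
QB2QD1,150,1000,0,16.0,13.7232,-14.23,flow-stratified mean loss at 1000 ml/h dialysate flow; blood flow assumed mid-grid
QB2QD3,150,3000,0,16.0,14.0976,-11.89,flow-stratified mean loss at 3000 ml/h dialysate flow; blood flow assumed mid-grid; non-monotonic vs 1000 ml/h figure
QB3QD1,200,1000,64,16.0,18.992,18.7,reported minimum enrichment gain at 64 mg/L dialysate; corner assignment is an assumption
QB1QD3,100,3000,64,16.0,28.608,78.8,reported maximum enrichment gain at 64 mg/L dialysate; corner assignment is an assumption
QB2QD1,150,1000,64,16.0,19.1856,19.91,flow-stratified mean gain at 1000 ml/h dialysate flow; blood flow assumed mid-grid
QB2QD3,150,3000,64,16.0,20.016,25.1,flow-stratified mean gain at 3000 ml/h dialysate flow; blood flow assumed mid-grid
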