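# Demographic profile of each patient group in the reference multimorbidity
# cohort, plus the non-multimorbid (<2 conditions) background stratum; used as
# the default demographics of the synthetic episode generator.
# n: group size; ages: median and quartiles (years); male_pct: % male;
# simd1..simd5: % per deprivation quintile (1 = most deprived);
# ur1..ur6: % per sixfold urban-rural class (1 = large urban ... 6 = remote rural);
# emergency_pct: % of index admissions that were emergencies.
group,n,age_median,age_q1,age_q3,male_pct,simd1,simd2,simd3,simd4,simd5,ur1,ur2,ur3,ur4,ur5,ur6,emergency_pct
g1,2590,78,68,84,51.6,6.3,14.5,24.7,26.9,27.4,38.4,15.4,8.3,9.8,17.5,10.1,76.6
g2,1290,70,60,79,42.3,11.9,17.5,28.1,22.3,19.7,41.3,15.9,8.1,8.5,18.1,7.1,77.8
g3,931,51,39,64,53.1,14.1,21.2,27.0,19.3,18.0,49.4,15.9,6.1,8.6,13.3,5.5,86.3
g4,878,75,66,81,52.7,8.1,16.7,26.3,25.6,23.1,35.8,16.9,8.1,10.3,19.9,8.4,73.9
g5,1396,76,64,84,42.0,8.7,14.9,24.2,25.3,26.4,39.8,17.3,8.7,9.8,14.7,8.7,74.4
g6,834,69,56,79,35.4,9.1,15.9,21.7,25.2,27.7,39.7,15.6,9.7,7.8,17.3,9.0,64.3
g7,654,66,56,74,44.6,6.9,11.6,21.3,28.0,32.1,36.4,14.8,8.3,8.4,20.3,10.6,66.2
g8,694,79,70,85,58.9,6.8,15.4,24.2,25.9,27.4,40.3,17.7,8.1,8.9,16.0,8.6,84.4
g9,1614,71,62,79,50.7,6.9,17.0,26.0,26.5,23.3,35.6,16.5,8.1,9.1,20.8,9.2,69.5
g10,508,74,64,82,15.9,6.9,17.9,21.5,25.8,28.0,40.9,16.5,7.1,10.2,16.3,8.9,68.5
background,30156,56,39,71,47.6,7.8,14.7,23.4,26.3,26.9,36.8,14.9,8.0,8.8,18.2,11.7,67.3
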