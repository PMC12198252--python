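# Published per-patient CFD-derived hemodynamic indices for the nine-patient
# percutaneous-pulmonary-valve-implantation cohort this package's synthetic
# generators emulate (pre- and post-implantation states).  Transcribed from
# the source study's per-patient summary table; Re and Wo dimensionless,
# Vo in 1/s, ED in mW.
patient,state,mpa_re,mpa_wo,mpa_vo,rpa_re,rpa_wo,rpa_vo,lpa_re,lpa_wo,lpa_vo,ed
1,pre,936.0,16.7,129.2,698.0,13.4,248.7,704.8,9.1,462.2,55.3
1,post,1004.2,14.2,75.0,725.6,11.9,188.5,352.6,13.9,125.6,64.7
2,pre,560.9,18.5,103.7,528.8,11.4,337.2,410.1,11.0,310.3,27.7
2,post,728.8,20.3,35.2,724.8,14.8,90.4,598.3,10.5,178.3,32.5
3,pre,579.5,17.2,87.2,579.7,11.0,295.4,249.1,14.2,195.8,26.2
3,post,899.4,20.0,43.7,557.1,15.0,109.2,544.9,17.9,122.0,21.4
4,pre,849.6,22.8,95.4,907.5,12.8,292.3,590.4,13.3,231.4,110.7
4,post,726.7,21.7,39.3,568.5,16.1,148.1,400.3,16.9,139.9,14.1
5,pre,618.7,20.6,105.8,706.4,9.1,465.5,481.3,12.5,408.3,106.8
5,post,306.6,17.6,24.8,76.5,13.3,43.9,300.6,14.4,78.7,9.5
6,pre,869.2,17.1,113.1,1035.4,9.8,709.2,384.8,12.0,547.2,234.9
6,post,977.8,16.6,65.6,850.8,11.2,218.0,1082.1,7.5,422.0,87.0
7,pre,1077.5,16.8,129.3,949.1,11.4,283.4,489.1,15.3,208.0,52.2
7,post,1006.5,15.4,85.4,782.5,11.0,176.9,554.4,12.2,217.2,38.3
8,pre,649.9,20.1,129.6,580.6,11.4,466.9,418.3,15.0,337.1,155.5
8,post,429.0,20.0,39.1,456.0,11.4,130.7,256.9,15.1,83.1,9.4
9,pre,1285.9,16.5,157.1,1340.8,12.5,401.2,495.5,9.2,286.0,74.7
9,post,1307.3,18.9,35.7,2037.6,13.1,122.7,318.1,12.0,69.4,29.2
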