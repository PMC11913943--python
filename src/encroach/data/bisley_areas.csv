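year,class,area_ha,percent_cover_printed,status
2009,woody vegetation,133.32,37.69,observed
2009,grasses,213.15,60.25,observed
2009,bare areas,7.28,2.06,observed
2014,woody vegetation,181.05,51.18,observed
2014,grasses,153.79,43.47,observed
2014,bare areas,18.96,5.35,observed
2019,woody vegetation,224.55,64.52,observed
2019,grasses,124.93,35.32,observed
2019,bare areas,4.28,0.16,observed
2023,woody vegetation,261.86,74.02,observed
2023,grasses,89.79,25.38,observed
2023,bare areas,2.00,0.60,observed
2028,woody vegetation,281.31,79.52,projected
2028,grasses,66.89,18.91,projected
2028,bare areas,5.55,1.57,projected
2033,woody vegetation,304.91,86.19,projected
2033,grasses,46.10,13.03,projected
2033,bare areas,2.75,0.78,projected
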