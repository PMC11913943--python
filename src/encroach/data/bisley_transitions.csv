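interval,year_start,year_end,from,to,area_ha
2009-2014,2009,2014,grasses,grasses,137.98
2009-2014,2009,2014,grasses,woody vegetation,58.63
2009-2014,2009,2014,woody vegetation,grasses,10.18
2009-2014,2009,2014,woody vegetation,woody vegetation,121.70
2009-2014,2009,2014,grasses,bare areas,16.07
2009-2014,2009,2014,bare areas,grasses,5.21
2014-2019,2014,2019,grasses,grasses,104.85
2014-2019,2014,2019,grasses,woody vegetation,47.24
2014-2019,2014,2019,woody vegetation,grasses,8.74
2014-2019,2014,2019,woody vegetation,woody vegetation,172.06
2014-2019,2014,2019,grasses,bare areas,1.41
2014-2019,2014,2019,bare areas,grasses,10.10
2019-2023,2019,2023,grasses,grasses,97.19
2019-2023,2019,2023,grasses,woody vegetation,44.10
2019-2023,2019,2023,woody vegetation,grasses,6.96
2019-2023,2019,2023,woody vegetation,woody vegetation,217.23
2019-2023,2019,2023,grasses,bare areas,1.08
2019-2023,2019,2023,bare areas,grasses,3.41
2009-2023,2009,2023,grasses,grasses,80.52
2009-2023,2009,2023,grasses,woody vegetation,130.69
2009-2023,2009,2023,woody vegetation,grasses,2.78
2009-2023,2009,2023,woody vegetation,woody vegetation,130.07
2009-2023,2009,2023,grasses,bare areas,0.43
2009-2023,2009,2023,bare areas,grasses,6.2
2023-2028,2023,2028,grasses,grasses,44.84
2023-2028,2023,2028,grasses,woody vegetation,40.68
2023-2028,2023,2028,woody vegetation,grasses,20.87
2023-2028,2023,2028,woody vegetation,woody vegetation,239.39
2023-2028,2023,2028,grasses,bare areas,3.99
2023-2028,2023,2028,bare areas,grasses,0.64
2028-2033,2028,2033,grasses,grasses,37.07
2028-2033,2028,2033,grasses,woody vegetation,28.97
2028-2033,2028,2033,woody vegetation,grasses,8.41
2028-2033,2028,2033,woody vegetation,woody vegetation,272.55
2028-2033,2028,2033,grasses,bare areas,0.86
2028-2033,2028,2033,bare areas,grasses,0.61
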