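# Seasonal distribution of weather types (WT) and of damaging flood/landslide
# events in Italy, 1948-2003. n_days = number of days classified to the WT in
# the season; n_events = number of damaging events recorded on those days.
season,wt,n_days,n_events
winter,1,675,70
winter,2,1073,156
winter,3,538,83
winter,4,489,72
winter,5,1309,99
winter,6,15,2
winter,7,550,63
winter,8,383,119
spring,1,613,27
spring,2,989,76
spring,3,584,37
spring,4,782,45
spring,5,958,71
spring,6,2,0
spring,7,565,60
spring,8,659,90
summer,1,272,25
summer,2,1381,97
summer,3,626,29
summer,4,730,29
summer,5,1199,100
summer,6,0,0
summer,7,601,50
summer,8,343,136
autumn,1,506,27
autumn,2,960,158
autumn,3,574,150
autumn,4,511,219
autumn,5,1601,285
autumn,6,1,0
autumn,7,458,123
autumn,8,480,504
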