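# Catalog of the eight European weather types (WTs) used throughout the
# package, with the circulation prevailing over Italy under each.
wt,description
1,Marked northward expansion of the Azores anticyclone with blocked anticyclonic circulation over the North Atlantic and northerly winds over Italy
2,Moderate northward expansion of the Azores anticyclone with cyclonic circulation over south Scandinavia and north-westerly winds over Italy
3,"Marked cyclonic circulation over Iceland with anticyclonic circulation over northern central Europe accompanied with increased precipitation over Italy, generated by intermittent Atlantic perturbations"
4,Cyclonic circulation over the North Atlantic and cyclonic circulation over west Mediterranean Europe and central Mediterranean Europe with decreased precipitations over central Mediterranean Europe
5,"Cyclonic circulation over the north-west Atlantic with marked anticyclonic circulation over west Mediterranean Europe and central Mediterranean Europe, inducing warm and dry conditions over Italy"
6,"Anticyclonic circulation over Iceland and cyclonic circulation over central Europe, with higher precipitation over Tuscany by intrusions of artic and polar continental air"
7,"South westerly flow over the North Atlantic with ridging over the British Isles towards Scandinavia, with easterly wind over central Mediterranean Europe resulting in very cold dry conditions"
8,Cyclonic circulation over west Europe with a ridge over the eastern Mediterranean
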