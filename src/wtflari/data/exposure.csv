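# Exposure / vulnerability measurements per Italian region:
# population density (inhabitants per km^2), river surface (km),
# non-plain (hilly + mountainous) surface (km^2).
region,population_density,river_surface,non_plain_surface
Abruzzo,121,4671,10831
Basilicata,57,5550,9267
Calabria,129,9504,15221
Campania,422,6147,11675
Emilia Romagna,195,10587,11720
Friuli Venezia Giulia,155,4005,4866
Lazio,322,9464,13803
Liguria,289,3943,5416
Lombardia,410,10289,12623
Marche,164,5594,9401
Molise,70,2414,4460
Piemonte,172,15077,18684
Puglia,207,4395,9145
Sardegna,68,15104,19641
Sicilia,194,11122,22164
Toscana,161,15098,21056
Trentino Alto Adige,76,7355,13605
Umbria,105,5214,8464
Veneto,265,7553,8025
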