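#meta subject=Manda experiment=exp2 correct_exchanges=6 incorrect_exchanges=0
subject,species,experiment,trial,entered,removed,first_touch,offered,foreign_offer,note
Manda,Pan troglodytes,exp2,1,1,jute;metal;wood,UNKNOWN,UNKNOWN,,"metal touched first in 11 of 12 trials; exception trial not reported, placed at trial 1"
Manda,Pan troglodytes,exp2,2,1,metal;rope;wood,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,3,1,metal;rope,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,4,1,metal;rope,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,5,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,6,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,7,1,metal;wood,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,8,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,9,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,10,1,metal;rope,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,11,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Manda,Pan troglodytes,exp2,12,1,metal,metal,UNKNOWN,,exchange outcome known only in aggregate (6 of 12)
Maria-Magdalena,Pan troglodytes,exp2,1,1,jute;metal;rope;wood,UNKNOWN,metal,,first touch not target; identity not reported
Maria-Magdalena,Pan troglodytes,exp2,2,1,jute;wood,UNKNOWN,NONE,,first touch not target; identity not reported
Maria-Magdalena,Pan troglodytes,exp2,3,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,4,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,5,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,6,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,7,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,8,1,rope;wood,UNKNOWN,NONE,,first touch not target; identity not reported
Maria-Magdalena,Pan troglodytes,exp2,9,1,metal,metal,metal,,
Maria-Magdalena,Pan troglodytes,exp2,10,1,rope;wood,UNKNOWN,NONE,,first touch not target; identity not reported
Maria-Magdalena,Pan troglodytes,exp2,11,1,rope,UNKNOWN,NONE,,first touch not target; identity not reported
Maria-Magdalena,Pan troglodytes,exp2,12,1,rope,UNKNOWN,NONE,,first touch not target; identity not reported
Naong,Pongo abelii,exp2,1,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,2,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,3,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,4,0,,NONE,NONE,,did not enter
Naong,Pongo abelii,exp2,5,0,,NONE,NONE,,did not enter
Naong,Pongo abelii,exp2,6,0,,NONE,NONE,,did not enter
Naong,Pongo abelii,exp2,7,0,,NONE,NONE,,did not enter
Naong,Pongo abelii,exp2,8,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,9,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,10,1,metal,metal,metal,,
Naong,Pongo abelii,exp2,11,1,rope;wood,metal,wood,,"metal touched first but accidentally swept out of reach; took rope and wood, tried to exchange wood"
Naong,Pongo abelii,exp2,12,1,metal,metal,metal,,
Dunja,Pongo abelii,exp2,1,0,,NONE,OTHER,faeces,came to the exchange location; trial placement of the two foreign offers not reported
Dunja,Pongo abelii,exp2,2,0,,NONE,OTHER,sponge,came to the exchange location; trial placement of the two foreign offers not reported
Dunja,Pongo abelii,exp2,3,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,4,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,5,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,6,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,7,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,8,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,9,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,10,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,11,0,,NONE,NONE,,did not enter
Dunja,Pongo abelii,exp2,12,0,,NONE,NONE,,did not enter
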