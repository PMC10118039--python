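species,condition,metabolite,mean,sd,significant
mustard,HYDRO,Citrate,8.1,5.7,False
phacelia,FIELD,Citrate,17.5,15.2,False
phacelia,HYDRO,Citrate,1.1,1.0,True
oat,FIELD,Citrate,2.4,3.5,False
clover,FIELD,Citrate,73.9,71.5,False
clover,HYDRO,Citrate,0.7,0.8,True
phacelia,FIELD,Fumarate,137.0,98.3,False
clover,FIELD,Fumarate,9.2,2.1,False
mustard,HYDRO,Malate,16.3,13.1,False
phacelia,FIELD,Malate,67.0,38.3,False
oat,FIELD,Malate,8.6,8.6,False
oat,HYDRO,Malate,19.3,6.8,True
clover,FIELD,Malate,49.3,47.3,False
phacelia,FIELD,Succinate,6.1,3.5,False
oat,FIELD,Succinate,1.6,1.0,False
clover,FIELD,Succinate,5.6,4.1,False
mustard,HYDRO,Glucose,222.8,143.7,False
phacelia,FIELD,Glucose,50.1,36.2,False
clover,FIELD,Glucose,52.2,31.7,False
clover,HYDRO,Glucose,52.4,32.8,False
mustard,FIELD,Fructose,22.9,14.2,False
mustard,HYDRO,Fructose,153.6,113.3,True
phacelia,FIELD,Fructose,43.6,29.6,False
phacelia,HYDRO,Fructose,68.5,59.3,False
oat,FIELD,Fructose,24.1,21.7,False
clover,FIELD,Fructose,50.0,32.9,False
mustard,HYDRO,Sucrose,161.0,114.9,False
phacelia,FIELD,Sucrose,73.7,41.0,False
phacelia,HYDRO,Sucrose,56.6,43.3,False
oat,FIELD,Sucrose,10.6,5.9,False
oat,HYDRO,Sucrose,17.8,12.5,False
clover,FIELD,Sucrose,24.3,18.1,False
clover,HYDRO,Sucrose,170.4,134.9,True
mustard,FIELD,Ala,23.7,8.8,False
mustard,HYDRO,Ala,52.0,35.3,False
phacelia,FIELD,Ala,46.1,25.7,False
oat,FIELD,Ala,30.9,13.2,False
oat,HYDRO,Ala,54.7,15.4,False
clover,FIELD,Ala,29.9,21.0,False
clover,HYDRO,Ala,17.7,9.3,False
oat,HYDRO,Arg,23.4,9.0,False
clover,FIELD,Asn,56.7,45.7,False
clover,HYDRO,Asn,19.1,6.4,False
phacelia,FIELD,Asp,27.1,9.9,False
oat,FIELD,Asp,22.1,4.8,False
oat,HYDRO,Asp,21.4,8.3,False
mustard,HYDRO,Gaba,62.3,25.0,False
phacelia,HYDRO,Gaba,25.8,23.6,False
mustard,HYDRO,Glu,20.3,12.4,False
phacelia,FIELD,Glu,27.3,8.4,False
oat,HYDRO,Glu,37.1,9.7,False
clover,HYDRO,Glu,20.4,23.5,False
mustard,FIELD,Gln,31.8,19.5,False
phacelia,FIELD,Gln,234.4,187.5,False
oat,FIELD,Gln,76.4,48.3,False
clover,FIELD,Gln,117.5,113.5,False
mustard,HYDRO,Gly,15.2,7.1,False
phacelia,FIELD,Gly,34.1,17.5,False
oat,HYDRO,Gly,51.0,15.1,False
oat,HYDRO,Ile,15.6,5.5,False
mustard,HYDRO,Leu,20.0,11.4,False
phacelia,FIELD,Leu,32.5,24.6,False
oat,FIELD,Leu,19.1,4.5,False
oat,HYDRO,Leu,40.1,12.2,True
mustard,HYDRO,Lys,14.7,8.6,False
oat,HYDRO,Lys,23.7,9.9,False
mustard,FIELD,Met,25.2,10.0,False
mustard,HYDRO,Met,18.7,12.8,False
oat,HYDRO,Met,26.4,10.1,False
clover,HYDRO,Met,18.8,6.6,False
oat,HYDRO,Phe,13.7,4.0,False
mustard,HYDRO,Pro,12.9,4.9,False
oat,HYDRO,Pro,13.6,4.0,False
mustard,HYDRO,Ser,13.2,6.4,False
phacelia,FIELD,Ser,45.6,25.4,False
oat,HYDRO,Ser,20.4,6.4,False
mustard,HYDRO,Thr,16.7,6.5,False
phacelia,FIELD,Thr,26.7,9.4,False
oat,HYDRO,Thr,19.3,5.4,False
mustard,FIELD,Tyr,45.9,39.8,False
mustard,HYDRO,Tyr,23.9,19.9,False
phacelia,FIELD,Tyr,32.8,34.9,False
oat,FIELD,Tyr,33.8,15.9,False
oat,HYDRO,Tyr,29.7,9.9,False
clover,HYDRO,Tyr,15.0,11.7,False
mustard,HYDRO,Val,17.1,10.0,False
phacelia,FIELD,Val,28.4,20.0,False
oat,FIELD,Val,19.7,5.2,False
oat,HYDRO,Val,32.4,10.0,True
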