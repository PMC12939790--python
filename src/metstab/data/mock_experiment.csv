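environment,genotype,block,role,yield
E1,L001,B1,line,6.935329553549338
E1,L002,B2,line,10.272482191735465
E1,L003,B3,line,9.726058567540052
E1,L004,B4,line,7.987382784117564
E1,L005,B1,line,8.054551000794797
E1,L006,B2,line,8.745078395110468
E1,L007,B3,line,6.035665798297851
E1,L008,B4,line,6.8364086281699725
E1,L009,B1,line,8.496707358759135
E1,L010,B2,line,7.9632539253978525
E1,L011,B3,line,8.1917756296736
E1,L012,B4,line,7.529162853440537
E1,L013,B1,line,9.135238296516212
E1,L014,B2,line,8.727177369653758
E1,L015,B3,line,8.45419024379411
E1,L016,B4,line,8.77762998337376
E1,L017,B1,line,8.32288528322276
E1,L018,B2,line,8.234538641871266
E1,L019,B3,line,6.881834731519577
E1,L020,B4,line,7.482019258384351
E1,CHK1,B1,check,8.4547277308276
E1,CHK2,B1,check,8.804337998126215
E1,CHK3,B1,check,8.265839221861135
E1,CHK4,B1,check,8.450168351732193
E1,CHK1,B2,check,8.884004975692458
E1,CHK2,B2,check,8.710027453454495
E1,CHK3,B2,check,8.752158761313803
E1,CHK4,B2,check,8.336706915312028
E1,CHK1,B3,check,8.636603712965593
E1,CHK2,B3,check,8.389658304292047
E1,CHK3,B3,check,7.935861253769345
E1,CHK4,B3,check,8.335439248485045
E1,CHK1,B4,check,8.284392367057835
E1,CHK2,B4,check,8.508336784627511
E1,CHK3,B4,check,8.10435581705751
E1,CHK4,B4,check,8.759153001880007
E2,L001,B1,line,4.890065366179243
E2,L002,B2,line,8.368530917459474
E2,L003,B3,line,6.491889746183503
E2,L004,B4,line,6.2977788680761
E2,L005,B1,line,6.648526441245957
E2,L006,B2,line,7.250186569580533
E2,L007,B3,line,5.597834042537448
E2,L008,B4,line,3.583120572080559
E2,L009,B1,line,3.6516268534482723
E2,L010,B2,line,6.221303120777136
E2,L011,B3,line,7.743744801131076
E2,L012,B4,line,6.244751859171134
E2,L013,B1,line,6.431359317100972
E2,L014,B2,line,7.702320858055507
E2,L015,B3,line,6.412605400594835
E2,L016,B4,line,7.1785266635024
E2,L017,B1,line,7.246196169509745
E2,L018,B2,line,5.390386803566089
E2,L019,B3,line,4.941828515866286
E2,L020,B4,line,5.540410458136125
E2,CHK1,B1,check,6.605777924482851
E2,CHK2,B1,check,6.545752826377052
E2,CHK3,B1,check,6.530931963719941
E2,CHK4,B1,check,6.361243114548437
E2,CHK1,B2,check,6.667553853874712
E2,CHK2,B2,check,6.792417099306044
E2,CHK3,B2,check,6.163337805481454
E2,CHK4,B2,check,6.848208546440838
E2,CHK1,B3,check,6.3802904399027085
E2,CHK2,B3,check,6.379082762851116
E2,CHK3,B3,check,6.559023851762735
E2,CHK4,B3,check,6.715158894188394
E2,CHK1,B4,check,6.752901753690592
E2,CHK2,B4,check,6.4490403159967755
E2,CHK3,B4,check,6.376416903481442
E2,CHK4,B4,check,6.929284109735038
E3,L001,B1,line,6.168766802259426
E3,L002,B2,line,9.016233451093091
E3,L003,B3,line,8.627064497348163
E3,L004,B4,line,7.559739796358684
E3,L005,B1,line,7.0391592906878255
E3,L006,B2,line,8.47708360774943
E3,L007,B3,line,5.898261249180746
E3,L008,B4,line,5.634580092783565
E3,L009,B1,line,6.387692389971092
E3,L010,B2,line,7.055339076242795
E3,L011,B3,line,7.742776042778476
E3,L012,B4,line,7.3338004813263185
E3,L013,B1,line,8.014125967707228
E3,L014,B2,line,8.196385119503407
E3,L015,B3,line,7.564995907670632
E3,L016,B4,line,7.237031316615543
E3,L017,B1,line,8.201963287410381
E3,L018,B2,line,7.066036219667939
E3,L019,B3,line,6.093034632705135
E3,L020,B4,line,6.967789210681903
E3,CHK1,B1,check,7.354141000757269
E3,CHK2,B1,check,7.6044496338077945
E3,CHK3,B1,check,7.529795405689972
E3,CHK4,B1,check,7.882644336972014
E3,CHK1,B2,check,7.9748827935670406
E3,CHK2,B2,check,7.867299837327246
E3,CHK3,B2,check,7.3444531978757075
E3,CHK4,B2,check,7.55924381186831
E3,CHK1,B3,check,7.705452249151442
E3,CHK2,B3,check,7.940804043246511
E3,CHK3,B3,check,7.958958883082861
E3,CHK4,B3,check,7.268997758256456
E3,CHK1,B4,check,7.684680526641184
E3,CHK2,B4,check,7.632004081118755
E3,CHK3,B4,check,7.512230458381235
E3,CHK4,B4,check,7.67038132456792
E4,L001,B1,line,4.363880506746786
E4,L002,B2,line,8.906644138829556
E4,L003,B3,line,9.055695087399071
E4,L004,B4,line,6.837964759732803
E4,L005,B1,line,6.73649853223402
E4,L006,B2,line,7.739869054247008
E4,L007,B3,line,4.260912682809644
E4,L008,B4,line,4.360923024177534
E4,L009,B1,line,4.530357537654455
E4,L010,B2,line,6.080693608243895
E4,L011,B3,line,6.667871347219704
E4,L012,B4,line,6.040413185595263
E4,L013,B1,line,8.026465290243689
E4,L014,B2,line,6.661276136764078
E4,L015,B3,line,6.46498005102412
E4,L016,B4,line,6.8257276409980845
E4,L017,B1,line,5.854613013115065
E4,L018,B2,line,5.797356514005171
E4,L019,B3,line,6.233175263668215
E4,L020,B4,line,5.604060882949292
E4,CHK1,B1,check,6.173048928338691
E4,CHK2,B1,check,7.3918166924888675
E4,CHK3,B1,check,6.42853651976382
E4,CHK4,B1,check,7.038788650616098
E4,CHK1,B2,check,6.965472177551632
E4,CHK2,B2,check,6.968476045011929
E4,CHK3,B2,check,6.4121482630480156
E4,CHK4,B2,check,6.803159242537284
E4,CHK1,B3,check,6.622413723825594
E4,CHK2,B3,check,6.938901909167945
E4,CHK3,B3,check,6.345195182531256
E4,CHK4,B3,check,6.867297258424384
E4,CHK1,B4,check,7.1225981073705125
E4,CHK2,B4,check,6.720983802942708
E4,CHK3,B4,check,6.539019726027633
E4,CHK4,B4,check,6.686506703284714
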