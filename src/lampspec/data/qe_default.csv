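wavelength_nm,value
350.0,0.04167854980631477
355.0,0.05001548441688787
360.0,0.05966015795157224
365.0,0.07069934270767815
370.0,0.08318856300851576
375.0,0.0971420530507523
380.0,0.11252423458175441
385.0,0.12924422694815524
390.0,0.1471547467104072
395.0,0.16605624246372733
400.0,0.1857062991934652
405.0,0.20583341090473792
410.0,0.22615340910145557
415.0,0.24638637981214018
420.0,0.26627192559671886
425.0,0.2855810973790799
430.0,0.30412406678560644
435.0,0.3217534086123708
440.0,0.3383635200535461
445.0,0.3538871086449379
450.0,0.36828981991815024
455.0,0.38156400312629624
460.0,0.3937224135328684
465.0,0.40479240354791274
470.0,0.4148109212552229
475.0,0.4238204459631823
480.0,0.43186585677462724
485.0,0.43899214812112153
490.0,0.44524286522662404
495.0,0.4506591203965078
500.0,0.45527905699573634
505.0,0.4591376435805248
510.0,0.46226670006704573
515.0,0.4646950774368114
520.0,0.46644893030219214
525.0,0.46755203680066926
530.0,0.4680261325450768
535.0,0.4678912348958893
540.0,0.4671659409809639
545.0,0.4658676880603497
550.0,0.46401296839562167
555.0,0.4616174930640246
560.0,0.4586963004285146
565.0,0.4552638054500061
570.0,0.4513337858737154
575.0,0.4469193006671798
580.0,0.4420325350421609
585.0,0.4366845650632934
590.0,0.4308850333636303
595.0,0.42464172604059003
600.0,0.41796003969410495
605.0,0.4108423272745655
610.0,0.40328711270511236
615.0,0.39528816834781805
620.0,0.38683345816224113
625.0,0.3779039656307733
630.0,0.368472453157384
635.0,0.358502244032637
640.0,0.3479461858291545
645.0,0.33674605228030946
650.0,0.324832774240493
655.0,0.31212805668168797
660.0,0.29854811797932823
665.0,0.2840104276667015
670.0,0.2684443166250876
675.0,0.25180602558507287
680.0,0.2340979400163528
685.0,0.2153902772843814
690.0,0.19584142497993323
695.0,0.17571103176172942
700.0,0.1553589635310668
705.0,0.13522475565474695
710.0,0.11578693831949219
715.0,0.0975085239376947
720.0,0.08078098302247336
725.0,0.06588073275833882
730.0,0.052948142489140114
735.0,0.041991300056679205
740.0,0.03290926943541172
745.0,0.02552552345503982
750.0,0.019622359147789002
755.0,0.014969954166672378
760.0,0.011347248492914304
765.0,0.008554608242379448
770.0,0.006419770613114682
775.0,0.004799058589581455
780.0,0.0035757019480905754
785.0,0.0026566784090427866
790.0,0.0019690313345385327
795.0,0.0014562390671418134
800.0,0.0010749360661358248
805.0,0.0007921077817980462
810.0,0.0005827765014519005
815.0,0.00042814069011929524
820.0,0.00031410683667171675
825.0,0.00023014723554229443
830.0,0.0001684208792278299
835.0,0.0001231025026961825
840.0,8.987387069858757e-05
845.0,6.554011405892729e-05
850.0,4.774161947149112e-05
855.0,3.4738442714966356e-05
860.0,2.524947048215236e-05
865.0,1.8332732846056006e-05
870.0,1.3296535030143022e-05
875.0,9.6336017242448e-06
880.0,6.9723607369777e-06
885.0,5.040963356668281e-06
890.0,3.640751109201563e-06
895.0,2.626716211445813e-06
900.0,1.893131478695207e-06
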