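0.000976344926142
0.0295416518248 0.0384030161295
9.99954930066e-05 0.00281722763431 0.000501869693609
0.00163321757432 0.00280202469938 0.000362301017068 0.00125947661828
0.0036390055982 0.00677678012051 0.000608090741558 0.00303453799579 6.22365216961e-05
0.00146625320101 0.00517742014779 0.0004961215888 0.00226811019264 0.00176556882818 0.00257360617016
0.00448984207952 0.000819623552378 0.000701242605669 0.00144353402372 0.000617041278272 0.000437138881039 0.00969157439885
0.00277095856334 0.00349023346767 0.00495032090037 0.00056054616678 0.00173302154743 0.00316502676387 0.00211656638948 0.00172587315395
0.000372181742738 0.00149316327987 0.00219203813188 0.0123175548242 0.00308834490504 0.00882678685914 0.000351161804366 0.000131978662075 0.000804673982642
0.000511607011516 0.000444488073205 0.00410166523744 0.00160119379756 0.00125771210807 0.00124064547905 0.00362495180896 0.00668125524732 0.00434267454596 0.00650931270155
0.00693405872937 0.000929965015973 0.000684830976292 0.000649231410051 0.000919895929176 0.032194599688 0.00116577873626 0.00740777983969 0.13927352068 0.00381928071778 0.0114804933025
0.0684381804772 0.00398807620676 0.0801455591113 0.000758983301894 0.00195607234866 0.000847504624131 0.00245802177917 0.00249933611285 0.00232303322806 0.000741847657308 0.0160621524671 0.00472792418124
0.00105893485606 0.00113071165195 0.00444335707431 0.00106502436318 0.000868542014069 0.000455749954039 0.000768602740064 0.00451312292584 0.00516027933275 0.00657593872059 0.000787705440176 0.000994722034227 0.0027408997343
0.00300062193899 0.0014902446497 0.00944179437057 0.00406934690886 0.00233997960926 0.000211158738737 0.019980632554 0.00283687865516 0.000551053454341 0.0055128418398 0.0219407984632 0.000243337833575 0.00285584307343 0.0561210919703
0.00059322475794 0.000627633479971 0.00230260675517 0.00020032301785 0.000943524973812 0.00587260958631 0.000710524585022 0.00151294457233 0.00185875901687 0.00177190350086 0.00131765469361 0.000208609358366 0.00257555556636 0.000832972584985 0.00447483958632
0.00079553493883 0.00130147192158 0.011011700927 0.000106345803682 0.00344232830202 0.000311058808181 4.5723849344e-05 0.000602179358453 0.00686106687798 0.000595279217605 0.00249056081986 0.00135317188511 0.00086811828256 0.000410622859942 0.00050955479548 0.0026883234687
0.00188968261374 0.00137942217043 0.00171193097747 0.00256176169271 0.00352993902105 0.000614077733144 0.0036662174671 0.00106982296707 0.00224984258178 0.00162306381606 0.0118302311632 0.00080972308695 0.000877306777488 0.0245650990331 0.00183429947083 0.00259604156963 0.00125808768627
0.0047376688998 0.0070945412035 0.00348144434682 0.00592256072114 0.000328250059512 0.000311881727938 0.000459360090379 0.00234385810858 0.00368996856501 0.000581457392656 0.00332189489201 0.000384023911145 0.00176408722812 0.00344340676517 0.0351476103253 0.00100761779566 0.00657014245037 0.000144050376376
0.000585211409437 0.000213595454108 0.000788494056878 0.000119248393972 0.000241624735739 0.0100213044942 0.000807331182131 0.00246313988001 0.00183057557957 0.00458269094948 0.00279568593455 0.00115144330245 0.00724521405944 0.000396852782586 0.000528524916219 0.00084381473527 0.00235526995875 0.00236208082966 0.000234662392051

0.0438494751894 0.0637449548067 0.0538238651 0.0412438545357 0.0530507443298 0.0495436972966 0.0477010202394 0.0461324576432 0.0459112774953 0.0550650767005 0.0565870018168 0.0475441672794 0.0510096043594 0.0624484499392 0.0412678719112 0.0668668975032 0.034321858953 0.0543861448002 0.0428314621736 0.0426701179273
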